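drug,display_name,refractivity,enthalpy,molar_volume,polarity,complexity,boiling_point
fluticasone-propionate,Fluticasone propionate,121.65,98.0,377.00,48.01,984,568.30
clobetasone,Clobetasone,104.72,95.3,309.10,40.50,850,549.00
beclomethasone-dipropionate,Beclomethasone dipropionate,134.79,103.5,302.60,41.60,1050,600.20
desonide,Desonide,112.06,99.6,320.10,43.30,873,580.10
clobetasol-propionate,Clobetasol propionate,119.32,98.1,364.10,46.70,929,569.00
azathioprine,Azathioprine,69.94,96.9,145.40,27.30,354,685.70
monobenzone,Monobenzone,59.11,62.8,172.60,23.50,167,359.10
betamethasone-valerate,Betamethasone valerate,,102.3,382.40,49.00,957,598.90
psoralen,Psoralen,,60.9,134.00,19.80,284,362.60
hydrocortisone-valerate,Hydrocortisone valerate,120.38,101.8,367.60,47.20,832,595.30
fluticasone,Fluticasone,107.87,95.9,323.20,42.40,861,553.20
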