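drug,display_name,ABC,RA,S,GA,M1,M2,H,HM,F
fluticasone-propionate,Fluticasone propionate,22.48,13.29,13.8,29.32,162,204,12.43,886,478
clobetasone,Clobetasone,22.62,12.96,13.57,29.08,167,214,12.01,941,513
beclomethasone-dipropionate,Beclomethasone dipropionate,28.11,16.81,17.42,36.98,204,261,15.78,1128,606
desonide,Desonide,24.48,13.98,14.85,32.2,184,238,13.11,1036,560
clobetasol-propionate,Clobetasol propionate,21.63,12.54,13.17,28.36,162,212,11.73,922,498
azathioprine,Azathioprine,14.08,8.79,9.24,19.68,96,115,8.6,474,244
monobenzone,Monobenzone,11.42,7.34,7.58,15.7,72,79,7.2,328,170
betamethasone-valerate,Betamethasone valerate,24.36,14.65,15.29,32.58,174,219,13.91,932,494
psoralen,Psoralen,11.34,6.82,7.29,15.66,78,93,6.67,386,200
hydrocortisone-valerate,Hydrocortisone valerate,25.04,15.13,15.74,33.48,180,227,14.36,974,520
fluticasone,Fluticasone,26.65,15.83,16.43,35.03,196,254,14.81,1098,590
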