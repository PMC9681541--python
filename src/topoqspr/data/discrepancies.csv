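quantity,location_a,value_a,location_b,value_b,default_choice,note
monobenzone polarity,Table 2,23.50,Table 15,35.50,Table 2,conflicting duplicated observation; which value produced the printed polarity statistics is undeterminable
azathioprine refractivity,Table 2,69.94,Table 18,59.94,Table 2,conflicting duplicated observation
fluticasone molar volume,Table 2,323.20,Table 16,336.6,Table 2,conflicting duplicated observation
psoralen hyper-Zagreb HM,Theorem 1 statement / Table 1,386,Theorem 1 proof,336,Definition formula,proof line is a typo; the definition evaluates to 386
azathioprine GA,Theorem 2 statement / Table 1,19.68,Definition formula on the printed partition,19.63,Definition formula,formula value reported; printed value treated as a typo
azathioprine ABC,Theorem 2 statement / Table 1,14.08,Definition formula on the printed partition,14.09,Definition formula,formula value reported; printed value treated as rounding error
psoralen Randic RA,Table 1 / Theorem 1,6.82,Definition formula on the printed partition,6.83,Definition formula,printed value appears truncated rather than rounded
azathioprine harmonic H,Theorem 2 proof,9.60,Theorem 2 statement / Table 1,8.60,Definition formula,definition evaluates to 8.60; proof line is a typo
H-polarity correlation,Table 12,0.8663,Table 10,0.663,Definition formula,same quantity printed twice with different values; the pipeline reports the value recomputed from Table 2
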