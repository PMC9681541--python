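index,property,N,A,b,r,r2,F,p,se
ABC,enthalpy,11,46.897,2.171,0.836,0.699,20.880,0.001,21.4533
ABC,polarity,11,6.498,1.426,0.621,0.386,5.658,0.041,5.14068
ABC,molar_volume,11,2.954,13.765,0.858,0.736,25.032,0.001,51.8856
ABC,complexity,11,-309.258,50.191,0.945,0.893,75.089,0.000,107.768
ABC,refractivity,9,14.804,4.199,0.920,0.846,38.376,0.000,10.49394
RA,enthalpy,11,-2.826,6.871,0.743,0.552,11.019,0.009,22.2725
RA,polarity,11,5.422,2.676,0.875,0.765,29.283,0.000,5.34215
RA,molar_volume,11,-1.826,23.293,0.843,0.710,22.062,0.001,53.57962
RA,complexity,11,-321.914,84.555,0.924,0.855,52.887,0.000,125.620
RA,refractivity,9,11.323,7.267,0.908,0.824,32.860,0.001,11.19653
S,enthalpy,11,-4.082,6.671,0.745,0.555,11.243,0.008,22.1989
S,polarity,11,4.913,2.599,0.877,0.770,30.112,0.000,5.28520
S,molar_volume,11,-5.918,22.601,0.845,0.713,22.386,0.001,53.30246
S,complexity,11,-338.894,82.205,0.928,0.862,56.013,0.000,122.563
S,refractivity,9,10.675,7.010,0.910,0.828,33.799,0.001,11.06695
GA,enthalpy,11,-3.676,3.112,0.747,0.559,11.388,0.008,22.1199
GA,polarity,11,5.068,1.213,0.880,0.774,30.897,0.000,5.23301
GA,molar_volume,11,-4.316,10.537,0.846,0.716,22.713,0.001,53.02684
GA,complexity,11,-335.797,38.423,0.932,0.870,59.991,0.000,118.977
GA,refractivity,9,11.940,3.243,0.912,0.832,34.670,0.001,10.95059
M1,enthalpy,11,5.191,0.514,0.770,0.593,13.093,0.006,21.2492
M1,polarity,11,9.228,0.196,0.886,0.784,32.691,0.000,5.11913
M1,molar_volume,11,30.594,1.708,0.856,0.732,24.595,0.001,51.52025
M1,complexity,11,-214.531,6.269,0.949,0.900,81.168,0.000,104.072
M1,refractivity,9,24.456,0.513,0.920,0.846,38.420,0.000,10.48881
M2,enthalpy,11,11.592,0.374,0.769,0.591,12.989,0.006,21.2992
M2,polarity,11,11.709,0.142,0.883,0.779,31.732,0.000,5.17904
M2,molar_volume,11,52.287,1.240,0.853,0.727,23.987,0.001,51.99331
M2,complexity,11,-138.898,4.569,0.950,0.902,83.061,0.000,102.996
M2,refractivity,9,31.763,0.368,0.971,0.841,37.087,0.000,10.64628
H,enthalpy,11,43.150,4.138,0.838,0.703,21.272,0.001,22.7532
H,polarity,11,1.974,2.891,0.663,0.439,7.054,0.026,5.45760
H,molar_volume,11,-11.641,25.466,0.835,0.697,20.680,0.001,54.81297
H,complexity,11,-355.677,92.284,0.914,0.835,45.710,0.000,133.606
H,refractivity,9,7.904,7.986,0.900,0.809,29.722,0.001,11.66503
HM,enthalpy,11,13.232,0.085,0.776,0.602,13.614,0.005,21.0026
HM,polarity,11,12.603,0.032,0.882,0.778,31.535,0.000,5.19160
HM,molar_volume,11,59.517,0.279,0.854,0.730,24.303,0.001,51.74557
HM,complexity,11,-111.888,1.029,0.951,0.905,85.436,0.000,101.693
HM,refractivity,9,33.988,0.083,0.918,0.842,37.321,0.000,10.61813
F,enthalpy,11,57.317,0.079,0.821,0.674,18.643,0.002,21.0026
F,polarity,11,14.324,0.050,0.584,0.341,4.663,0.059,5.19160
F,molar_volume,11,65.780,0.508,0.855,0.731,24.433,0.001,51.64475
F,complexity,11,-88.525,1.870,0.952,0.905,86.119,0.000,101.327
F,refractivity,9,35.904,0.150,0.917,0.842,37.172,0.000,10.63600
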