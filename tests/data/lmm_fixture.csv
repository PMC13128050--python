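participant,group,condition,velocity,value
Y00,young,level,1.233622,15.828829
Y00,young,ascent,1.425497,21.611923
Y00,young,descent,1.074951,14.972916
Y01,young,level,1.227871,21.439842
Y01,young,ascent,1.134247,25.821864
Y01,young,descent,1.016569,25.882143
Y02,young,level,1.330235,21.727208
Y02,young,ascent,1.229667,25.560598
Y02,young,descent,1.276003,22.467341
Y03,young,level,1.254445,22.23372
Y03,young,ascent,1.318097,26.464487
Y03,young,descent,1.300888,22.872421
Y04,young,level,1.200345,11.812429
Y04,young,ascent,1.42905,25.13526
Y04,young,descent,1.429311,17.19788
Y05,young,level,1.33917,19.293876
Y05,young,ascent,1.220482,29.238028
Y05,young,descent,1.204932,24.109252
Y06,young,level,1.129635,18.253292
Y06,young,ascent,1.271227,27.463304
Y06,young,descent,1.092348,21.6642
Y07,young,level,1.053183,22.798765
Y07,young,ascent,1.323013,28.531651
Y07,young,descent,1.128694,24.934509
Y08,young,level,1.072823,21.602464
Y08,young,ascent,1.074979,24.749097
Y08,young,descent,1.296251,23.732991
Y09,young,level,1.379204,23.907979
Y09,young,ascent,1.137695,31.41974
Y09,young,descent,1.265633,28.75481
Y10,young,level,0.994377,23.016212
Y10,young,ascent,1.186362,24.891636
Y10,young,descent,1.197009,24.012328
Y11,young,level,1.067146,22.635436
Y11,young,ascent,1.199141,25.298747
Y11,young,descent,1.24261,23.421194
O00,old,level,1.289496,21.493321
O00,old,ascent,1.058936,33.97464
O00,old,descent,1.062371,28.289586
O01,old,level,0.95682,22.719854
O01,old,ascent,1.137338,36.88518
O01,old,descent,1.034792,29.19857
O02,old,level,0.962394,19.916113
O02,old,ascent,0.926231,28.58228
O02,old,descent,1.098309,27.759653
O03,old,level,1.276106,25.653041
O03,old,ascent,1.086743,32.432503
O03,old,descent,1.235985,29.20664
O04,old,level,1.269388,29.787555
O04,old,ascent,1.180269,37.567
O04,old,descent,1.119617,29.449824
O05,old,level,1.168133,21.824313
O05,old,ascent,1.20462,29.53996
O05,old,descent,0.978957,23.963226
O06,old,level,1.186384,30.605929
O06,old,ascent,1.010003,37.880075
O06,old,descent,1.14275,32.493009
O07,old,level,0.883545,23.039017
O07,old,ascent,1.229079,34.830441
O07,old,descent,1.074532,29.083954
O08,old,level,1.224824,24.324383
O08,old,ascent,1.232553,34.215812
O08,old,descent,1.248985,27.864455
O09,old,level,1.164025,25.388875
O09,old,ascent,1.094177,34.401901
O09,old,descent,0.944189,24.371997
O10,old,level,1.215621,15.117566
O10,old,ascent,0.973781,25.267057
O10,old,descent,1.296002,15.390471
O11,old,level,1.146324,32.246956
O11,old,ascent,1.278068,38.382894
O11,old,descent,0.810775,31.2686
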