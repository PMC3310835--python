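p,r,prob
0.005,8,0.4602923
0.005,18,0.9439192
0.005,28,0.9985824
0.005,48,0.9999997
0.0075,18,0.4937528
0.0075,28,0.8677739
0.0075,38,0.9860621
0.0075,58,0.9999798
0.01,31,0.4764102
0.01,41,0.792025
0.01,51,0.9491423
0.01,71,0.9993324
0.0125,49,0.4825564
0.0125,59,0.7531049
0.0125,69,0.9091713
0.0125,89,0.9962656
0.015,70,0.4831282
0.015,80,0.6966756
0.015,90,0.867216
0.015,110,0.9873122
0.0175,96,0.49556
0.0175,106,0.6823066
0.0175,116,0.83486
0.0175,136,0.9736274
0.02,126,0.4923463
0.02,136,0.6682315
0.02,146,0.8073307
0.02,166,0.9575451
0.0225,159,0.4885201
0.0225,169,0.6302238
0.0225,179,0.7655083
0.0225,199,0.9288043
0.025,198,0.5028085
0.025,208,0.631837
0.025,218,0.7583371
0.025,238,0.9121938
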