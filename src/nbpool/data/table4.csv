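method,gamma,p,omega,coverage,assurance
wald,0.5,0.0050,0.007,0.9544,0.5393
wald,0.5,0.0050,0.008,0.9580,0.5431
wald,0.5,0.0050,0.009,0.9538,0.5653
wald,0.5,0.0050,0.010,0.9581,0.5498
wald,0.5,0.0075,0.007,0.9548,0.5388
wald,0.5,0.0075,0.008,0.9523,0.5329
wald,0.5,0.0075,0.009,0.9533,0.5576
wald,0.5,0.0075,0.010,0.9595,0.5337
wald,0.5,0.0100,0.007,0.9524,0.5397
wald,0.5,0.0100,0.008,0.9502,0.5012
wald,0.5,0.0100,0.009,0.9574,0.5028
wald,0.5,0.0100,0.010,0.9536,0.5383
wald,0.5,0.0125,0.007,0.9499,0.5040
wald,0.5,0.0125,0.008,0.9508,0.5134
wald,0.5,0.0125,0.009,0.9518,0.5079
wald,0.5,0.0125,0.010,0.9557,0.5015
wald,0.5,0.0150,0.007,0.9505,0.5216
wald,0.5,0.0150,0.008,0.9522,0.5116
wald,0.5,0.0150,0.009,0.9520,0.5384
wald,0.5,0.0150,0.010,0.9507,0.5107
wald,0.5,0.0175,0.007,0.9489,0.5149
wald,0.5,0.0175,0.008,0.9497,0.5069
wald,0.5,0.0175,0.009,0.9489,0.5165
wald,0.5,0.0175,0.010,0.9479,0.5317
wald,0.5,0.0200,0.007,0.9522,0.5133
wald,0.5,0.0200,0.008,0.9485,0.5112
wald,0.5,0.0200,0.009,0.9494,0.5139
wald,0.5,0.0200,0.010,0.9509,0.5113
wald,0.5,0.0225,0.007,0.9514,0.5072
wald,0.5,0.0225,0.008,0.9519,0.5076
wald,0.5,0.0225,0.009,0.9457,0.5048
wald,0.5,0.0225,0.010,0.9548,0.5151
wald,0.5,0.0250,0.007,0.9520,0.5086
wald,0.5,0.0250,0.008,0.9512,0.5115
wald,0.5,0.0250,0.009,0.9465,0.5051
wald,0.5,0.0250,0.010,0.9516,0.5179
wald,0.8,0.0050,0.007,0.9543,0.8286
wald,0.8,0.0050,0.008,0.9528,0.8531
wald,0.8,0.0050,0.009,0.9532,0.8413
wald,0.8,0.0050,0.010,0.9566,0.8109
wald,0.8,0.0075,0.007,0.9554,0.8206
wald,0.8,0.0075,0.008,0.9523,0.8051
wald,0.8,0.0075,0.009,0.9551,0.8029
wald,0.8,0.0075,0.010,0.9516,0.8293
wald,0.8,0.0100,0.007,0.9516,0.8296
wald,0.8,0.0100,0.008,0.9524,0.8019
wald,0.8,0.0100,0.009,0.9560,0.8206
wald,0.8,0.0100,0.010,0.9545,0.8415
wald,0.8,0.0125,0.007,0.9476,0.8092
wald,0.8,0.0125,0.008,0.9473,0.8226
wald,0.8,0.0125,0.009,0.9508,0.8016
wald,0.8,0.0125,0.010,0.9529,0.8167
wald,0.8,0.0150,0.007,0.9477,0.8077
wald,0.8,0.0150,0.008,0.9517,0.8028
wald,0.8,0.0150,0.009,0.9511,0.8161
wald,0.8,0.0150,0.010,0.9526,0.8128
wald,0.8,0.0175,0.007,0.9504,0.8108
wald,0.8,0.0175,0.008,0.9503,0.8170
wald,0.8,0.0175,0.009,0.9502,0.8063
wald,0.8,0.0175,0.010,0.9466,0.8180
wald,0.8,0.0200,0.007,0.9508,0.8089
wald,0.8,0.0200,0.008,0.9514,0.8050
wald,0.8,0.0200,0.009,0.9504,0.8180
wald,0.8,0.0200,0.010,0.9504,0.8146
wald,0.8,0.0225,0.007,0.9498,0.7995
wald,0.8,0.0225,0.008,0.9500,0.8131
wald,0.8,0.0225,0.009,0.9460,0.8092
wald,0.8,0.0225,0.010,0.9527,0.8034
wald,0.9,0.0050,0.007,0.9492,0.9223
wald,0.9,0.0050,0.008,0.9525,0.9104
wald,0.9,0.0050,0.009,0.9527,0.9223
wald,0.9,0.0050,0.010,0.9537,0.9294
wald,0.9,0.0075,0.007,0.9504,0.9050
wald,0.9,0.0075,0.008,0.9529,0.9165
wald,0.9,0.0075,0.009,0.9526,0.9242
wald,0.9,0.0075,0.010,0.9548,0.9103
wald,0.9,0.0100,0.007,0.9505,0.9130
wald,0.9,0.0100,0.008,0.9520,0.9054
wald,0.9,0.0100,0.009,0.9518,0.9106
wald,0.9,0.0100,0.010,0.9493,0.9056
wald,0.9,0.0125,0.007,0.9524,0.9113
wald,0.9,0.0125,0.008,0.9533,0.9093
wald,0.9,0.0125,0.009,0.9512,0.9039
wald,0.9,0.0125,0.010,0.9513,0.9158
wald,0.9,0.0150,0.007,0.9484,0.8985
wald,0.9,0.0150,0.008,0.9498,0.8999
wald,0.9,0.0150,0.009,0.9492,0.9016
wald,0.9,0.0150,0.010,0.9551,0.9088
wald,0.9,0.0175,0.007,0.9486,0.9070
wald,0.9,0.0175,0.008,0.9486,0.9023
wald,0.9,0.0175,0.009,0.9510,0.9090
wald,0.9,0.0175,0.010,0.9478,0.9061
wald,0.9,0.0200,0.007,0.9518,0.9019
wald,0.9,0.0200,0.008,0.9482,0.9011
wald,0.9,0.0200,0.009,0.9495,0.9074
wald,0.9,0.0200,0.010,0.9567,0.9067
wald,0.9,0.0225,0.007,0.9494,0.8969
wald,0.9,0.0225,0.008,0.9534,0.9041
wald,0.9,0.0225,0.009,0.9509,0.9064
wald,0.9,0.0225,0.010,0.9472,0.9089
wald,0.9,0.0250,0.007,0.9492,0.9056
wald,0.9,0.0250,0.008,0.9511,0.8986
wald,0.9,0.0250,0.009,0.9533,0.9036
wald,0.9,0.0250,0.010,0.9530,0.9019
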