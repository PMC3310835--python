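method,gamma,p,omega,coverage,assurance
clopper_pearson,0.5,0.0050,0.007,0.9537,0.5383
clopper_pearson,0.5,0.0050,0.008,0.9564,0.5426
clopper_pearson,0.5,0.0050,0.009,0.9532,0.5696
clopper_pearson,0.5,0.0050,0.010,0.9566,0.5513
clopper_pearson,0.5,0.0075,0.007,0.9555,0.5404
clopper_pearson,0.5,0.0075,0.008,0.9535,0.5303
clopper_pearson,0.5,0.0075,0.009,0.9543,0.5564
clopper_pearson,0.5,0.0075,0.010,0.9593,0.5375
clopper_pearson,0.5,0.0100,0.007,0.9499,0.5673
clopper_pearson,0.5,0.0100,0.008,0.9547,0.5402
clopper_pearson,0.5,0.0100,0.009,0.9527,0.5721
clopper_pearson,0.5,0.0100,0.010,0.9537,0.5426
clopper_pearson,0.5,0.0125,0.007,0.9540,0.5607
clopper_pearson,0.5,0.0125,0.008,0.9517,0.5776
clopper_pearson,0.5,0.0125,0.009,0.9513,0.5795
clopper_pearson,0.5,0.0125,0.010,0.9527,0.5863
clopper_pearson,0.5,0.0150,0.007,0.9556,0.5650
clopper_pearson,0.5,0.0150,0.008,0.9493,0.5945
clopper_pearson,0.5,0.0150,0.009,0.9550,0.5486
clopper_pearson,0.5,0.0150,0.010,0.9500,0.5651
clopper_pearson,0.5,0.0175,0.007,0.9529,0.5660
clopper_pearson,0.5,0.0175,0.008,0.9525,0.5968
clopper_pearson,0.5,0.0175,0.009,0.9554,0.5521
clopper_pearson,0.5,0.0175,0.010,0.9509,0.5635
clopper_pearson,0.5,0.0200,0.007,0.9517,0.5953
clopper_pearson,0.5,0.0200,0.008,0.9506,0.5836
clopper_pearson,0.5,0.0200,0.009,0.9552,0.5930
clopper_pearson,0.5,0.0200,0.010,0.9505,0.5740
clopper_pearson,0.5,0.0225,0.007,0.9527,0.5940
clopper_pearson,0.5,0.0225,0.008,0.9488,0.6096
clopper_pearson,0.5,0.0225,0.009,0.9516,0.5919
clopper_pearson,0.5,0.0225,0.010,0.9545,0.5859
clopper_pearson,0.5,0.0250,0.007,0.9507,0.6014
clopper_pearson,0.5,0.0250,0.008,0.9491,0.6093
clopper_pearson,0.5,0.0250,0.009,0.9487,0.6103
clopper_pearson,0.5,0.0250,0.010,0.9523,0.5903
clopper_pearson,0.8,0.0050,0.007,0.9549,0.8299
clopper_pearson,0.8,0.0050,0.008,0.9518,0.8509
clopper_pearson,0.8,0.0050,0.009,0.9526,0.8453
clopper_pearson,0.8,0.0050,0.010,0.9551,0.8478
clopper_pearson,0.8,0.0075,0.007,0.9538,0.8182
clopper_pearson,0.8,0.0075,0.008,0.9549,0.8563
clopper_pearson,0.8,0.0075,0.009,0.9529,0.8384
clopper_pearson,0.8,0.0075,0.010,0.9538,0.8296
clopper_pearson,0.8,0.0100,0.007,0.9511,0.8403
clopper_pearson,0.8,0.0100,0.008,0.9502,0.8336
clopper_pearson,0.8,0.0100,0.009,0.9505,0.8388
clopper_pearson,0.8,0.0100,0.010,0.9551,0.8369
clopper_pearson,0.8,0.0125,0.007,0.9511,0.8422
clopper_pearson,0.8,0.0125,0.008,0.9526,0.8602
clopper_pearson,0.8,0.0125,0.009,0.9547,0.8517
clopper_pearson,0.8,0.0125,0.010,0.9541,0.8324
clopper_pearson,0.8,0.0150,0.007,0.9523,0.8493
clopper_pearson,0.8,0.0150,0.008,0.9517,0.8456
clopper_pearson,0.8,0.0150,0.009,0.9537,0.8631
clopper_pearson,0.8,0.0150,0.010,0.9521,0.8429
clopper_pearson,0.8,0.0175,0.007,0.9489,0.8444
clopper_pearson,0.8,0.0175,0.008,0.9537,0.8534
clopper_pearson,0.8,0.0175,0.009,0.9471,0.8478
clopper_pearson,0.8,0.0175,0.010,0.9517,0.8544
clopper_pearson,0.8,0.0200,0.007,0.9513,0.8567
clopper_pearson,0.8,0.0200,0.008,0.9537,0.8593
clopper_pearson,0.8,0.0200,0.009,0.9537,0.8587
clopper_pearson,0.8,0.0200,0.010,0.9510,0.8530
clopper_pearson,0.8,0.0225,0.007,0.9494,0.8525
clopper_pearson,0.8,0.0225,0.008,0.9512,0.8427
clopper_pearson,0.8,0.0225,0.009,0.9512,0.8692
clopper_pearson,0.8,0.0225,0.010,0.9531,0.8606
clopper_pearson,0.9,0.0050,0.007,0.9529,0.9234
clopper_pearson,0.9,0.0050,0.008,0.9543,0.9112
clopper_pearson,0.9,0.0050,0.009,0.9522,0.9235
clopper_pearson,0.9,0.0050,0.010,0.9509,0.9280
clopper_pearson,0.9,0.0075,0.007,0.9521,0.9235
clopper_pearson,0.9,0.0075,0.008,0.9536,0.9140
clopper_pearson,0.9,0.0075,0.009,0.9507,0.9237
clopper_pearson,0.9,0.0075,0.010,0.9534,0.9086
clopper_pearson,0.9,0.0100,0.007,0.9500,0.9217
clopper_pearson,0.9,0.0100,0.008,0.9516,0.9107
clopper_pearson,0.9,0.0100,0.009,0.9527,0.9188
clopper_pearson,0.9,0.0100,0.010,0.9522,0.9350
clopper_pearson,0.9,0.0125,0.007,0.9492,0.9165
clopper_pearson,0.9,0.0125,0.008,0.9501,0.9263
clopper_pearson,0.9,0.0125,0.009,0.9547,0.9269
clopper_pearson,0.9,0.0125,0.010,0.9529,0.9185
clopper_pearson,0.9,0.0150,0.007,0.9493,0.9232
clopper_pearson,0.9,0.0150,0.008,0.9533,0.9284
clopper_pearson,0.9,0.0150,0.009,0.9535,0.9323
clopper_pearson,0.9,0.0150,0.010,0.9494,0.9385
clopper_pearson,0.9,0.0175,0.007,0.9492,0.9249
clopper_pearson,0.9,0.0175,0.008,0.9531,0.9355
clopper_pearson,0.9,0.0175,0.009,0.9505,0.9321
clopper_pearson,0.9,0.0175,0.010,0.9518,0.9307
clopper_pearson,0.9,0.0200,0.007,0.9477,0.9238
clopper_pearson,0.9,0.0200,0.008,0.9512,0.9402
clopper_pearson,0.9,0.0200,0.009,0.9486,0.9299
clopper_pearson,0.9,0.0200,0.010,0.9520,0.9336
clopper_pearson,0.9,0.0225,0.007,0.9530,0.9346
clopper_pearson,0.9,0.0225,0.008,0.9471,0.9380
clopper_pearson,0.9,0.0225,0.009,0.9478,0.9340
clopper_pearson,0.9,0.0225,0.010,0.9539,0.9347
clopper_pearson,0.9,0.0250,0.007,0.9511,0.9381
clopper_pearson,0.9,0.0250,0.008,0.9492,0.9371
clopper_pearson,0.9,0.0250,0.009,0.9504,0.9416
clopper_pearson,0.9,0.0250,0.010,0.9516,0.9316
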