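method,gamma,p,omega,coverage,assurance
analytic,0.5,0.0050,0.007,0.9550,0.4670
analytic,0.5,0.0050,0.008,0.9553,0.4323
analytic,0.5,0.0050,0.009,0.9590,0.4764
analytic,0.5,0.0050,0.010,0.9534,0.4543
analytic,0.5,0.0075,0.007,0.9530,0.4917
analytic,0.5,0.0075,0.008,0.9585,0.4782
analytic,0.5,0.0075,0.009,0.9534,0.4863
analytic,0.5,0.0075,0.010,0.9573,0.4613
analytic,0.5,0.0100,0.007,0.9512,0.4573
analytic,0.5,0.0100,0.008,0.9546,0.4713
analytic,0.5,0.0100,0.009,0.9508,0.4669
analytic,0.5,0.0100,0.010,0.9555,0.4546
analytic,0.5,0.0125,0.007,0.9508,0.4601
analytic,0.5,0.0125,0.008,0.9518,0.4973
analytic,0.5,0.0125,0.009,0.9551,0.4920
analytic,0.5,0.0125,0.010,0.9522,0.4787
analytic,0.5,0.0150,0.007,0.9497,0.4886
analytic,0.5,0.0150,0.008,0.9475,0.4731
analytic,0.5,0.0150,0.009,0.9527,0.4485
analytic,0.5,0.0150,0.010,0.9541,0.4614
analytic,0.5,0.0175,0.007,0.9513,0.4821
analytic,0.5,0.0175,0.008,0.9506,0.4696
analytic,0.5,0.0175,0.009,0.9533,0.4826
analytic,0.5,0.0175,0.010,0.9533,0.4895
analytic,0.5,0.0200,0.007,0.9525,0.4867
analytic,0.5,0.0200,0.008,0.9516,0.4835
analytic,0.5,0.0200,0.009,0.9539,0.4893
analytic,0.5,0.0200,0.010,0.9523,0.4826
analytic,0.5,0.0225,0.007,0.9483,0.4949
analytic,0.5,0.0225,0.008,0.9527,0.4878
analytic,0.5,0.0225,0.009,0.9458,0.5046
analytic,0.5,0.0225,0.010,0.9539,0.4850
analytic,0.5,0.0250,0.007,0.9527,0.5019
analytic,0.5,0.0250,0.008,0.9514,0.4907
analytic,0.5,0.0250,0.009,0.9481,0.4992
analytic,0.5,0.0250,0.010,0.9472,0.4725
analytic,0.8,0.0050,0.007,0.9521,0.7314
analytic,0.8,0.0050,0.008,0.9542,0.7523
analytic,0.8,0.0050,0.009,0.9546,0.7352
analytic,0.8,0.0050,0.010,0.9581,0.7334
analytic,0.8,0.0075,0.007,0.9546,0.7367
analytic,0.8,0.0075,0.008,0.9571,0.7324
analytic,0.8,0.0075,0.009,0.9549,0.7626
analytic,0.8,0.0075,0.010,0.9542,0.7191
analytic,0.8,0.0100,0.007,0.9509,0.7603
analytic,0.8,0.0100,0.008,0.9515,0.7573
analytic,0.8,0.0100,0.009,0.9534,0.7538
analytic,0.8,0.0100,0.010,0.9548,0.7743
analytic,0.8,0.0125,0.007,0.9489,0.7725
analytic,0.8,0.0125,0.008,0.9557,0.7594
analytic,0.8,0.0125,0.009,0.9495,0.7622
analytic,0.8,0.0125,0.010,0.9494,0.7653
analytic,0.8,0.0150,0.007,0.9511,0.7819
analytic,0.8,0.0150,0.008,0.9488,0.7704
analytic,0.8,0.0150,0.009,0.9525,0.7536
analytic,0.8,0.0150,0.010,0.9520,0.7839
analytic,0.8,0.0175,0.007,0.9521,0.7760
analytic,0.8,0.0175,0.008,0.9538,0.7781
analytic,0.8,0.0175,0.009,0.9499,0.7630
analytic,0.8,0.0175,0.010,0.9511,0.7678
analytic,0.8,0.0200,0.007,0.9484,0.7780
analytic,0.8,0.0200,0.008,0.9495,0.7692
analytic,0.8,0.0200,0.009,0.9507,0.7740
analytic,0.8,0.0200,0.010,0.9493,0.7522
analytic,0.8,0.0225,0.007,0.9491,0.7848
analytic,0.8,0.0225,0.008,0.9514,0.7636
analytic,0.8,0.0225,0.009,0.9541,0.7766
analytic,0.8,0.0225,0.010,0.9495,0.7656
analytic,0.9,0.0050,0.007,0.9535,0.8300
analytic,0.9,0.0050,0.008,0.9524,0.8007
analytic,0.9,0.0050,0.009,0.9551,0.7798
analytic,0.9,0.0050,0.010,0.9546,0.8127
analytic,0.9,0.0075,0.007,0.9504,0.8434
analytic,0.9,0.0075,0.008,0.9534,0.8537
analytic,0.9,0.0075,0.009,0.9527,0.8385
analytic,0.9,0.0075,0.010,0.9532,0.8301
analytic,0.9,0.0100,0.007,0.9502,0.8741
analytic,0.9,0.0100,0.008,0.9503,0.8686
analytic,0.9,0.0100,0.009,0.9521,0.8384
analytic,0.9,0.0100,0.010,0.9508,0.8583
analytic,0.9,0.0125,0.007,0.9534,0.8689
analytic,0.9,0.0125,0.008,0.9495,0.8672
analytic,0.9,0.0125,0.009,0.9539,0.8483
analytic,0.9,0.0125,0.010,0.9552,0.8580
analytic,0.9,0.0150,0.007,0.9476,0.8670
analytic,0.9,0.0150,0.008,0.9545,0.8722
analytic,0.9,0.0150,0.009,0.9510,0.8646
analytic,0.9,0.0150,0.010,0.9501,0.8677
analytic,0.9,0.0175,0.007,0.9515,0.8757
analytic,0.9,0.0175,0.008,0.9538,0.8682
analytic,0.9,0.0175,0.009,0.9543,0.8633
analytic,0.9,0.0175,0.010,0.9521,0.8570
analytic,0.9,0.0200,0.007,0.9490,0.8781
analytic,0.9,0.0200,0.008,0.9484,0.8723
analytic,0.9,0.0200,0.009,0.9487,0.8764
analytic,0.9,0.0200,0.010,0.9549,0.8644
analytic,0.9,0.0225,0.007,0.9490,0.8766
analytic,0.9,0.0225,0.008,0.9500,0.8767
analytic,0.9,0.0225,0.009,0.9520,0.8850
analytic,0.9,0.0225,0.010,0.9544,0.8744
analytic,0.9,0.0250,0.007,0.9522,0.8803
analytic,0.9,0.0250,0.008,0.9488,0.8671
analytic,0.9,0.0250,0.009,0.9543,0.8784
analytic,0.9,0.0250,0.010,0.9492,0.8698
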