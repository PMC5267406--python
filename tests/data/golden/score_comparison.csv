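variable,all_mean,all_sd,survivor_mean,survivor_sd,nonsurvivor_mean,nonsurvivor_sd,test,statistic,p_value
t0_respiratory,1.7916666666666667,0.9315329426211431,1.6363636363636365,1.12006493318265,1.9230769230769231,0.7595545253127499,t,0.7203299275292144,0.4810340407275476
t0_coagulation,0.08333333333333333,0.28232985128663995,0.18181818181818182,0.4045199174779452,0.0,0.0,t,-1.4907119849998602,0.16688959581639698
t0_liver,0.25,0.6079187588743288,0.18181818181818182,0.6030226891555273,0.3076923076923077,0.6304251719561151,t,0.4990063137275947,0.6228118261240507
t0_cardiovascular,0.5,1.06321906614239,0.5454545454545454,1.0357254813546264,0.46153846153846156,1.126601424298216,t,-0.18995761384057536,0.851098386003672
t0_cns,2.75,0.7939992333804207,2.727272727272727,1.009049958219026,2.769230769230769,0.5991446895152781,t,0.12103401287124305,0.9052003029030867
t0_renal,0.8333333333333334,1.0072203103706696,0.8181818181818182,1.0787197799411874,0.8461538461538461,0.9870962335856491,t,0.06579635630964419,0.948174914953021
t48_respiratory,1.7083333333333333,1.1220775245117838,1.0,1.0,2.3076923076923075,0.8548504142651103,t,3.409310834410777,0.0028019588074399016
t48_coagulation,0.16666666666666666,0.38069349381344053,0.0,0.0,0.3076923076923077,0.48038446141526137,t,2.3094010767585034,0.039519052319786474
t48_liver,0.20833333333333334,0.5089773777040516,0.0,0.0,0.38461538461538464,0.6504436355879909,t,2.1320071635561044,0.05436012321987263
t48_cardiovascular,0.7083333333333334,1.2676293062133797,0.2727272727272727,0.6466697906828633,1.0769230769230769,1.5525000516123697,t,1.7013745626324168,0.1075385880922386
t48_cns,2.7083333333333335,0.9078961186825509,2.1818181818181817,0.9816498172140427,3.1538461538461537,0.5547001962252291,t,2.91397568365985,0.010566826024042256
t48_renal,0.7916666666666666,0.7790276362049131,0.5454545454545454,0.8201995322647243,1.0,0.7071067811865476,t,1.4401481877945457,0.1653305338204345
t0_total,6.208333333333333,3.7761167846101493,6.090909090909091,4.085450904234328,6.3076923076923075,3.6602507970678593,t,0.13581012059520162,0.8933047385194903
t48_total,6.291666666666667,3.6532197432886,4.0,2.8635642126552705,8.23076923076923,3.1399003740523934,t,3.4499986651022017,0.0022983343960733043
mean_score,6.25,3.1484986069968124,5.045454545454546,3.387141460395074,7.269230769230769,2.6427210142151516,t,1.7690271719336048,0.09311153821071384
highest,7.583333333333333,4.095773714310958,6.090909090909091,4.085450904234328,8.846153846153847,3.804518231571374,t,1.6987088212028223,0.10432018682265441
delta,0.08333333333333333,3.944359392156444,-2.090909090909091,1.9725387425622574,1.9230769230769231,4.310095483504174,t,3.0063194602273535,0.007795482982261559
total_sum,12.5,6.296997213993625,10.090909090909092,6.774282920790148,14.538461538461538,5.285442028430303,t,1.7690271719336048,0.09311153821071384
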