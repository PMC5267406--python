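variable,all_mean,all_sd,survivor_mean,survivor_sd,nonsurvivor_mean,nonsurvivor_sd,test,statistic,p_value
age,41.62916666666667,16.520224210676272,39.69090909090909,16.472064506032908,43.26923076923077,17.047794804381816,t,0.5218285731622858,0.607106448714781
icu_los_days,6.32375,4.807408967235975,8.591818181818182,6.021957851366644,4.404615384615385,2.317540418146702,mann_whitney,34.0,0.032023404034938786
sex_male,0.5416666666666666,,0.36363636363636365,,0.6923076923076923,,chi_square,2.5925962149738364,0.10736421970055815
mechanically_ventilated,0.7083333333333334,,0.5454545454545454,,0.8461538461538461,,chi_square,2.607745195980489,0.10634286884008776
vasopressor_used,0.3333333333333333,,0.2727272727272727,,0.38461538461538464,,chi_square,0.33566433566433573,0.5623426051791448
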