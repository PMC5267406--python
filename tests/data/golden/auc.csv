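variant,auc,ci_low,ci_high,ci_method,comparison,comparison_p
initial,0.5419580419580419,0.27995207544591644,0.8039640084701674,delong,,
48h,0.846153846153846,0.6886287463237686,1.0,delong,,
mean,0.7132867132867133,0.4914915028216912,0.9350819237517355,delong,mean_vs_initial,0.010254632013005714
highest,0.6853146853146854,0.4590923229119096,0.9115370477174612,delong,,
delta,0.8531468531468531,0.6866640437135878,1.0,delong,,
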