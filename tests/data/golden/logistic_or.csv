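term,odds_ratio,ci_low,ci_high,p_value,coefficient,converged,separation,n_used
const,0.27847660193668805,0.01061908029070465,7.302818671979232,0.44306062647310696,-1.2784212377342108,True,False,24
initial,0.8793355787654352,0.6316305790001098,1.2241824347814048,0.4462180148293864,-0.1285886808143421,True,False,24
age,0.9893246412891475,0.9295133207555327,1.0529846361602826,0.7358749934366906,-0.010732749160518517,True,False,24
sex_male,5.244945582978327,0.6467787454269097,42.533021319749956,0.12068293914231949,1.6572648667664753,True,False,24
mechanically_ventilated,11.905051732660006,0.5669071056620227,250.00613917477932,0.11080449722997243,2.476962825385916,True,False,24
vasopressor_used,1.313643240603589,0.12212658276127236,14.130081466020709,0.821914139164169,0.2728043768079234,True,False,24
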