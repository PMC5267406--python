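patient_id,t0_respiratory,t0_coagulation,t0_liver,t0_cardiovascular,t0_cns,t0_renal,t48_respiratory,t48_coagulation,t48_liver,t48_cardiovascular,t48_cns,t48_renal,t0_total,t48_total,initial,at48,mean_score,highest,delta,total_sum,complete,missing_t0,missing_t48,age,sex,mechanically_ventilated,vasopressor_used,icu_los_days,outcome
P0001,2,0,0,2,3,0,1,0,0,0,2,1,7,4,7,4,5.5,7,-3,11,True,,,35.1,female,True,True,4.6,survived
P0002,1,0,0,0,2,0,3,0,0,3,4,1,3,11,3,11,7.0,11,8,14,True,,,59.4,female,True,True,3.13,died
P0003,2,0,0,0,3,1,3,0,0,4,3,1,6,11,6,11,8.5,11,5,17,True,,,42.2,female,True,True,4.65,died
P0004,2,0,0,3,4,2,2,0,0,0,2,2,11,6,11,6,8.5,11,-5,17,True,,,50.9,female,True,True,8.15,survived
P0005,1,0,0,0,1,0,0,0,0,0,1,0,2,1,2,1,1.5,2,-1,3,True,,,13.5,female,False,False,20.1,survived
P0006,1,0,0,0,2,0,1,0,0,0,2,0,3,3,3,3,3.0,3,0,6,True,,,13.5,male,False,False,3.59,died
P0007,2,0,0,1,3,1,3,0,0,0,3,2,7,8,7,8,7.5,8,1,15,True,,,26.2,female,True,False,1.89,died
P0008,0,0,0,0,2,0,0,0,0,0,1,0,2,1,2,1,1.5,2,-1,3,True,,,13.5,female,False,False,6.15,survived
P0009,1,0,0,0,2,0,1,0,0,0,2,0,3,3,3,3,3.0,3,0,6,True,,,51.2,female,False,False,6.09,survived
P0010,1,0,0,0,2,0,0,0,0,0,2,0,3,2,3,2,2.5,3,-1,5,True,,,55.4,male,False,False,3.27,survived
P0011,2,0,0,0,3,1,2,0,0,0,3,1,6,6,6,6,6.0,6,0,12,True,,,43.7,male,True,False,2.53,died
P0012,3,0,1,0,3,2,3,1,1,1,3,2,9,11,9,11,10.0,11,2,20,True,,,59.2,male,True,False,3.16,died
P0013,2,0,0,0,3,0,1,1,0,0,3,0,5,5,5,5,5.0,5,0,10,True,,,34.8,male,True,False,6.05,died
P0014,2,0,0,0,3,1,2,0,1,0,3,0,6,6,6,6,6.0,6,0,12,True,,,79.4,male,True,False,3.09,died
P0015,0,0,0,0,2,0,0,0,0,0,1,0,2,1,2,1,1.5,2,-1,3,True,,,47.8,male,False,False,18.3,survived
P0016,2,0,0,0,2,0,3,1,2,3,4,1,4,14,4,14,9.0,14,10,18,True,,,52.4,male,True,True,8.99,died
P0017,3,1,0,1,4,2,1,0,0,0,3,1,11,5,11,5,8.0,11,-6,16,True,,,23.4,male,True,False,1.98,survived
P0018,3,1,2,0,4,3,3,0,0,1,4,2,13,10,13,10,11.5,13,-3,23,True,,,40.3,female,True,False,13.46,survived
P0019,3,0,2,4,4,3,3,1,1,0,3,2,16,10,16,10,13.0,16,-6,26,True,,,46.6,female,True,True,3.5,died
P0020,3,0,1,1,3,2,3,0,0,0,4,1,10,8,10,8,9.0,10,-2,18,True,,,26.3,male,True,False,4.42,died
P0021,3,0,0,0,3,1,2,0,0,2,3,0,7,7,7,7,7.0,7,0,14,True,,,44.3,male,True,True,5.72,survived
P0022,1,0,0,0,2,0,2,0,0,3,3,1,3,9,3,9,6.0,9,6,12,True,,,41.0,male,True,True,3.09,died
P0023,2,0,0,0,3,1,1,0,0,0,3,0,6,4,6,4,5.0,6,-2,10,True,,,61.2,female,True,False,6.69,survived
P0024,1,0,0,0,3,0,1,0,0,0,3,1,4,5,4,5,4.5,5,1,9,True,,,37.8,male,False,False,9.17,died
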