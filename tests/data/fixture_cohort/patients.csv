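patient_id,age,sex,admission_source,admission_type,mechanically_ventilated,vasopressor_used,low_risk_monitoring,icu_los_days,outcome
P0001,35.1,female,obstetric_theatre,surgical,1,1,0,4.6,survived
P0002,59.4,female,surgical_ward,surgical,1,1,0,3.13,died
P0003,42.2,female,emergency_room,surgical,1,1,0,4.65,died
P0004,50.9,female,obstetric_gynecology_ward,surgical,1,1,0,8.15,survived
P0005,13.5,female,emergency_room,surgical,0,0,0,20.1,survived
P0006,13.5,male,emergency_room,surgical,0,0,0,3.59,died
P0007,26.2,female,pacu,surgical,1,0,0,1.89,died
P0008,13.5,female,other_hospital,medical,0,0,0,6.15,survived
P0009,51.2,female,obstetric_theatre,surgical,0,0,0,6.09,survived
P0010,55.4,male,obstetric_gynecology_ward,surgical,0,0,0,3.27,survived
P0011,43.7,male,operating_room,medical,1,0,0,2.53,died
P0012,59.2,male,obstetric_gynecology_ward,surgical,1,0,0,3.16,died
P0013,34.8,male,surgical_ward,surgical,1,0,0,6.05,died
P0014,79.4,male,medical_ward,surgical,1,0,0,3.09,died
P0015,47.8,male,surgical_ward,medical,0,0,0,18.3,survived
P0016,52.4,male,obstetric_gynecology_ward,surgical,1,1,0,8.99,died
P0017,23.4,male,emergency_room,medical,1,0,0,1.98,survived
P0018,40.3,female,medical_ward,surgical,1,0,0,13.46,survived
P0019,46.6,female,emergency_room,medical,1,1,0,3.5,died
P0020,26.3,male,obstetric_theatre,surgical,1,0,0,4.42,died
P0021,44.3,male,operating_room,surgical,1,1,0,5.72,survived
P0022,41.0,male,obstetric_theatre,surgical,1,1,0,3.09,died
P0023,61.2,female,pacu,medical,1,0,0,6.69,survived
P0024,37.8,male,pacu,surgical,0,0,0,9.17,died
D0001,52.5,male,surgical_ward,surgical,0,0,1,0.5,survived
D0002,54.1,female,medical_ward,surgical,0,0,1,0.71,survived
D0003,19.3,female,medical_ward,surgical,0,0,1,0.87,survived
D0004,42.2,male,surgical_ward,surgical,0,0,1,0.51,survived
D0005,38.4,female,obstetric_gynecology_ward,surgical,0,0,1,0.54,survived
D0006,37.8,female,pacu,surgical,0,0,1,0.65,survived
D0007,17.3,female,operating_room,surgical,0,0,1,0.59,survived
D0008,29.7,male,pacu,surgical,0,1,1,0.87,survived
D0009,22.6,female,medical_ward,medical,0,0,1,0.2,survived
D0010,33.3,male,surgical_ward,surgical,1,1,0,0.45,died
D0011,13.5,male,emergency_room,surgical,1,0,0,0.36,died
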