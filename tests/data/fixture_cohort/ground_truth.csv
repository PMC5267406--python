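patient_id,z0,z48,p_death,outcome,decoy
P0001,-0.08999602273800206,-0.8102553520488749,0.42989399321804217,0,
P0002,-0.29580286900905206,0.3750210492907473,0.38520580228231727,1,
P0003,0.5144959100367014,1.0998443228592931,0.565068660911243,1,
P0004,0.483724816177005,0.45669458560547327,0.5582505686879434,0,
P0005,-1.0980239766742013,-1.7935385786970075,0.23334679300276884,0,
P0006,-0.3301841102071101,-0.31095146643708027,0.37790430053786567,1,
P0007,0.49780540569814924,0.588123430914369,0.5613733548261302,1,
P0008,-1.5457353011887092,-1.7052490413467847,0.16903961590500405,0,
P0009,-0.3619622989626153,-0.9490229517877116,0.37120441663995446,0,
P0010,-0.7183691096315026,-1.5201404605380513,0.29989047810090835,0,
P0011,0.004915206312702013,0.3757178674583372,0.45094244347039764,1,
P0012,0.92663889778581,1.0037111509746686,0.6530986533432666,1,
P0013,-0.03431584476768419,-0.20358950272651077,0.4422164516104359,1,
P0014,0.2240715055770363,0.20863866485743338,0.500094276506598,1,
P0015,-1.0113766191341134,-1.8645387755060048,0.24758646604750909,0,
P0016,0.04346345160945222,1.036194151986816,0.4595460841791867,1,
P0017,0.8917712255273361,-0.43946118052643124,0.6459552368779503,0,
P0018,1.8834636039947803,0.9302048802507755,0.8166524380300987,0,
P0019,1.5527375743025507,0.9317121710047379,0.7678439179755105,1,
P0020,0.6926003405064647,0.36518093268191876,0.6039744239587232,1,
P0021,0.8283749066846373,0.14323657920986577,0.6328005598395767,0,
P0022,-0.6691967892871362,0.3261148856108427,0.30926358458701825,1,
P0023,0.0637919338571842,-0.6796524874787024,0.4640932902105217,0,
P0024,-1.064705045656817,-0.5691646893453349,0.2387541892510415,1,
D0001,-1.3412836451619414,-1.3412836451619414,,0,low_risk
D0002,-1.3267014971513227,-1.3267014971513227,,0,low_risk
D0003,-1.1340813659755655,-1.1340813659755655,,0,low_risk
D0004,-1.1660387052182284,-1.1660387052182284,,0,low_risk
D0005,-1.2863717648845574,-1.2863717648845574,,0,low_risk
D0006,-1.031670265279232,-1.031670265279232,,0,low_risk
D0007,-1.1492698651740068,-1.1492698651740068,,0,low_risk
D0008,-0.6987201536914269,-0.6987201536914269,,0,low_risk
D0009,-1.0621100466471083,-1.0621100466471083,,0,low_risk
D0010,1.4171472741450173,1.4171472741450173,,1,early_death
D0011,2.1890324279637694,2.1890324279637694,,1,early_death
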