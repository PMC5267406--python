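item,count
screened,35
enrolled,35
excluded_low_risk_monitoring,9
excluded_died_or_discharged_lt_24h,2
excluded_no_outcome,0
excluded_age_le_12,0
analyzed,24
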