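id,race,sex,age_years,height_m,weight_kg
1,Caucasian,male,72,1.75,59
2,Caucasian,male,53,1.70,70
3,Caucasian,female,57,1.64,57
4,Caucasian,male,76,1.73,96
5,Caucasian,female,78,1.68,48
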