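predictor	dataset	tp	tn	fp	fn
mitoclass1	validation	22	623	454	1
polyphen2	validation	21	514	563	2
polyphen2	full	54	1303	1475	3
provean	validation	21	650	427	2
provean	full	50	1646	1132	7
mutpred	validation	14	922	155	9
mutpred	full	33	2426	352	24
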