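base_id	name
atp	ATP
adp	ADP
amp	AMP
pi	Orthophosphate
ppi	Pyrophosphate
h	H+
h2o	H2O
co2	CO2
o2	O2
nad	NAD+
nadh	NADH
nadp	NADP+
nadph	NADPH
coa	Coenzyme A
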