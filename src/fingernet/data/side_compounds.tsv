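# Default side-compound (ubiquitous cofactor) list excluded from path-finding;
# BiGG-style base identifiers, matched case-insensitively against metabolite ids
# with and without compartment suffix. Edit freely.
network_id	name
h2o	water
h	proton
atp	ATP
adp	ADP
amp	AMP
nad	NAD+
nadh	NADH
nadp	NADP+
nadph	NADPH
co2	carbon dioxide
pi	phosphate
ppi	diphosphate
o2	oxygen
coa	coenzyme A
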