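# Curated metabolite name -> network species id (BiGG-style base ids, no compartment
# suffix) covering the discriminant metabolite names of the packaged shift tables.
# Names are matched case-insensitively. Isopropanol has no counterpart in the human
# reconstruction and is intentionally absent.
name	network_id
Alanine	ala_L
AMP	amp
Arginine	arg_L
Asparagine	asn_L
Citrate	cit
Creatine	creat
Dimethylglycine	dmgly
Glutamine	gln_L
Reduced glutathione	gthrd
Glycerol	glyc
Glycerophosphocholine	g3pc
Isoleucine	ile_L
Lactate	lac_L
Leucine	leu_L
Lysine	lys_L
Proline	pro_L
Serine	ser_L
Succinate	succ
Valine	val_L
Acetate	ac
Choline	chol
Ethanolamine	etha
Formate	for
Glucose	glc_D
Glutamate	glu_L
Glycine	gly
Phosphocholine	cholp
Tyrosine	tyr_L
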