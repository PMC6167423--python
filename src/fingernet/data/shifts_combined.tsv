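# Endogenous metabolite variations induced by BPA or 17beta-estradiol exposure (vs DMSO
# control) in HepG2 cells, from the joint 7-group comparison: 1H chemical shifts
# (ppm, multiplicity) and per-exposure-group discriminance flags.
metabolite	shifts	BPA_1e-6M	BPA_1e-9M	BPA_1e-12M	E2_1e-9M	E2_1e-12M	E2_1e-15M
Arginine	1.66(m); 1.74(m); 1.93(m); 3.25(t,6.9)	x	x	x	x	x	x
Asparagine	2.85(dd,16.8 and 7.4); 2.95(dd,16.8 and 4.3); 4.01(dd,7.4 and 4.3)				x
Choline	3.20(s); 3.52(m); 4.07(m)				x
Citrate	2.66(d,18.1); 2.81(d,18.1)	x		x
Creatine	3.04(s); 3.93(s)	x	x	x
Ethanolamine	3.14(m); 3.82(m)				x	x	x
Glutamate	2.06(m); 2.13(m); 2.35(m); 3.77(dd,7.5 and 4.9)				x	x
Glutamine	2.14(m); 2.46(m); 3.78(t,6.2)	x	x	x	x	x	x
Reduced glutathione	2.17(m); 2.56(m); 2.96(m); 3.78(m); 4.58(m)			x	x
Glycerophosphocholine	3.23(s); 3.62(m); 3.68(m); 3.89(m); 3.94(m); 4.33(m)					x	x
Glycine	3.55(s)				x
Isoleucine	0.94(t,7.4); 1.01(d,7); 1.27(m); 1.47(m); 1.98(m); 3.68(d,4)	x	x	x			x
Leucine	0.96(t,6.3); 1.71(m); 3.74(m)	x	x	x
Lysine	1.45(m); 1.52(m); 1.73(m); 1.91(m); 3.02(t,7.5)	x	x	x	x	x
Phosphocholine	3.22(s); 3.58(m); 4.17(m)				x	x
Proline	2.01(m); 2.08(m); 2.35(m); 3.35(m); 3.42(m); 4.14(dd,6.7 and 8.7)	x	x		x
Succinate	2.41(s)				x	x
Tyrosine	3.09(dd,14.5 and 7.5); 3.21(dd,14.5 and 5.1); 3.95(dd,7.5 and 5.1); 6.9(d,8.5); 7.20(d,8.5)			x	x
Valine	0.995(d,7); 1.045(d,7); 2.28(m); 3.62(d,4.4)	x	x	x	x
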