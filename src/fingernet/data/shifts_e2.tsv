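# Endogenous metabolite variations induced by 17beta-estradiol exposure (vs DMSO control)
# in HepG2 cells: 1H chemical shifts (ppm, multiplicity) and per-dose discriminance flags.
metabolite	shifts	E2_1e-9M	E2_1e-12M	E2_1e-15M
Acetate	1.91(s)		x	x
Alanine	1.48(d,7.2); 3.79(q,7.2)	x
Asparagine	2.85(dd,16.8 and 7.4); 2.95(dd,16.8 and 4.3); 4.01(dd,7.4 and 4.3)	x	x
Choline	3.20(s); 3.52(m); 4.07(m)	x	x	x
Citrate	2.66(d,18.1); 2.81(d,18.1)	x
Ethanolamine	3.14(m); 3.82(m)	x	x	x
Formate	8.45(s)		x	x
Glucose	3.25(dd,7.3 and 7.9); 3.42(m); 3.47(m); 3.51(m); 3.54(m); 3.72(m); 3.73(m); 3.77(m); 3.84(m); 3.90(m); 4.65(d,8); 5.24(d,3.8)	x
Glutamine	2.14(m); 2.46(m); 3.78(t,6.2)	x	x
Glutamate	2.06(m); 2.13(m); 2.35(m); 3.77(dd,7.5 and 4.9)	x	x
Reduced glutathione	2.17(m); 2.56(m); 2.96(m); 3.78(m); 4.58(m)	x
Glycerol	3.57(m); 3.66(m); 3.79(m)		x
Glycerophosphocholine	3.23(s); 3.62(m); 3.68(m); 3.89(m); 3.94(m); 4.33(m)		x	x
Glycine	3.55(s)	x
Isoleucine	0.94(t,7.4); 1.01(d,7); 1.27(m); 1.47(m); 1.98(m); 3.68(d,4)		x	x
Isopropanol	1.16(d,6.11); 4.01(m)		x	x
Lactate	1.33(d,6.9); 4.12(q,6.9)	x	x
Lysine	1.45(m); 1.52(m); 1.73(m); 1.91(m); 3.02(t,7.5)	x
Phosphocholine	3.22(s); 3.58(m); 4.17(m)	x	x
Proline	2.01(m); 2.08(m); 2.35(m); 3.35(m); 3.42(m); 4.14(dd,6.7 and 8.7)	x
Serine	3.84(m); 3.94(dd,12.4 and 5.8); 3.98(dd,12.4 and 3.7)		x
Succinate	2.41(s)		x
Tyrosine	3.09(dd,14.5 and 7.5); 3.21(dd,14.5 and 5.1); 3.95(dd,7.5 and 5.1); 6.9(d,8.5); 7.20(d,8.5)	x
Valine	0.995(d,7); 1.045(d,7); 2.28(m); 3.62(d,4.4)	x
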