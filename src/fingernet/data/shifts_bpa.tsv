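# Endogenous metabolite variations induced by BPA exposure (vs DMSO control) in HepG2 cells:
# 1H chemical shifts (ppm, multiplicity) and per-dose discriminance flags.
metabolite	shifts	BPA_1e-6M	BPA_1e-9M	BPA_1e-12M
Alanine	1.48(d,7.2); 3.79(q,7.2)		x
AMP	4.03(m); 4.38(m); 4.51(m); 6.14(d,5.9); 8.27(s); 8.61(s)			x
Arginine	1.66(m); 1.74(m); 1.93(m); 3.25(t,6.9)	x	x	x
Asparagine	2.85(dd,16.8 and 7.4); 2.95(dd,16.8 and 4.3); 4.01(dd,7.4 and 4.3)			x
Citrate	2.66(d,18.1); 2.81(d,18.1)		x	x
Creatine	3.04(s); 3.93(s)	x	x	x
Dimethylglycine	2.93(s)			x
Glutamine	2.14(m); 2.46(m); 3.78(t,6.2)	x	x	x
Reduced glutathione	2.17(m); 2.56(m); 2.96(m); 3.78(m); 4.58(m)			x
Glycerol	3.57(m); 3.66(m); 3.79(m)	x
Glycerophosphocholine	3.23(s); 3.62(m); 3.68(m); 3.89(m); 3.94(m); 4.33(m)	x
Isoleucine	0.94(t,7.4); 1.01(d,7); 1.27(m); 1.47(m); 1.98(m); 3.68(d,4)	x	x	x
Isopropanol	1.16(d,6.11); 4.01(m)		x
Lactate	1.33(d,6.9); 4.12(q,6.9)		x	x
Leucine	0.96(t,6.3); 1.71(m); 3.74(m)	x	x	x
Lysine	1.45(m); 1.52(m); 1.73(m); 1.91(m); 3.02(t,7.5)	x	x	x
Proline	2.01(m); 2.08(m); 2.35(m); 3.35(m); 3.42(m); 4.14(dd,6.7 and 8.7)	x	x
Serine	3.84(m); 3.94(dd,12.4 and 5.8); 3.98(dd,12.4 and 3.7)	x
Succinate	2.41(s)	x
Valine	0.995(d,7); 1.045(d,7); 2.28(m); 3.62(d,4.4)	x	x	x
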