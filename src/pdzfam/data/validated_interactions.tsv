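domain	peptide	svm_score	mdsm_score	pubmed_id
Cipp-(3/10)	IESDV	0.44	-0.7	9647694
Cipp-(3/10)	LESEV	0.30	-0.62	9647694
Cipp-(3/10)	QQSNV	0.29	-0.78	9647694
Cipp-(3/10)	KEYYV	0.51	-0.34	9647694
Dvl1-(1/1)	SETSV	-1.27	-0.74	12490194
Pdlim5-(1/1)	DITSL	-0.24	-0.15	10359609
Erbin-(1/1)	LDVPV	0.99	0.61	10878805
Magi-2-(5/6)	KESSL	1.76	0.19	10681527
MUPP1-(10/13)	IATLV	1.00	0.46	11000240
MUPP1-(10/13)	GKDYV	1.00	1.68	11689568
NHERF-1-(1/2)	FDTPL	1.06	0.01	10980202
LIN-7A-(1/1)	IESDV	0.33	0.29	10341223
Lin7c-(1/1)	IESDV	0.33	1.00	10341223
ZO-3-(1/3)	GKDYV	0.99	0.09	10601346
a1-syntrophin-(1/1)	VLSSV	-1.47	0.16	11571312
PSD95-(1/3)	LQTEV	0.38	1.41	11937501
PSD95-(1/3)	NETVV	-1.35	1.19	12067714
PSD95-(1/3)	GETAV	-1.32	1.23	12067714
PSD95-(1/3)	EESSV	-2.23	0.77	11134026
PSD95-(1/3)	RTTPV	1.00	0.61	12359873
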