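gene_symbol	description	cytoband	lnc_symbol	r	p_value	de_direction	de_contrast	note
FBXW7	F-box and WD repeat domain containing 7	4q31	RP11-588K22.2	0.42	0.016	DW	t(11;14)
CCND2	cyclin D2	12p13	CCND2-AS1	0.95	1.50E-16	DW	t(11;14)
CUL4A	cullin 4A	13q34	GAS6-AS2	0.45	0.011	DW	t(11;14)
CCR2	C-C motif chemokine receptor 2	3p21	RP4-555D20.2	0.63	1.22E-04	DW	t(11;14)
WWOX	WW domain containing oxidoreductase	16q23	RP11-679B19.1	0.53	0.002	DW	t(11;14)
WWOX	WW domain containing oxidoreductase	16q23	RP11-70D24.2	0.68	1.77E-05	DW	t(11;14)
MAF	MAF bZIP transcription factor	16q23	RP11-679B19.1	0.42	0.016	DW	t(11;14)
MAF	MAF bZIP transcription factor	16q23	RP11-70D24.2	0.63	1.27E-04	DW	t(11;14)
RELN	reelin	7q22	CTB-107G13.1	0.42	0.017	UP	t(11;14)
PIK3CG	phosphatidylinositol-4,5-bisphosphate 3-kinase catalytic subunit gamma	7q22	CTB-107G13.1	0.45	0.009	UP	t(11;14)
PAX5	paired box 5	9p13	EBLN3	0.59	4.27E-04	UP	t(11;14)
KREMEN2	kringle containing transmembrane protein 2	16p13	AC005606.14	0.53	0.002	UP	t(11;14)
CCL2	C-C motif chemokine ligand 2	17q12	RP11-848P1.5	0.46	0.008	UP	t(11;14)
STAT3	signal transducer and activator of transcription 3	17q21	RARA-AS1	0.52	0.002	UP	t(11;14)
RARA	retinoic acid receptor alpha	17q21	RARA-AS1	0.70	8.49E-06	UP	t(11;14)
PMAIP1	phorbol-12-myristate-13-acetate-induced protein 1	18q21	RP11-299P2.2	0.42	0.017	UP	t(11;14)
HGF	hepatocyte growth factor	7q21	AC006145.4	0.45	0.009	DW	t(4;14)
AKT1	AKT serine/threonine kinase 1	14q32	RP11-731F5.2	0.43	0.013	DW	t(4;14)
DNMT1	DNA methyltransferase 1	19p13	CTD-3214H19.6	0.41	0.021	DW	t(4;14)
CD81	CD81 molecule	11p15	RP11-326C3.2	0.70	9.41E-06	DW	t(4;14)
PTGS2	prostaglandin-endoperoxide synthase 2	1q31	GS1-115G20.1	0.71	5.05E-06	UP	t(4;14)
TNFRSF1A	TNF receptor superfamily member 1A	12p13	RP5-1063M23.2	0.80	4.32E-08	UP	t(4;14)
PAK2	p21 (RAC1) activated kinase 2	3q29	LMLN-AS1	0.49	0.005	UP	t(4;14)
ADAM9	ADAM metallopeptidase domain 9	8p11	RP11-350N15.6	0.44	0.013	UP	t(4;14)
DICER1	dicer 1, ribonuclease III	14q32	RP11-433J8.1	0.41	0.018	UP	t(4;14)
PTPN6	protein tyrosine phosphatase, non-receptor type 6	12p13	RP5-1063M23.2	0.94	2.00E-15	UP	t(4;14)
BCL9	B-cell CLL/lymphoma 9	1q21	RP11-196G18.22	0.67	2.58E-05	DW	HD
HIST2H3C	histone cluster 2 H3 family member c	1q21	RP11-196G18.22	0.53	0.002	DW	HD
ILF2	interleukin enhancer binding factor 2	1q21	ASH1L-AS1	0.59	3.52E-04	DW	HD
DEPTOR	DEP domain containing MTOR interacting protein	8q24	KB-1471A8.1	0.73	2.38E-06	DW	HD
P2RX7	purinergic receptor P2X 7	12q24	RP11-347I19.7	0.49	0.005	DW	HD
CIITA	class II major histocompatibility complex transactivator	16p13	RP11-490O6.2	0.61	2.10E-04	DW	HD
NES	nestin	1q23	RP11-404F10.2	0.41	0.020	DW	MAF trx
FCRL4	Fc receptor like 4	1q23	RP11-404F10.2	0.43	0.015	DW	MAF trx
DKK1	dickkopf WNT signaling pathway inhibitor 1	10q21	PRKG1-AS1	0.51	0.003	DW	MAF trx
MBL2	mannose binding lectin 2	10q21	PRKG1-AS1	0.71	5.70E-06	DW	MAF trx
NCAM1	neural cell adhesion molecule 1	11q23	RP11-629G13.1	0.53	0.002	DW	MAF trx
XPO1	exportin 1	2p15	RP11-373L24.1	0.46	0.009	DW	MAF trx
XPO1	exportin 1	2p15	RP11-568N6.1	0.53	0.00	DW	MAF trx	printed 0.00; <0.005 after rounding
IFNL1	interferon lambda 1	19q13	PCAT19	0.40	0.023	DW	MAF trx
TIMP1	TIMP metallopeptidase inhibitor 1	Xp11	RP6-99M1.3	0.50	0.003	DW	MAF trx
TIMP1	TIMP metallopeptidase inhibitor 1	Xp11	MIR222HG	0.46	0.009	DW	MAF trx
HAVCR2	hepatitis A virus cellular receptor 2	5q33	AC008697.1	0.47	0.007	UP	MAF trx
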