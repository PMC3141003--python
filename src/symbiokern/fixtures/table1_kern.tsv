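kern_id	av_cluster	protein_name	role	array_fold	qpcr_fold
1	av01015l05	Calumenin precursor (Calu-a)	Ca2+ binding	7.29
2	CL1319Ct1	Niemann Pick type C2 protein homolog (NPC2-D)	metabolism-FA	4.39	4.6
3	CL4283Ct1	Carbonic anhydrase 2 cytosolic (CA2-c)	pH homeostasis	4.06	13.2
4	CL363Ct1	Sym32	cell adhesion	3.36	47.8
5	CL263Ct1	Carbonic anhydrase 2 membrane (CA2-m)	pH homeostasis	2.90	8.6
6	av01009g10	Uromodulin domain (URO domain)	cell adhesion	2.66
7	av02058f16	Col protein	cell adhesion	2.53
8	av01002j09	Tyrosine kinase receptor (Tyr-K Receptor)	receptor signaling	2.35
9	av02120i19	Catenin delta	cell adhesion	2.17
10	CL1994Ct1	Mitochondrial fission 1 protein (FIS1)	vesicle	1.98
11	av02092k17	E3 ubiquitin-protein ligase RNF34	Ubiquitin pathway	1.87
12	CL3310Ct1	Secretory glutathione peroxidase	antioxidant	1.85
13	CL298Ct1	Lipid storage droplets surface-binding protein 2	metabolism-FA	1.82
14	av02096o03	Prolyl-4-hydroxylase-alpha	Collagen processing	1.82
15	av01005l13	2-hydroxyacyl-CoA lyase 1	metabolism-FA	1.81
16	av01017f01	Visinin-like protein 1	Ca2+ binding	1.79
17	av02097k23	Dehydrogenase/reductase_SDR family member 12	metabolism-FA	1.72
18	av01023c17	Ubiquitin thioesterase 34 (Ubiquitin hydrolase 34)	Ubiquitin pathway	1.71
19	CL187Ct1	Zona Pellucida-like domain-containing protein	cell adhesion	1.58
20	CL1460Ct1	Branched-chain-amino-acid aminotransferase	metabolism	-1.58
21	CL2889Ct1	E3 ubiquitin-protein ligase (parkin)	Ubiquitin pathway	-1.59
22	av01029c01	Trafficking protein particle complex I sub.2 (Sedlin)	vesicle	-1.60
23	CL2824Ct1	Trafficking protein particle complex II sub.10 (TMEM1)	vesicle	-1.63
24	CL829Ct1	Peroxidasin	antioxidant	-1.68
25	CL1127Ct1	STE20	ion transport	-1.69
26	CL2771Ct1	Voltage-gated Hydrogen channel 1 (HVCN1)	ion chanel	-1.74
27	av02120i05	Galaxin	cell adhesion	-1.76
28	CL240Ct1	Phosphoenolpyruvate carboxykinase (PEPCK-C)	metabolism	-1.81
29	av02125c09	Type III iodothyronine deiodinase	metabolism	-1.82
30	av02109e14	Polyamine oxidase	antioxidant	-1.83
31	av02115o13	Ataxia telangiectasia and Rad3 related (ATR)	DNA damage	-1.89
32	CL2461Ct1	Cullin family	Ubiquitin pathway	-1.90
33	av01046b22	pre-mRNA-splicing factor 18 (PRP18)	RNA processing	-2.02
34	av02084n10	Putative transposon-derived protein ReO_6	transposon	-2.12
35	av02100k07	Glutathione S-transferase Y1 (GST class-mu)	detoxification	-2.15
36	av02069c14	SLC30a2, Zinc transporter 2 (ZnT-2)	solute transporter	-2.24
37	av01039o13	C3-2 complement	cell adhesion	-2.25
38	CL627Ct1	AP-2 sigma-1	vesicle	-2.40
39	av02114d05	Notch-like family	cell adhesion	-4.60
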