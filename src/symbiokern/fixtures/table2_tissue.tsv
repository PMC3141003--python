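av_cluster	protein_name	role	kern_id	dual_deg	array_fold	qpcr_fold	tissue_array	tissue_qpcr
av01015l05	Calumenin precursor (AvCALUa)	Ca2+ binding	1	#	7.29		G
CL1014Ct1	Calumenin precursor (AvCALUb)	Ca2+ binding			1.15
CL101Ct1	Calumenin precursor (AvCALUc)	Ca2+ binding			-1.27
CL363Ct1	Sym32	cell adhesion	4	#	3.36	47.9	G	G
av02077g18	Periostin	cell adhesion			1.36
CL1319Ct1	Niemann Pick type C2 protein homolog NPC2-D	metabolism-FA	2	#	4.39	4.6	G	G
CL214Ct1	Niemann Pick type C2 protein homolog NPC2-a	metabolism-FA			-1.06
CL308Ct1	Niemann Pick type C1 protein homolog NPC1	metabolism-FA			1.13
CL263Ct1	Carbonic anhydrase 2 membrane (CA2-m)	pH regulation	5	#	2.90	8.6	G	G
CL4283Ct1	Carbonic anhydrase 2 cytosolic (CA2-c)	pH regulation	3		4.06	13.2		ge
av01043f14	Rh AG 1	solute transporter		#	1.58	4.4		G
av02095l23	Rh AG 2	solute transporter			1.11
CL506Ct1	C3-1 complement	cell adhesion			1.47	1.3		G
av01039o13	C3-2 complement	cell adhesion	35		-2.25
CL92Ct2	MERP-1	cell adhesion			-1.57
CL194Ct2	MERP-1	cell adhesion			-1.37		G
CL51Ct1	MERP-1	cell adhesion			-1.06		G
av02096o03	Prolyl-4-hydroxylase alpha	collagen processing	14	#	1.82		G
CL3699Ct1	Prolyl-4-hydroxylase alpha	collagen processing			-1.00		G
av02049b06	Procollagen lysine2 oxoglutarate 5 dioxygenase 3	collagen processing			1.24
av02062m24	Collagenase type IV	collagen processing			-1.08
CL143Ct1	Collagenase type IV	collagen processing			-1.39
CL38Ct2	Collagen-like	collagen precursor			-1.07		G
CL1481Ct1	Collagen-like	collagen precursor			-1.09		G
av01033k13	Collagen, type IX, alpha 1	collagen precursor			-1.10
av02101l17	Collagen like	collagen precursor			-1.26		G
CL2177Ct1	Collagen alpha-5(VI)	collagen precursor			1.20		G
av01030e14	Collagen alpha-2(V)	collagen precursor			-1.34		G
CL253Ct1	Collagen alpha-2(I)	collagen precursor			1.15		G
CL902Ct1	Collagen alpha-2(I)	collagen precursor			-1.06		G
CL2629Ct1	Collagen alpha-1(V)	collagen precursor			-1.03		G
CL635Ct1	Collagen alpha-1(V)	collagen precursor			-1.23		G
CL389Ct1	Collagen alpha-1(III)	collagen precursor			-1.19		G
CL4Ct6	Collagen alpha-1(II)	collagen precursor			-1.36		G
CL934Ct1	Col protein	collagen precursor			-1.02		G
av02058f16	Col-like protein	cell adhesion	7	#	2.53			G
av01028j14	Collagen triple helix repeat-containing protein 1	cell adhesion			-1.23		E
av01009g10	Uromodulin domain (URO domain)	cell adhesion	6	#	2.66		G
av02120i19	Catenin delta	cell adhesion	9	#	2.17		G
CL1994Ct1	Mitochondrial fission 1 protein (FIS1)	vesicle	10	#	1.98		G
av02071b13	Tousled-like kinase 1	cell cycle		#	1.82		G
CL3005Ct1	DNA repair protein RAD50	DNA damage		#	1.60		G
av02071o11	Cytoskeleton-associated protein 5 (TOG protein)	cytoskeleton		#	-1.52		G
av01002j09	Tyrosine kinase receptor (Tyr-K Receptor)	receptor signaling	8	#	2.35		E
av02074d19	Sulfuric ester hydrolases	hormone		#	1.63		E
CL2622Ct1	Predicted protein	receptor signaling		#	-1.59		E
CL3901Ct1	Hydroxymethylglutaryl-CoA reductase	metabolism-FA		#	-1.73		E
av01020d21	Carboxylesterase	metabolism-FA			-1.53	2.0		ge
CL450Ct1	Cold shock domain-containing protein E1 (UNR)	RNA processing			-1.70	-1.3		ge
CL1958Ct1	no hits found	predicted prot			-1.03	-1.9		ge
CL1127Ct1	STE20	ion transport	23		-1.69	-1.4		ge
CL612Ct1	GFP	GFP			1.23	1.5	E	E
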