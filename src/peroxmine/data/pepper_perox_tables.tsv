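# Peroxisomal proteins identified in sweet pepper (Capsicum annuum) fruit
# by ortholog confrontation of the iTRAQ whole-fruit proteome with the
# Arabidopsis peroxisomal reference list: matrix proteins with PTS, matrix
# proteins lacking PTS, and membrane-associated proteins (PMPs), with their
# ripening-stage regulation (log2FC = log2(red) - log2(green)).
protein_name	abbreviation	accession	pts_notation	compartment	log2FC	regulation
Alanine-glyoxylate aminotransferase	AGT	A0A1U8ESR9	SRI	matrix	1.396	UP
Probable acyl-CoA dehydrogenase	IBR3	A0A2G2ZKA1	AKL	matrix	1.376	UP
2-hydroxyacyl-CoA lyase	HPCL2	A0A1U8FNI1	HKN	matrix	1.109	UP
Acyl-coenzyme A oxidase 4	ACOX4	A0A1U8ERN1	SRL	matrix	0.906	UP
Monodehydroascorbate reductase 1	MDAR1	A0A1U8E6R6	SKI	matrix	0.972	UP
4-coumarate-CoA ligase 7	4CLL7	A0A2G2YHF4	SKL	matrix	0.793	UP
Carboxypeptidase	CP	A0A1U8H246	KNI	matrix	0.894	UP
Glutamate-glyoxylate aminotransferase 2	GGAT2	A0A1U8EMR4	SRM	matrix	0.884	UP
Enoyl-CoA hydratase 2	ECH2	A0A1U8F2R5	SSL	matrix	0.595	UP
Glutathione reductase	GR2	A0A1U8G435	TNL	matrix	0.459	UP
Superoxide dismutase [CuZn]	SOD	A0A1U8EPJ0	SSV	matrix	0.655	UP
Amine oxidase	AOX	A0A1U8EUZ0	AKL	matrix	0.374	UP
Probable acetyl-CoA acetyltransferase	THIC2	A0A1U8GL52	SSL	matrix	1.302	UP
Hydroxypyruvate reductase	HPR	A0A1U8DY61	SKL	matrix	NA	NONE
Sulfite oxidase	SO	A0A2G3ACR2	ANL	matrix	NA	NONE
3-hydroxyacyl-CoA dehydrogenase	HADH	A0A1U8EU39	SRL	matrix	NA	NONE
Dienoyl-CoA isomerase	DCI	A0A2G3ACC8	AKL	matrix	NA	NONE
4-coumarate-CoA ligase 5	4CLL5	A0A2G2YA92	SKL	matrix	NA	NONE
Acyl-coenzyme A oxidase 1	ACOX1	A0A2G3AEV5	ARL	matrix	NA	NONE
Zinc-binding alcohol dehydrogenase domain-containing protein 2	ZBADH	A0A1U8DX36	AKL	matrix	NA	NONE
Insulin-degrading enzyme-like 1	IDE1	A0A1U8GL11	VKL	matrix	-1.689	DOWN
NADP-isocitrate dehydrogenase	ICDH	A0A2G2Y555	PKI	matrix	-1.373	DOWN
6-phosphogluconate dehydrogenase 2	6PGDH2	A0A1U8F1E8	SKI	matrix	-0.017	DOWN
Isopentenyl-diphosphate isomerase	IDI2	A0A2G2ZKS5	HKL	matrix	-1.543	DOWN
(S)-2-hydroxy-acid oxidase	HAO	A0A1U8EZL8	PRL	matrix	-0.638	DOWN
NADH:ubiquinone reductase	NDB1	A0A1U8EN49	SRI	matrix	-1.147	DOWN
Isopentenyl-diphosphate isomerase	IDI1	A0A2G2Y814	HKL	matrix	-1.206	DOWN
Methyltetrahydropteroyltriglutamate-homocysteine S-methyltransferase	METE1	A0A1U8F6S1	SAK	matrix	-0.899	DOWN
Urate oxidase	UO	A0A2G2Y6K0	SNM	matrix	-1.889	DOWN
Acyl-CoA thioesterase 2	ACTES	A0A1U8E2R5	PKL	matrix	-0.319	DOWN
4-coumarate-CoA ligase 4	4CLL4	A0A2G3AFX5	SKL	matrix	NA	NONE
12-oxophytodienoate reductase 3	OPR3	A0A1U8H923	SRL	matrix	NA	NONE
Probable 6-phosphogluconolactonase 4	6PGL4	A0A1U8FYP2	SKL	matrix	NA	NONE
Uncharacterized protein	UP3	A0A2G2Z370	ASL	matrix	NA	NONE
Catalase 2	CAT2	A0A1U8FMA2	QKL (internal)	matrix	-1.102	DOWN
Catalase 3	CAT3	A0A1U8GAA6	QKL (internal)	matrix	-1.374	DOWN
Acyl-coenzyme A oxidase 3	ACOX3	A0A1U8ENR3	RIx5HL	matrix	0.786	UP
Malate dehydrogenase	PMDH	A0A1U8FSV3	RIx5HL	matrix	1.333	UP
3-ketoacyl-CoA thiolase 2	ACAA1	A0A2G2ZTY4	RQx5HL	matrix	2.402	UP
Mevalonate kinase	MKV	A0A1U8GJW7	DVx5QM	matrix	NA	NONE
Citrate synthase	CISY2	A0A1U8FK78	RLx5HL	matrix	NA	NONE
Long chain acyl-CoA synthetase 6	ACLS	A0A2G2Y0B5	RLx5HL	matrix	NA	NONE
Hydroxyisourate hydrolase	HSH	A0A2G3ALZ5	RVx5HL	matrix	NA	NONE
14 kDa zinc-binding protein	ZBP	A0A1U8F6W1	RLx5HF	matrix	NA	NONE
Serine/threonine-protein phosphatase 2A	STP2A	A0A1U8EKG3	-	matrix	1.531	UP
Serine/threonine-protein phosphatase	STP	A0A2G2YDX1	-	matrix	NA	NONE
Probable sarcosine oxidase	PIPOX	A0A1U8F0Q0	-	matrix	-0.644	DOWN
Nucleoside diphosphate kinase	NDK1	A0A2G3AM91	-	matrix	-0.456	DOWN
Glyoxalase 1	GLX1	A0A2G3A977	-	matrix	-0.915	DOWN
Peroxisome biogenesis protein 19	PEX19	A0A2G3AER5	-	membrane	1.084	UP
Fission 1 protein	FP1	A0A1U8FBV7	-	membrane	0.669	UP
ABC transporter D 1	ABCD1	A0A2G2Y840	-	membrane	0.724	UP
Peroxin 4	PEX4	A0A1U8EYW8	-	membrane	NA	NONE
Peroxisome biogenesis protein 22	PEX22	A0A1U8F7K6	-	membrane	NA	NONE
L-ascorbate peroxidase 5	APX5	A0A2G2Y2S6	-	membrane	NA	NONE
Ras-related protein RABE1C	RABE1C	A0A1U8GLM9	-	membrane	NA	NONE
Dehydroascorbate reductase 2	DAR2	A0A1U8GZY4	-	membrane	-0.662	DOWN
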