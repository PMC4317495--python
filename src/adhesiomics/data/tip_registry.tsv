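gene	protein_name	alias	identified	fold_or_U
ARHGEF2	Rho/rac guanine nucleotide exchange factor 2	GEF-H1	1	4.3
BCAS2	Pre-mRNA-splicing factor SPF27	DAM1	1	1.9
CDK5RAP2	CDK5 regulatory subunit-associated protein 2	CEP215	1	U
CKAP5	Cytoskeleton-associated protein 5	Ch-TOG, XMAP215	1	3.4
CLASP1	Cytoplasmic linker-associated protein 1	CLIP-associating protein 1, hOrbit1	1	5.1
CLASP2	Cytoplasmic linker-associated protein 2	CLIP-associating protein 2, hOrbit2	1	U
DCTN1	Dynactin subunit 1	p150-glued	1	1.6
DIAPH1	Protein diaphanous homologue 1	DRF1, mDia	1	2.5
DST	Dystonin	BPA	1	U
DYNC1H1	Cytoplasmic dynein 1 heavy chain 1	-	1	3.1
KIF18B	Kinesin-like protein KIF18B	-	1	U
KIF2C	Kinesin-like protein KIF2C	MCAK	1	1.4
MACF1	Microtubule-actin crosslinking factor 1	ABP620, ACF7	1	8.0
MAPRE1	Microtubule-associated protein RP/EB family member 1	EB1	1	1.7
MAPRE2	Microtubule-associated protein RP/EB family member 2	EB2	1	3.6
APC	Adenomatous polyposis coli protein	-	0
CLIP1	CAP-Gly domain-containing linker protein 1	CLIP-170	0
KIF17	Kinesin-like protein KIF17	-	0
KIF2B	Kinesin-like protein KIF2B	-	0
KNSTRN	Small kinetochore-associated protein	SKAP	0
MAPRE3	Microtubule-associated protein RP/EB family member 3	EB3	0
MLPH	Melanophilin	-	0
MTUS2	Microtubule-associated tumour suppressor candidate 2	TIP150	0
MYO5A	Unconventional myosin-Va	-	0
NAV1	Neuron navigator 1	-	0
PAFAH1B1	Platelet-activating factor acetylhydrolase IB subunit alpha	LIS1	0
PSRC1	Proline/serine-rich coiled-coil protein 1	DDA3	0
SLAIN2	SLAIN motif-containing protein 2	-	0
SPAG5	Sperm-associated antigen 5	Astrin	0
SRCIN1	SRC kinase signalling inhibitor 1	p140Cap	0
STIM1	Stromal interaction molecule 1	-	0
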