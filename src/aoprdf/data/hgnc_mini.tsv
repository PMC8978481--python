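hgnc_id	symbol	name	alias_symbol	alias_name
HGNC:7	A2M	alpha-2-macroglobulin	FWP007	
HGNC:395	ALAD	aminolevulinate dehydratase	ALADH	porphobilinogen synthase
HGNC:399	ALB	albumin gene product		
HGNC:613	APOE	apolipoprotein E	AD2	
HGNC:1100	BRCA1	BRCA1 DNA repair associated	RNF53	breast cancer 1 gene
HGNC:1101	BRCA2	BRCA2 DNA repair associated	FANCD1	breast cancer 2 gene
HGNC:1516	CAT	catalase enzyme gene		
HGNC:1504	CASP3	caspase 3	CPP32	apopain protease
HGNC:1784	CDKN1A	cyclin dependent kinase inhibitor 1A	p21	
HGNC:2595	CYP1A1	cytochrome P450 family 1 subfamily A member 1	CP11	
HGNC:2596	CYP1A2	cytochrome P450 family 1 subfamily A member 2	CP12	
HGNC:2631	CYP2E1	cytochrome P450 family 2 subfamily E member 1	CYP2E	
HGNC:3236	EGFR	epidermal growth factor receptor	ERBB1	
HGNC:3467	ESR1	estrogen receptor 1	NR3A1	
HGNC:4638	GSTP1	glutathione S-transferase pi 1	GST3	
HGNC:14726	HDAC9	histone deacetylase 9	HDAC7B	histone deacetylase 9 enzyme
HGNC:5013	HMOX1	heme oxygenase 1	HO-1	
HGNC:5992	IL1B	interleukin 1 beta	IL1F2	
HGNC:6018	IL6	interleukin 6	IFNB2	B cell stimulatory factor 2
HGNC:6204	JUN	Jun proto-oncogene	AP-1	
HGNC:23177	KEAP1	kelch like ECH associated protein 1	INrf2	
HGNC:6775	MAA	melanoma associated antigen gene		
HGNC:6871	MAPK1	mitogen-activated protein kinase 1	ERK2	
HGNC:7553	MYC	MYC proto-oncogene	c-Myc	
HGNC:7782	NFE2L2	NFE2 like bZIP transcription factor 2	NRF2	
HGNC:2874	NQO1	NAD(P)H quinone dehydrogenase 1	DIA4	DT-diaphorase enzyme
HGNC:270	PARP1	poly(ADP-ribose) polymerase 1	ADPRT	
HGNC:9232	PPARA	peroxisome proliferator activated receptor alpha	NR1C1	
HGNC:9236	PPARG	peroxisome proliferator activated receptor gamma	NR1C3	
HGNC:9353	PRDX2	peroxiredoxin 2	TDPX1	thiol-specific antioxidant protein
HGNC:9605	PTGS2	prostaglandin-endoperoxide synthase 2	COX2	cyclooxygenase 2 enzyme
HGNC:9955	RELA	RELA proto-oncogene NF-kB subunit	p65	
HGNC:11179	SOD1	superoxide dismutase 1	ALS1	
HGNC:11180	SOD2	superoxide dismutase 2	MnSOD	manganese superoxide dismutase
HGNC:11289	SREBF1	sterol regulatory element binding transcription factor 1	SREBP1	
HGNC:11364	STAT3	signal transducer and activator of transcription 3	APRF	
HGNC:11766	TGFB1	transforming growth factor beta 1	TGFB	
HGNC:11892	TNF	tumor necrosis factor	TNFA	tumor necrosis factor alpha
HGNC:11998	TP53	tumor protein p53	p53	Li-Fraumeni syndrome gene
HGNC:12435	TXN	thioredoxin gene product	TRX	
HGNC:12591	UROD	uroporphyrinogen decarboxylase	UPD	
HGNC:12680	VEGFA	vascular endothelial growth factor A	VEGF	vascular permeability factor
HGNC:12805	XDH	xanthine dehydrogenase	XO	xanthine oxidase enzyme
HGNC:348	AHR	aryl hydrocarbon receptor	bHLHe76	dioxin receptor protein
HGNC:7968	NR1I2	nuclear receptor subfamily 1 group I member 2	PXR	pregnane X receptor
HGNC:7969	NR1I3	nuclear receptor subfamily 1 group I member 3	CAR1	constitutive androstane receptor
HGNC:40	ABCB1	ATP binding cassette subfamily B member 1	MDR1	multidrug resistance protein 1
HGNC:119	ACOX1	acyl-CoA oxidase 1	PALMCOX	
HGNC:3594	FASN	fatty acid synthase	OA-519	
HGNC:2328	CPT1A	carnitine palmitoyltransferase 1A	CPT1	
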