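fragment_id	target_name	category	text
72	FTL	DNA_RNA	In our patients with undetectable serum ferritin levels, idiopathic generalized seizures, and atypical RLS, we screened all exons encoding the FTL gene for neuroferritinopathy-associated mutations. As a result, we detected a G > T nucleotide substitution (G310T) in exon 3.
1	DOCK8	DNA_RNA	Combined immunodeficiency associated with DOCK8 mutations.
3	IL23R	DNA_RNA	A genome-wide association study identifies IL23R as an inflammatory bowel disease gene.
153	GLI2	DNA_RNA	We describe three novel heterozygous frameshift or nonsense GLI2 mutations, predicting truncated proteins lacking the activator domain associated with IGHD or combined pituitary hormone deficiency and ectopic posterior pituitary lobe without HPE. In addition, the GLI2 coding region of patients with isolated GH deficiency (IGHD) or combined pituitary hormone deficiency was amplified by PCR using intronic primers and sequenced.
90	IDH2	DNA_RNA	Subsequent studies revealed that IDH mutations were extremely rare in primary (de novo) glioblastomas but were common in recurrent glioblastomas developing secondary to low-grade tumors, which frequently have IDH mutations. These findings suggested that IDH mutations are an early event in gliomagenesis and persist during the progression to recurrent glioblastomas. In addition, somatic heterozygous IDH1 or IDH2 mutations have frequently been detected in glioma/glioblastomas by genome-wide mutation searches.
184	SRPK1	PROTEIN	Lysates were separated by SDS-PAGE, transferred to nitrocellulose, and subjected to Western blot analysis using anti-SRPK1 (A), anti-SRPK2 (B), anti-topoisomerase I: arthritis foundation/CDC reference sera (C), and anti-cdc2 (CDK1) (mouse monoclonal) (D).
152	Spexin	PROTEIN	Spexin is a Novel Human Peptide that Reduces Adipocyte Uptake of Long Chain Fatty Acids and Causes Weight Loss in Rodents with Diet-induced Obesity Spexin is a novel human peptide that reduces adipocyte uptake of long-chain fatty acids and causes weight loss in rodents with diet-induced obesity. Spexin is a novel hormone involved in weight regulation, potentially for obesity therapy. A commercial immunoassay allowed us to examine possible relationships between circulating levels of Spexin and those of known obesity-related adipokines in human sera.
123	GGA2	PROTEIN	As recent studies have shown GGA1 and GGA3 protein level alterations in postmortem samples of AD patients, we also compared the expression of GGA2 in 26 temporal lobe samples obtained from control and AD patients. Some AD patients showed altered GGA2 levels compared with matched controls. (D) GGA2 levels were analyzed by Western blot in postmortem temporal lobe samples of AD and controlled patients (MADRC).
97	NBS1	PROTEIN	To test whether NBS1 indeed interacts with the mTOR/Rictor/SIN1 complex, co-immunoprecipitation assays using extracts from a lung cancer cell line H1299 were used.
43	prostatic acid phosphatase	PROTEIN	In semen, proteolytic peptide fragments from prostatic acid phosphatase can form amyloid fibrils termed SEVI (semen-derived enhancer of viral infection).
44	FIT2	METABOLITE	Miranda et al found that mice with adipose-specific FIT2 deficiency developed severe, progressive lipodystrophy with fatty liver, tissue macrophage infiltration, and insulin resistance, with few but abnormally large lipid droplets on histology.
19	CCDC3	METABOLITE	Thus, we decided first to determine if CCDC3 could affect lipid metabolism in hepatic cancer cells by performing a metabolomics analysis.
108	alpha-N-acetylgalactosaminidase	METABOLITE	The degradation of blood group glycolipid A-6-2 (GalNAc(alpha1-->3)[Fuc alpha1-->2]Gal(beta1-->4)GlcNAc(beta1-->3)Gal(beta1-->4)Glc(beta1-->1')Cer, IV2-alpha-fucosyl-IV3-alpha-N-acetylgalactosaminylneolactotetraosylceramide), tritium-labeled in its ceramide moiety, was studied in situ, in skin fibroblast cultures from normal controls, from patients with defects of lysosomal alpha-N-acetylgalactosaminidase, and patients with other lysosomal storage diseases.
84	NNMT	METABOLITE	To address this problem, we employed an untargeted metabolomics approach, where metabolomes from NNMT-OE and GFP-OE renal carcinoma (769P), ovarian cancer (OVCAR3), and melanoma (MUM2C) cells were comparatively analyzed by an HPLC-Q-TOF-MS system operating in the broad mass scanning mode (m/z range of 50-1200 Da).
167	DDHD2	METABOLITE	In line with the function of DDHD2 in lipid metabolism and its role in the CNS, an abnormal lipid peak indicating accumulation of lipids was detected with cerebral magnetic resonance spectroscopy, which provides an applicable diagnostic biomarker that can distinguish the DDHD2 phenotype from other complex HSP phenotypes.
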