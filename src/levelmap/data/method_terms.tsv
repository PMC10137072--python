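term	category	whole_word_only	source_group
gene	DNA_RNA	false	Genomics and Nucleic Acid Analysis
genome	DNA_RNA	false	Genomics and Nucleic Acid Analysis
genome-wide association	DNA_RNA	false	Genomics and Nucleic Acid Analysis
genotyping	DNA_RNA	false	Genomics and Nucleic Acid Analysis
mutation	DNA_RNA	false	Genomics and Nucleic Acid Analysis
exon	DNA_RNA	false	Genomics and Nucleic Acid Analysis
intron	DNA_RNA	false	Genomics and Nucleic Acid Analysis
nucleotide	DNA_RNA	false	Genomics and Nucleic Acid Analysis
oligonucleotide	DNA_RNA	false	Genomics and Nucleic Acid Analysis
polymerase chain reaction	DNA_RNA	false	Genomics and Nucleic Acid Analysis
pcr	DNA_RNA	false	Genomics and Nucleic Acid Analysis
rt-pcr	DNA_RNA	false	Genomics and Nucleic Acid Analysis
primer	DNA_RNA	false	Genomics and Nucleic Acid Analysis
sequencing	DNA_RNA	false	Genomics and Nucleic Acid Analysis
dna	DNA_RNA	true	Genomics and Nucleic Acid Analysis
rna	DNA_RNA	true	Genomics and Nucleic Acid Analysis
mrna	DNA_RNA	false	Genomics and Nucleic Acid Analysis
cdna	DNA_RNA	false	Genomics and Nucleic Acid Analysis
transcript	DNA_RNA	false	Genomics and Nucleic Acid Analysis
transcription	DNA_RNA	false	Genomics and Nucleic Acid Analysis
hybridization	DNA_RNA	false	Genomics and Nucleic Acid Analysis
microarray	DNA_RNA	false	Genomics and Nucleic Acid Analysis
northern blot	DNA_RNA	false	Genomics and Nucleic Acid Analysis
southern blot	DNA_RNA	false	Genomics and Nucleic Acid Analysis
polymorphism	DNA_RNA	false	Genomics and Nucleic Acid Analysis
snp	DNA_RNA	true	Genomics and Nucleic Acid Analysis
allele	DNA_RNA	false	Genomics and Nucleic Acid Analysis
replication	DNA_RNA	false	Genomics and Nucleic Acid Analysis
gag	DNA_RNA	true	Genomics and Nucleic Acid Analysis
knockout	DNA_RNA	false	Genomics and Nucleic Acid Analysis
sirna	DNA_RNA	false	Genomics and Nucleic Acid Analysis
plasmid	DNA_RNA	false	Genomics and Nucleic Acid Analysis
cloning	DNA_RNA	false	Genomics and Nucleic Acid Analysis
western blot	PROTEIN	false	Immunoanalytical methods
immunoblot	PROTEIN	false	Immunoanalytical methods
immunoassay	PROTEIN	false	Immunoanalytical methods
radioimmunoassay	PROTEIN	false	Immunoanalytical methods
ria	PROTEIN	true	Immunoanalytical methods
elisa	PROTEIN	false	Immunoanalytical methods
immunoprecipitation	PROTEIN	false	Immunoanalytical methods
immunohistochemistry	PROTEIN	false	Immunoanalytical methods
immunofluorescence	PROTEIN	false	Immunoanalytical methods
immunostaining	PROTEIN	false	Immunoanalytical methods
antibody	PROTEIN	false	Immunoanalytical methods
monoclonal	PROTEIN	false	Immunoanalytical methods
sds-page	PROTEIN	false	Proteomics
electrophoresis	PROTEIN	false	Proteomics
proteomics	PROTEIN	false	Proteomics
proteome	PROTEIN	false	Proteomics
peptide	PROTEIN	false	Proteomics
mass spectrometry	PROTEIN	false	Proteomics
flow cytometry	PROTEIN	false	Immunoanalytical methods
enzyme assay	PROTEIN	false	Enzymatic methods
kinase assay	PROTEIN	false	Enzymatic methods
metabolomics	METABOLITE	false	Metabolomics
metabolome	METABOLITE	false	Metabolomics
metabolite profiling	METABOLITE	false	Metabolomics
magnetic resonance spectroscopy	METABOLITE	false	Metabolomics
lipidomics	METABOLITE	false	Lipidomics
lipidome	METABOLITE	false	Lipidomics
lipids	METABOLITE	false	Lipidomics
lipid droplets	METABOLITE	false	Lipidomics
sphingolipid	METABOLITE	false	Lipidomics
triglyceride	METABOLITE	false	Lipidomics
cholesterol	METABOLITE	false	Lipidomics
glycolipid	METABOLITE	false	Glycomics
glycomics	METABOLITE	false	Glycomics
glycome	METABOLITE	false	Glycomics
glycan	METABOLITE	false	Glycomics
carbohydrate	METABOLITE	false	Glycomics
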