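BLAST
R
Gene Ontology
GenBank
ClustalW
ClustalX
Clustal W	ClustalW
Clustal X	ClustalX
MUMmer
Vmatch
MUSCLE
Ensembl
KEGG
PDB
MySQL
GEO
RefSeq
SCOP
Pfam
PubMed
Swiss-Prot
SwissProt	Swiss-Prot
UniProt
TrEMBL
Bioconductor
MEDLINE
MeSH
Galaxy
HMMER
SAMtools
BWA
Bowtie
TopHat
Cufflinks
EMBOSS
T-Coffee
MAFFT
PhyML
RAxML
MrBayes
PHYLIP
Cytoscape
BioPerl
Biopython
InterPro
PROSITE
dbSNP
OMIM
Reactome
STRING
Taverna
WEKA
MEME
Primer3
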