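DNA
RNA
PCR
GO
SNP
EST
ORF
UTR
ATP
NADH
HIV
AIDS
BMI
ANOVA
CI
SD
SE
CPU
RAM
XML
HTML
HTTP
FTP
URL
API
GUI
SQL
CSV
TSV
PDF
ID
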