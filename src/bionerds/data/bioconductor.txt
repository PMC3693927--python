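affy
limma
aCGH
graph
ROC
edgeR
DESeq
Biostrings
GenomicRanges
vsn
marray
siggenes
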