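# bionerds

Rule-based named-entity recognition of **bioinformatics database and
software names** in full-text articles, plus the evaluation and
literature-survey machinery that turns per-document annotations into
usage statistics.

Resource names ("BLAST", "Gene Ontology", "ClustalW", ...) are central
to computational biology, but they are hard to catalogue: new tools
appear constantly, many names are ambiguous English words ("analysis",
"Network") or collide with acronyms and identifiers ("GO" inside
`GO:001234`), and most resources are mentioned once and never again.
This package is aimed at text-mining practitioners and bioinformatics
methodologists who want to extract resource mentions from article
collections and analyse how resource usage changes over time.

## The method

Each document passes through a scoring pipeline:

1. **Preprocessing** — tokenisation, sentence splitting,
   part-of-speech tagging (a pluggable tagger contract with a bundled
   deterministic heuristic tagger).
2. **Dictionary lookup** — case-sensitive longest-match tagging against
   a resource-name dictionary (Bioconductor names carry an extra
   homonymy penalty).
3. **Candidate generation** — maximal noun-only token runs, merged with
   the dictionary matches.
4. **Local clues** — each candidate accumulates positive evidence
   (title pattern `Name: a <keyword> ...`, Hearst patterns
   (`tools such as X or Y`), enumerations containing a dictionary name,
   descriptor head nouns, trailing version numbers, citations, URLs,
   helpful casing) and negative evidence (English words, known
   acronyms, blacklisted heads such as `format`/`algorithm`,
   lower-case, partial-word matches).  The mention score is

       score = Σ clue scores + (# distinct positive clue types) × 0.50

5. **Cross-mention weak clues** — ambiguous indicators (`use`, `ran`,
   `platform`, ...) are tallied per name over the whole document;
   `tally × 0.50` is added to every mention of that name.
6. **Threshold and propagation** — mentions scoring strictly above
   **+5.00** are accepted, and every verbatim occurrence of an accepted
   surface in the document is tagged, yielding the document-level
   resource list.

Evaluation uses precision, recall and F-measure
(`F = 2PR/(P+R)`) at mention and document level, with strict (exact
offsets) and lenient (any overlap, one-to-one) matching.  The survey
layer computes yearly relative usage, the variation statistic
`ΣΔ = Σ_y |x_{y+1} − x_y|`, Gaussian random-walk envelopes
(`kμ ± 2σ√k`), long-tail summaries and cross-journal overlap.

See `docs/methods.md` for the full model description and design notes.

## Worked example

```python
from bionerds import Document, annotate_document

doc = Document(
    "demo",
    "FooTool: a database for sequence comparison",
    "We applied FooTool 2.3 [7] to the data. "
    "Alignment tools such as MUMmer or Vmatch were also used. "
    "FooTool is discussed further below.",
)
result = annotate_document(doc)
for m in result.mentions:
    print(m.start, m.end, m.surface, round(m.score, 2), m.propagated)
```

prints

```
0 7 FooTool 6.0 False
55 62 FooTool 6.5 False
108 114 MUMmer 16.0 False
118 124 Vmatch 14.5 False
141 148 FooTool 6.5 True
```

The title mention of `FooTool` scores 6.00 (Title +4.00, MixedCase
+1.00, two distinct positive clues × 0.50), above the +5.00 threshold;
the body mention adds Version and Reference evidence.  `MUMmer` and
`Vmatch` combine dictionary, Hearst and enumeration clues.  The final
bare `FooTool` carries no local clues at all — it is tagged by
document-level propagation (`propagated=True`), which is what keeps
recall high in articles that mention one tool many times.

The same pipeline is scriptable from the shell:

```sh
bionerds synth --out corpus/ --seed 7          # synthetic fixture corpus
bionerds annotate corpus/*.txt --out-mentions m.tsv --out-lists lists.json
bionerds evaluate --gold corpus/gold.tsv --pred m.tsv --level mention --mode lenient
bionerds survey --lists lists.json --metadata corpus/metadata.csv --resource FooTool
```

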