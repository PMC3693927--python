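# Methods

This note documents the recognition model, its parameters, the
synthetic study corpus, and the design decisions taken where the
design was genuinely open.

## The recognition model

The recogniser treats resource-name detection as evidence
accumulation over candidate spans rather than classification.  Two
observations motivate the design: resource names in bioinformatics
prose are almost always contiguous runs of nouns, and no dictionary
stays complete in a field that mints new tools continuously.  The
pipeline therefore combines a case-sensitive dictionary with
rule-based clues that can promote unknown names above an acceptance
threshold.

**Candidates.**  Maximal noun-only token runs (Penn tags NN/NNS/NNP/
NNPS) within a sentence, merged with dictionary matches.  Runs longer
than 6 tokens are discarded as improbable names (configurable
constant); runs consisting solely of descriptor keywords ("software
tools") are descriptors, not names, and are dropped.  A trailing
descriptor keyword, blacklisted head or weak head is trimmed from the
run ("The PolyFreq *program*" → candidate `PolyFreq`), feeding the
good-head / negative-head / weak logic respectively.

**Local scores.**  Each clue type fires at most once per candidate.
Defaults (all tunable via a flat `key = value` config file):

| clue | score | | clue | score |
|---|---|---|---|---|
| Dictionary | +5.50 | | Bioconductor | −1.75 |
| Title | +4.00 | | DictionaryWord | −4.00 |
| Hearst | +4.00 | | KnownAcronym | −15.00 |
| Enum | +3.00 | | NegativeHead | −15.00 |
| Version | +3.00 | | PartialWord | −15.00 |
| GoodHead | +2.00 | | LowerCase | −1.00 |
| HyperLink | +1.50 | | | |
| Reference | +1.00 | | CompoundFactor | +0.50 |
| MixedCase | +1.00 | | Weak | +0.50 |
| UpperCase | +0.50 | | threshold | +5.00 |

The compound bonus counts **distinct positive clue types** (not
firings) and excludes the weak clue, which has its own cross-mention
stage.  The −15 penalties are deliberately unrecoverable at the
default threshold: a candidate firing only `KnownAcronym` would need
more than 40 weak firings to pass.

**Cross-mention weak clues.**  A weak firing is a weak-indicator
token (verbs like *use*, *ran*, *develop*; heads like *interface*,
*platform*) within 4 tokens of a candidate inside one sentence.
Firings are tallied per normalised name over the whole document and
`tally × 0.50` is added to *every* mention of that name — weak
evidence is only convincing in aggregate.

**Threshold and propagation.**  Acceptance is *strictly greater than*
+5.00.  Overlapping accepted spans resolve to the highest score
(ties: longer span, then leftmost).  Accepted surfaces are propagated:
every verbatim, case-sensitive, token-boundary occurrence in the
document becomes a mention carrying the accepting name's best score.
Propagation is what recovers clue-less mentions in articles focused on
one tool; it trades a small precision risk for a large recall gain.

## Preprocessing choices

The tokeniser is an explicit rule set: punctuation separates, except
version-like digit strings (`2.0`, `v1.2.3`) and URLs, which stay
atomic — the version and hyperlink clues need them whole.  Alnum/punct
boundaries split identifiers so the `GO` of `GO:001234` is its own
token and can be caught by the partial-word filter.  Sentence
boundaries require terminal punctuation followed by whitespace and a
capital, which suppresses splits after "ver." and similar; the title
is always its own sentence so the title clue can address it.

Tagging is a contract (surfaces in, Penn tags out), so any external
tagger can be injected.  The bundled heuristic tagger needs no model
files: a closed-class word list, then orthographic rules (all-caps,
internal capitals and digit-bearing tokens → NNP), then suffix rules,
then a plain-noun default.  Its job is not general-purpose accuracy
but keeping verbs, determiners and frequent adjectives out of noun
runs; unknown lowercase words defaulting to NN errs toward candidate
generation, which the negative clues then police.

## Lexicons

Seven lists drive the system.  The bundled fixtures (~55 resource
names, ~12 Bioconductor packages, ~200 English words, ~30 acronyms,
keyword/blacklist/weak lists) are small, but the file formats are the
interface: full-scale lists are drop-in replacements.  Resource and
acronym lookups are case-sensitive; English words, keywords, heads and
weak indicators are case-insensitive.  Dictionary tagging is
left-to-right longest match on token boundaries, so `Gene Ontology`
pre-empts its `Gene` prefix.

## Evaluation conventions

Mention-level lenient matching is one-to-one: pairs are matched
greedily by largest overlap, ties leftmost, so one long prediction
cannot satisfy two gold mentions.  Document-level comparison operates
on normalised name sets, case-sensitive in strict mode and
case-insensitive in lenient mode.  Zero denominators yield 0 scores.
Name normalisation maps dashes to spaces and collapses whitespace
(`Clustal-W` ≡ `Clustal W`), preserving case within a document;
survey-level grouping additionally case-folds.

## Survey statistics

Relative usage is the fraction of a year's documents mentioning a
resource (mention-level counts are also available).  The variation
statistic ΣΔ sums absolute year-over-year changes; missing years count
as zero.  For trend testing, year-over-year changes of Year-0
normalised usage are pooled across resources, a Gaussian step
(μ, σ, sample statistics with ddof=1) is fitted, and the 95% envelope
at step k is `kμ ± 2σ√k` — the cumulative variance of a random walk.
A flat `kμ ± 2σ` variant is kept behind a flag because per-step bounds
are also a defensible reading; √k scaling is the default since it is
the variance law of the walk itself.  Figure-style normalisation
("top-50") divides each resource-year count by that year's total over
the top-N set.

## The synthetic corpus

The generator plants names in exactly the clue contexts the recogniser
is built around — title pattern, Hearst lists beside a dictionary
name, version + citation, URL, weak-verb sentences, plus one bare
mention reachable only through propagation — alongside distractors the
negative clues must reject (English words, acronyms, an identifier
prefix).  The default spec uses 12 documents over 8 recipes (three
names from the bundled dictionary, five novel), years 2004–2011 across
two journals, and 5 distractor types; each recipe's clue combination
was chosen to clear the +5.00 threshold through a *different* evidence
path (title alone, dictionary alone, Hearst+Enum, URL+weak, ...), so
end-to-end recovery exercises every scoring route.  A seeded PRNG
makes the corpus byte-reproducible.

What passing on this corpus shows: the clue rules, scoring arithmetic,
weak aggregation, thresholding and propagation interact correctly and
deterministically.  What it does not show: robustness to real article
noise — OCR artefacts, references sections, tables, coordination
("Clustal W and X"), acronym-definition patterns, or the long-tail
ambiguity of genuine prose.  Real-corpus performance is expected to be
substantially lower than the fixture's near-perfect scores, and the
published experience with full-text journals (F-measures in the
0.6–0.9 range depending on corpus) remains the realistic reference
point.

## Numerical and degenerate-input conventions

Scores are plain floats; clue sums are small and order-independent.
Empty documents produce empty token/sentence/candidate lists, not
errors.  Duplicate lexicon variants are deduplicated with a warning.
`sigma_delta` requires a ≥2-year range; the random-walk fit requires
≥2 change observations; long-tail statistics reject an empty count
table.  Multi-token candidates take the majority casing class, with
ties yielding no case clue.

## Known limitations

- The heuristic tagger's noun default over-generates candidates in
  prose with rare lowercase vocabulary; negative clues compensate but
  precision on unusual text depends on the English list's coverage.
- Hearst/enumeration detection chains candidates separated only by
  commas and conjunctions; elliptical coordination and nested lists
  are not reconstructed.
- Head detection is shallow (adjacent-token), not syntactic; a
  dependency-parsed head could differ in long noun phrases.
- Acronym-variant linking beyond dash/whitespace normalisation is out
  of scope, so `GO` and `Gene Ontology` are distinct names at the
  survey level.
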