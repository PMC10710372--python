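# tblat

Token-level, BLAST-inspired alignment for recognizing ontology concepts in
noisy (typo-laden) clinical text.

Instead of comparing characters, `tblat` decomposes tokens into overlapping
3-mers and scores a possibly misspelled query token against an ontology
vocabulary token by summing, position by position, the probabilities of
3-mer *transitions* learned from a corpus of canonical/typo token pairs.
Transitions missing from the matrix are filled by a penalty that combines
the relative frequency of the implied error category (shift, single/double
replacement, gap shift, inversion, other) with the source 3-mer's identity
value. A raw score is interpreted through the candidate token's own score
distribution — the multiset of all attainable sums — and accepted when it
clears a length-dependent percentile cut-off (40th percentile for lengths
5–8, 55th for 9, 70th from 10 up; tokens of length 3–4 match exactly only).
Concept linkage then requires the content tokens of at least one label or
exact synonym to be covered by the resolved span tokens, order-insensitive.

## Layout

| module | role |
| --- | --- |
| `tblat.textprep` | tokenization, punctuation cleansing, stop-word removal |
| `tblat.kmers` | 3-mer decomposition, transition alignment, error taxonomy |
| `tblat.matrix` | build/prune/save/load the 3-mer transition scoring matrix |
| `tblat.align` | token-level alignment score with penalty fallback |
| `tblat.scorespace` | per-token score distributions, percentiles, cut-off policy |
| `tblat.lexicon` | OBO / OBO-graph JSON loading, token + 3-mer inverted index |
| `tblat.recognize` | span-to-concept entity linkage and sliding-window annotation |
| `tblat.synthetic` | seed-deterministic typo generators and pair-corpus oracle |
| `tblat.evaluate` | precision / recall / F1 against gold annotations |

A small phenotype-style ontology fixture (`tblat/data/toy.obo`), a default
English stop-word list and a worked-example scoring matrix ship with the
package, so the full pipeline runs without any downloads.

## CLI

```bash
# learn a scoring matrix from canonical<TAB>typo pairs
tblat build-matrix --pairs pairs.tsv --prune 0.01 --out matrix.tsv

# score one token pair (value, coverage, percentile)
tblat score --matrix matrix.tsv --candidate abnormal --query abnrmal

# annotate free text / link pre-delimited spans
tblat annotate --text note.txt --ontology hp.obo --matrix matrix.tsv \
               --root HP:0000118 --out annotations.tsv
tblat link --spans spans.tsv --ontology hp.obo --matrix matrix.tsv --out pred.tsv

# evaluate against gold (doc_id, start, end, concept_id TSV)
tblat evaluate --pred pred.tsv --gold gold.tsv --mode mention

# generate length-banded synthetic typos (1 error below length 10,
# 3 for 10-17, 4 from 18)
tblat gen-typos --tokens tokens.txt --seed 42 --out typos.tsv
```

## Python API sketch

```python
from tblat import (build_matrix, profile_errors, load_ontology, Recognizer)
from tblat.kmers import TokenPairCorpus

corpus = TokenPairCorpus.from_file("pairs.tsv")
matrix = build_matrix(corpus, prune_threshold=0.01)
lexicon = load_ontology("hp.obo", root_filter="HP:0000118")
rec = Recognizer(lexicon, matrix, profile=profile_errors(corpus))
rec.link_span("Abnormal urinary ackylglycine profile")
# Annotation(concept_id='HP:0012073', match_type='FUZZY', ...)
```
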