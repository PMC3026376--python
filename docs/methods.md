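# Methods note

## Model and procedure

`goeffects` scores a differential-expression gene set against user-chosen
Gene Ontology (GO) hypothesis terms. Inputs are an OBO ontology, gene → GO
annotations (GAF or a simple id-map table), a gene-expression table, and a
list of hypothesis terms (free text or pre-bound `.hgt` files of GO ids).

1. **Hypothesis binding.** A free-text phrase is Porter-stemmed token by
   token and matched conjunctively against a single field of each
   non-obsolete GO term: all stems must occur (as stem-prefixed substrings)
   in the same field. Fields are ranked name > synonym > definition; hits
   are returned sorted by (field rank, GO id). The user selects or edits
   the bound ids; the `.hgt` file records the final binding.
2. **Effect matching.** For gene *G* with annotated ids *A(G)* and
   hypothesis *H* with ids *I(H)*, the matched ids are
   *I(H) ∩ ({a} ∪ ancestors(a))* for each *a ∈ A(G)*, where ancestors are
   taken over `is_a` and `part_of` edges. This is the true path rule: an
   annotation to a term entails annotation to all of its ancestors. Matches
   are found by breadth-first search upward; the minimal edge depth per
   (gene term, matched term) pair is recorded and duplicate pairs are
   dropped.
3. **Sign parsing.** The gene's own term name (the most specific one) is
   parsed for direction cues on tokens split at whitespace, hyphens,
   underscores and slashes: whole tokens *positive, pro, stimulates,
   upregulates* → +1 and *negative, anti, suppresses, inhibits,
   downregulates* → −1, plus stem prefixes *increas-, stimulat-,
   upregulat-* → +1 and *decreas-, suppress-, inhibit-, downregulat-* → −1.
   The leftmost cue in the name wins. Token anchoring prevents false fires
   such as "anti" inside "antigen presentation". If the gene term name
   carries no cue, the matched (more general) term name is tried; names
   with no cue at all are *unsigned*.
4. **Resolution.** Unsigned effects become 0 or +1 per `unsigned_policy`.
   A gene matching a hypothesis through both +1 and −1 effects is a
   *conflict*, resolved per `conflict_policy`. Genes with no annotations at
   all, or no match to a hypothesis, yield *undefined* cells that are
   excluded from all sums.
5. **Quantification.** The qualitative matrix QL (genes × hypotheses, values
   in {+1, −1, 0, undefined}) is multiplied element-wise by the gene
   expression vector GE to give QT. Per hypothesis: pro = Σ QT over
   positive cells, anti = Σ QT over negative cells, net = pro + anti. The
   net values are drawn as a green (net > 0) / red (net < 0) bar chart.
6. **Manual curation.** An edits file (gene, hypothesis, value ∈ {−1,0,1})
   overrides QL cells before quantification; edits clear any conflict flag
   and the last edit for a cell wins. Edited and conflicted cells are
   marked in the output tables.

## Assumptions

- Expression values are on (or convertible to) a log₂ scale where positive
  means up-regulated; fold changes are converted with log₂ and must be > 0.
- GO term names encode effect direction lexically; this is a heuristic and
  is why per-cell manual edits exist.
- `NOT`-qualified GAF rows are negative assertions and are dropped (the
  gene itself is retained, so it appears as an annotated gene with no
  usable ids rather than an unknown one).
- Annotations to obsolete or unknown GO ids are dropped with a warning;
  `alt_id`s are resolved to their primary id.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `unsigned_policy` | `positive` | A gene annotated to a process without a direction cue most often participates in, and thus promotes, that process; `no_effect` (→ 0) is the conservative alternative. |
| `conflict_policy` | `positives_override` | Matches the default used in the benchmark; `negatives_override` and `greater_of` (count comparison, tie → 0) are available. |
| `sign_from` | `original` | The gene's own term is the most specific biological statement; `matched` reads the sign from the hypothesis-side term instead. |
| `traverse_regulates` | `False` | "X regulates Y" does not imply "X is (part of) Y", so `regulates` edges break the true path rule for effect direction; enabling them trades precision for recall. |
| `max_depth` | `None` | Unlimited ancestor traversal; a bound exists for very deep ontologies and skipped paths are warned about. |

## Synthetic data

The toy generator (`goeffects.synthetic`) emulates only the *structure* the
pipeline consumes: a rooted DAG of `n_process_terms` processes, each with an
`is_a` chain "regulation of X" ← "positive/negative regulation of X" (a
`signed_fraction` of processes get the signed pair), GAF 2.2 annotations of
`n_genes` genes to leaf terms, and seeded log₂ expression ratios. It does
not emulate real GO topology (depth, fan-out, cross-links), realistic
annotation sparsity, evidence-code distributions, or expression-value
distributions from any platform; results on toy data exercise correctness,
not biology.

All randomness goes through `random.Random(seed)`; outputs, including the
SVG chart (fixed `svg.hashsalt`, date metadata stripped), are
byte-deterministic for a given seed.

## Numerical and formatting choices

- Table values are written with `%.12g`, so summary rows re-derived from the
  written table match the in-memory sums.
- `greater_of` ties resolve to 0 (equal evidence both ways).
- Conflict cells render as `+1/-1` in the qualitative table; undefined cells
  render empty.
- Matching records minimal depth and deduplicates (gene term, matched term)
  pairs, so a diamond in the DAG contributes one effect, not two.

## Benchmark

The packaged study fixture holds qualitative effects of nine cytokines on
eight immunological hypothesis terms, called both from GO annotations (G)
and manually by an immunologist (M). With unit gene weights and the default
policies, the G matrix reproduces per-hypothesis pro/anti/net sums and
agrees with the expert matrix in net direction on 6 of 8 hypotheses (75%),
disagreeing on Antigen Presentation and Apoptosis.

## Limitations

- Sign parsing is lexical; terms whose direction is implicit in biology but
  not in the name are unsigned, and unusual phrasings can be missed.
- A single qualitative value per (gene, hypothesis) discards magnitude and
  context of individual annotations; conflicts are resolved by policy, not
  evidence weighting.
- The net effect is a sum of signed expression changes, not a statistic: no
  null model or significance is attached, by design — this is a
  hypothesis-scoring tool, not an enrichment test.
- Hypothesis binding searches one ontology field at a time; phrases whose
  words are split across name and synonym will not bind automatically.

## Problem sizes exercised

The test suite runs the matcher against 100+ random DAGs of up to 50 terms
(brute-force transitive-closure oracle), conservation and linearity
properties on matrices up to 20 genes × 50 hypotheses, Porter-stemmer
word/stem pairs frozen from the published algorithm's reference behaviour,
and the full nine-gene × eight-hypothesis benchmark end to end.
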