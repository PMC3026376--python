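# goeffects

Hypothesis-driven analysis of differential gene-expression datasets with the
Gene Ontology (GO).

Most GO tooling is discovery-oriented: enrichment analysis asks *which* GO
categories are over- or under-represented in a gene list. `goeffects`
answers the converse, hypothesis-driven question: **given biological process
terms I chose up front — apoptosis, chemotaxis, angiogenesis — does my gene
set, with its measured expression changes, push each process up or down, and
by how much?** This works even for hypotheses touched by only a handful of
genes, where enrichment statistics have no power, and it uses the
quantitative expression values rather than term counts.

It is aimed at molecular biologists analysing differential-expression
experiments (microarray, RNA-seq, proteomics) who already have a statistical
gene list and want a functional, directional readout against their own
hypotheses.

## The model

For genes *G₁…Gₙ* (with normalised expression changes *GEᵢ*, log₂ scale:
positive = up-regulated) and hypothesis terms *H₁…Hₘ* (each bound to a set
of GO ids):

1. **Matching.** Each GO id annotated to *Gᵢ* is matched against the GO ids
   of *Hⱼ*, exactly or through any ancestor along `is_a`/`part_of` edges —
   valid by the GO's *true path rule* (a term's annotation implies all of
   its ancestors).
2. **Sign parsing.** Each matched term's name is parsed for direction cues:
   *positive, pro, stimulates, increases/d, upregulates* → **+1**;
   *negative, anti, suppresses, inhibits, decreases/d, downregulates* →
   **−1**; otherwise the term is *unsigned* and a user policy assigns 0 or
   +1.
3. **Resolution.** The multiset of effects for the pair (*Gᵢ*, *Hⱼ*)
   collapses to a qualitative value QLᵢⱼ ∈ {+1, −1, 0, *undefined*}; genes
   carrying both +1 and −1 (context-dependent biology) are resolved by a
   policy — positives override, negatives override, or the greater count.
4. **Summarising.** QTᵢⱼ = QLᵢⱼ · GEᵢ, and per hypothesis
   *Nⱼ* = Σᵢ QTᵢⱼ (with pro = Σ QT>0 and anti = Σ QT<0, so
   N = pro + anti). *Nⱼ* is the net, expression-weighted effect of the whole
   dataset on *Hⱼ*, also drawn as a green/red bar chart.

Free-text hypothesis terms are bound to GO ids by a Porter-stemmed substring
search over GO names, synonyms and definitions ("inflammation" → stem
"inflamm" → matches "inflammatory response"), and every automatic call can
be overridden through an edits file.

## Worked example

The packaged benchmark scores nine cytokine genes (IL-2 … TGFb) against
eight immunological hypothesis terms, and compares the GO-derived calls (G)
with an immunologist's manual calls (M):

```bash
python examples/04_cytokine_benchmark.py
```

```
hypothesis               pro  anti   net
TH2                        5     0     5
Antigen Presentation       0    -1    -1
Chemotaxis                 7     0     7
Metastasis                 6     0     6
Angiogenesis               6     0     6
T Cell Activation          4    -1     3
Cell Proliferation         6    -3     3
Apoptosis                  7    -1     6

net-direction agreement with the expert matrix: 75%
disagreeing hypothesis terms: Antigen Presentation, Apoptosis
```

Each `net` is the signed sum of resolved per-gene effects on that
hypothesis at unit gene weight: the cytokine set strongly promotes
chemotaxis (+7) and has a small net negative call on antigen presentation
(−1). Six of eight hypothesis directions agree with the expert; the two
exceptions trace to +1/−1 annotation conflicts resolved upward by the
positives-override policy and to expert knowledge not yet captured in GO
annotations.

Other entry points: `examples/01_sign_parsing.py` (name → sign),
`examples/02_true_path_matching.py` (ancestor matching),
`examples/03_full_pipeline.py` (toy end-to-end run), and the `goeffects`
CLI (`run`, `build-hgt`, `edit`, `plot`, `fixtures`, `benchmark`
subcommands) for shell use.

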