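"""Matching gene annotations against hypothesis GO ids via the true path rule.

A gene annotated to "negative regulation of apoptosis" is, by the true path
rule, also annotated to every ancestor of that term — so it matches a
hypothesis pinned to the more general "regulation of apoptosis", and the
sign is read from the gene's own (most specific) term name.
"""

from goeffects import ScoringConfig, match_effects
from goeffects.hypothesis import HypothesisTerm
from goeffects.ontology import parse_obo
from goeffects.synthetic import toy_apoptosis_obo

dag = parse_obo(toy_apoptosis_obo())

hypothesis = HypothesisTerm("apoptosis regulation", ["GO:0042981"])
gene_annotations = ["GO:0043066"]  # negative regulation of apoptosis

elist = match_effects(dag, gene_annotations, hypothesis, ScoringConfig())
for rec in elist:
    print(
        f"gene term {rec.gene_go_id} matched hypothesis id {rec.matched_go_id} "
        f"at depth {rec.depth} with sign {rec.sign}"
    )

# depth 1: one generalisation step was needed; the sign -1 comes from the
# word "negative" in the gene's own term name, which the more general
# matched term no longer carries.
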