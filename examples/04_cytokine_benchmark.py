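"""The nine-cytokine benchmark: tool-derived vs expert effect calls.

The packaged fixture holds qualitative effects of nine cytokines on eight
immunological hypothesis terms, called twice: from GO annotation matching
(G) and by an immunologist from the literature (M).  We resolve conflicts
with positives-override, weight every gene equally, and compare the net
effect direction per hypothesis.
"""

from goeffects import ScoringConfig, agreement_score, cytokine_study, summarize_study
from goeffects.study import disagreeing_terms

study = cytokine_study()
cfg = ScoringConfig(conflict_policy="positives_override", unsigned_policy="positive")

print(f"{'hypothesis':22s} {'pro':>5s} {'anti':>5s} {'net':>5s}")
qs = summarize_study(study, "G", cfg)
for hyp in qs.hypotheses:
    print(
        f"{hyp:22s} {qs.pro_sum[hyp]:5g} {qs.anti_sum[hyp]:5g} {qs.net[hyp]:5g}"
    )

score = agreement_score(study, cfg)
print(f"\nnet-direction agreement with the expert matrix: {score:g}%")
print(f"disagreeing hypothesis terms: {', '.join(disagreeing_terms(study, cfg))}")

# 75% agreement = 6 of 8 terms point the same way; the two disagreements
# (apoptosis, antigen presentation) trace to conflicting annotations that
# positives-override resolves upward and to expert knowledge not yet
# captured in GO annotations.
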