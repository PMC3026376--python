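"""End-to-end run on generated toy data.

Builds a small ontology with signed regulation branches, annotates a few
genes to its leaves, draws seeded log2 expression ratios, and runs the full
analysis: hypothesis search, effect matching, conflict resolution and the
quantitative summary.
"""

import tempfile
from pathlib import Path

from goeffects import PipelineConfig, run_pipeline
from goeffects.synthetic import (
    ToySpec,
    generate_toy_annotations,
    generate_toy_expression,
    generate_toy_ontology,
    toy_dag,
)

spec = ToySpec(seed=7, n_process_terms=3, signed_fraction=1.0, n_genes=5)

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    (root / "toy.obo").write_text(generate_toy_ontology(spec))
    (root / "toy.gaf").write_text(generate_toy_annotations(toy_dag(spec), spec))
    (root / "expr.csv").write_text(generate_toy_expression(spec))
    (root / "hyp.txt").write_text("process_1\nprocess_2\nprocess_3\n")

    paths = run_pipeline(
        PipelineConfig(
            obo=root / "toy.obo",
            annotations=root / "toy.gaf",
            annotation_format="gaf",
            expression=root / "expr.csv",
            scale="log2_ratio",
            out_dir=root / "out",
            hypotheses=root / "hyp.txt",
        )
    )

    print("qualitative effects (rows: genes, columns: hypothesis terms)")
    print(paths["qualitative"].read_text())
    print("quantitative effects, expression-weighted, with summary rows")
    print(paths["quantitative"].read_text())

# In the quantitative table each defined cell is QL * GE (qualitative effect
# times log2 expression); the last three rows give, per hypothesis, the
# summed positive contributions, summed negative contributions and their
# total - the net effect of the whole gene set on that hypothesis.
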