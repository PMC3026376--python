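"""Deterministic toy fixtures: ontology, annotations, expression values.

The toy ontology mimics the regulation structure that signed matching relies
on: a set of base biological-process terms, a seeded fraction of which gain
a ``regulation of X`` child with ``positive regulation of X`` and ``negative
regulation of X`` beneath it.  Genes are annotated to leaf terms, so the
true-path walk has real work to do.  All generators are pure functions of
their spec (same seed, same bytes).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .ontology import GoDag, parse_obo

GAF_COLUMNS = 17


@dataclass(frozen=True)
class ToySpec:
    seed: int = 0
    n_process_terms: int = 4
    signed_fraction: float = 0.5
    n_genes: int = 6
    annotations_per_gene: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.n_process_terms < 1 or self.n_genes < 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.signed_fraction <= 1.0:
            raise ValueError("signed_fraction must lie in [0, 1]")
        lo, hi = self.annotations_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("annotations_per_gene must be a non-empty range")


def _go_id(n: int) -> str:
    return f"GO:{n:07d}"


def generate_toy_ontology(spec: ToySpec) -> str:
    """Emit OBO text for the toy DAG.

    Term count: 1 root + n base terms + 3 per signed base term.  The signed
    base terms are a seeded sample of size round(signed_fraction * n).
    """
    rng = random.Random(spec.seed)
    n = spec.n_process_terms
    n_signed = round(spec.signed_fraction * n)
    signed = set(rng.sample(range(1, n + 1), n_signed))

    counter = 1
    root = _go_id(counter)
    stanzas = [
        "format-version: 1.2",
        "ontology: goeffects-toy",
        "",
        "[Term]",
        f"id: {root}",
        "name: biological process",
        "namespace: biological_process",
        "",
    ]

    def stanza(go_id: str, name: str, parent: str) -> None:
        stanzas.extend(
            ["[Term]", f"id: {go_id}", f"name: {name}", f"is_a: {parent}", ""]
        )

    for k in range(1, n + 1):
        counter += 1
        base = _go_id(counter)
        stanza(base, f"process_{k}", root)
        if k in signed:
            counter += 1
            reg = _go_id(counter)
            stanza(reg, f"regulation of process_{k}", base)
            counter += 1
            stanza(_go_id(counter), f"positive regulation of process_{k}", reg)
            counter += 1
            stanza(_go_id(counter), f"negative regulation of process_{k}", reg)
    return "\n".join(stanzas)


def _leaf_ids(dag: GoDag) -> list[str]:
    has_child: set[str] = set()
    for term in dag.terms.values():
        for parent, _rel in term.parents:
            has_child.add(dag.resolve(parent))
    return sorted(t for t in dag.terms if t not in has_child)


def generate_toy_annotations(dag: GoDag, spec: ToySpec) -> str:
    """Emit GAF 2.2 text annotating G001.. to seeded samples of leaf terms."""
    rng = random.Random(spec.seed)
    leaves = _leaf_ids(dag)
    lo, hi = spec.annotations_per_gene
    lines = ["!gaf-version: 2.2"]
    for i in range(1, spec.n_genes + 1):
        gene = f"G{i:03d}"
        k = min(rng.randint(lo, hi), len(leaves))
        for go_id in sorted(rng.sample(leaves, k)):
            fields = [""] * GAF_COLUMNS
            fields[0] = "TOY"
            fields[1] = gene
            fields[2] = gene
            fields[3] = "involved_in"
            fields[4] = go_id
            fields[5] = "TOY:0000001"
            fields[6] = "IEA"
            fields[8] = "P"
            fields[11] = "protein"
            fields[12] = "taxon:0"
            fields[13] = "20200101"
            fields[14] = "toy"
            lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def generate_toy_expression(spec: ToySpec) -> str:
    """Emit an expression CSV: seeded log2 ratios in [-4, 4), one per gene."""
    rng = random.Random(spec.seed)
    lines = []
    for i in range(1, spec.n_genes + 1):
        value = round(rng.uniform(-4.0, 4.0), 3)
        lines.append(f"G{i:03d},{value:g}")
    return "\n".join(lines) + ("\n" if lines else "")


def toy_dag(spec: ToySpec) -> GoDag:
    """Convenience: parse the generated toy ontology."""
    return parse_obo(generate_toy_ontology(spec))


def toy_apoptosis_obo() -> str:
    """Packaged 6-term apoptosis subtree (OBO text)."""
    from importlib import resources

    return resources.files("goeffects").joinpath("data/toy_apoptosis.obo").read_text()


def toy_apoptosis_gaf() -> str:
    """Packaged 10-row GAF annotating four genes to the apoptosis subtree."""
    from importlib import resources

    return resources.files("goeffects").joinpath("data/toy_apoptosis.gaf").read_text()
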