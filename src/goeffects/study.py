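"""The nine-cytokine benchmark: tool-derived vs expert qualitative effects.

The packaged fixture holds, for nine cytokine genes (IL-2, IL-4, IL-6,
IL-8, IL-10, IL-13, IL-18, IFNg, TGFb) and eight immunological hypothesis
terms, two parallel qualitative effect matrices: the G matrix as produced by
GO-based matching and the M matrix produced independently by an immunologist
reading the literature.  Conflicting calls are stored as the two-element
sign set {+1, −1}.  The benchmark enters the pipeline at the conflict
resolution stage: the underlying decade-old annotation databases behind the
G calls are irrecoverable, but the per-cell calls themselves are stable.

The agreement score asks, per hypothesis term, whether the *direction* of
the net effect (sum of resolved cells at unit gene weight) agrees between
the two matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .effects import ScoringConfig, resolve_values
from .tables import (
    Cell,
    GeneExpression,
    QLMatrix,
    QuantSummary,
    build_quantitative,
)

CellValue = frozenset  # frozenset of ints: {1}, {-1}, {0}, {1, -1}


@dataclass
class CytokineStudy:
    """Per-gene qualitative calls of the cytokine benchmark (no summary rows)."""

    genes: list[str]
    hypotheses: list[str]
    g_cells: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    m_cells: dict[tuple[str, str], frozenset] = field(default_factory=dict)

    def matrix(self, source: str) -> Mapping[tuple[str, str], frozenset]:
        if source == "G":
            return self.g_cells
        if source == "M":
            return self.m_cells
        raise ValueError(f"source must be 'G' or 'M', not {source!r}")


GENES = ["IL-2", "IL-4", "IL-6", "IL-8", "IL-10", "IL-13", "IL-18", "IFNg", "TGFb"]
HYPOTHESES = [
    "TH2",
    "Antigen Presentation",
    "Chemotaxis",
    "Metastasis",
    "Angiogenesis",
    "T Cell Activation",
    "Cell Proliferation",
    "Apoptosis",
]


def _parse_cell(token: str) -> frozenset:
    return frozenset(int(v) for v in token.split("/"))


def cytokine_study() -> CytokineStudy:
    """Load the packaged benchmark fixture."""
    text = (
        resources.files("goeffects").joinpath("data/cytokine_effects.tsv").read_text()
    )
    study = CytokineStudy(list(GENES), list(HYPOTHESES))
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"fixture line {lineno}: expected 4 fields")
        gene, hyp, source, token = parts
        if gene not in study.genes or hyp not in study.hypotheses:
            raise ValueError(f"fixture line {lineno}: unknown gene or hypothesis")
        target = study.g_cells if source == "G" else study.m_cells
        target[(gene, hyp)] = _parse_cell(token)
    return study


def resolve_study_matrix(
    study: CytokineStudy,
    source: str = "G",
    cfg: ScoringConfig = ScoringConfig(),
) -> QLMatrix:
    """Resolve one of the benchmark's matrices into a qualitative matrix.

    Conflict sets are collapsed per the configured conflict policy; absent
    cells become undefined.
    """
    cells_in = study.matrix(source)
    cells: dict[tuple[str, str], Cell] = {}
    for gene in study.genes:
        for hyp in study.hypotheses:
            signs = cells_in.get((gene, hyp))
            if signs is None:
                cells[(gene, hyp)] = Cell(ql="undefined")
            else:
                ql, conflict = resolve_values(sorted(signs), cfg)
                cells[(gene, hyp)] = Cell(ql=ql, conflict=conflict)
    return QLMatrix(list(study.genes), list(study.hypotheses), cells)


def unit_expressions(genes: list[str]) -> list[GeneExpression]:
    """Unit gene weights: every gene's GE is 1 (pure vote counting)."""
    return [GeneExpression(g, 1.0, "log2_ratio", 1.0) for g in genes]


def summarize_study(
    study: CytokineStudy,
    source: str = "G",
    cfg: ScoringConfig = ScoringConfig(),
) -> QuantSummary:
    """Pro/anti/net sums of one benchmark matrix at unit gene weights."""
    ql = resolve_study_matrix(study, source, cfg)
    return build_quantitative(ql, unit_expressions(study.genes))


def _sign(x: float) -> int:
    return 0 if x == 0 else (1 if x > 0 else -1)


def agreement_score(
    study: CytokineStudy, cfg: ScoringConfig = ScoringConfig()
) -> float:
    """Percentage of hypothesis terms whose net-effect direction agrees
    between the tool-derived (G) and expert (M) matrices.

    Nets are computed independently per matrix (conflicts resolved per
    *cfg*, unit weights, absent cells skipped); the direction of zero is
    distinct from either sign.
    """
    net_g = summarize_study(study, "G", cfg).net
    net_m = summarize_study(study, "M", cfg).net
    agree = sum(
        1 for h in study.hypotheses if _sign(net_g[h]) == _sign(net_m[h])
    )
    return 100.0 * agree / len(study.hypotheses)


def disagreeing_terms(
    study: CytokineStudy, cfg: ScoringConfig = ScoringConfig()
) -> list[str]:
    """Hypothesis terms where the two matrices' net directions differ."""
    net_g = summarize_study(study, "G", cfg).net
    net_m = summarize_study(study, "M", cfg).net
    return [h for h in study.hypotheses if _sign(net_g[h]) != _sign(net_m[h])]
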