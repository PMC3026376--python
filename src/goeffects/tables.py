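"""Expression input, qualitative/quantitative matrices, edits, and outputs.

The qualitative matrix holds QL[i,j] ∈ {+1, −1, 0, undefined}: the resolved
effect of gene i on hypothesis j.  The quantitative matrix weights each
defined cell by the gene's expression value, QT[i,j] = QL[i,j] · GE[i], and
summarises each hypothesis column as a pro sum (positive QT), anti sum
(negative QT) and net N[j] = pro + anti.  Undefined cells (no annotation
reached the hypothesis) are excluded from all sums and rendered blank —
distinct from QL = 0, which contributes an explicit zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Union

from .annotations import AnnotationSet
from .effects import (
    UNDEFINED,
    EffectList,
    ScoringConfig,
    apply_unsigned_policy,
    match_effects,
    resolve_values,
)
from .hypothesis import HypothesisSet
from .ontology import GoDag

SCALES = ("fold_change", "log2_ratio", "difference")


class ExpressionFormatError(ValueError):
    pass


class ExpressionDomainError(ValueError):
    pass


class EditError(ValueError):
    pass


@dataclass(frozen=True)
class GeneExpression:
    """One gene's differential-expression measurement.

    ``value`` is the normalised GE: fold changes are converted to log2 so
    that positive means up-regulation, negative down-regulation and zero no
    change; log2 ratios and differences already satisfy that convention and
    pass through unchanged.
    """

    gene_id: str
    raw_value: float
    scale: str
    value: float


def parse_expression(source: Union[str, IO[str]], scale: str) -> list[GeneExpression]:
    """Parse ``id,value`` lines into an ordered expression list.

    Raises a format error (with line number) for malformed lines, a domain
    error for non-positive fold changes, and rejects duplicate gene ids.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown expression scale: {scale!r}")
    text = source if isinstance(source, str) else source.read()
    out: list[GeneExpression] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," not in line:
            raise ExpressionFormatError(f"line {lineno}: missing comma in {line!r}")
        gene_id, _, value_str = line.partition(",")
        gene_id = gene_id.strip()
        try:
            raw_value = float(value_str.strip())
        except ValueError:
            raise ExpressionFormatError(
                f"line {lineno}: non-numeric expression value {value_str.strip()!r}"
            ) from None
        if gene_id in seen:
            raise ExpressionFormatError(f"line {lineno}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        if scale == "fold_change":
            if raw_value <= 0:
                raise ExpressionDomainError(
                    f"line {lineno}: fold change must be positive, got {raw_value}"
                )
            value = math.log2(raw_value)
        else:
            value = raw_value
        out.append(GeneExpression(gene_id, raw_value, scale, value))
    return out


@dataclass
class Cell:
    ql: Union[int, str]  # +1 | -1 | 0 | "undefined"
    conflict: bool = False
    effects: EffectList = field(default_factory=EffectList)
    edited: bool = False
    annotated: bool = True  # False when the gene was never seen in the GAF

    @property
    def defined(self) -> bool:
        return self.ql != UNDEFINED


@dataclass
class QLMatrix:
    genes: list[str]
    hypotheses: list[str]
    cells: dict[tuple[str, str], Cell]

    def cell(self, gene: str, hypothesis: str) -> Cell:
        return self.cells[(gene, hypothesis)]


@dataclass
class QuantSummary:
    genes: list[str]
    hypotheses: list[str]
    qt: dict[tuple[str, str], float]  # only defined cells
    pro_sum: dict[str, float]
    anti_sum: dict[str, float]
    net: dict[str, float]


@dataclass(frozen=True)
class EditRecord:
    gene_id: str
    hypothesis: str
    new_ql: int  # -1 | 0 | +1


def build_qualitative(
    expr: list[GeneExpression],
    aset: AnnotationSet,
    hset: HypothesisSet,
    dag: GoDag,
    cfg: ScoringConfig = ScoringConfig(),
) -> QLMatrix:
    """Assemble the qualitative effect matrix, genes × hypothesis terms.

    Rows follow expression-file order; columns follow hypothesis order.
    A gene absent from the annotations (or with no surviving annotation)
    yields an undefined row.
    """
    genes = [e.gene_id for e in expr]
    hyp_labels = hset.labels()
    cells: dict[tuple[str, str], Cell] = {}
    for gene in genes:
        go_ids, seen = aset.annotations_of(gene)
        for hyp in hset:
            elist = (
                match_effects(dag, sorted(go_ids), hyp, cfg)
                if go_ids
                else EffectList()
            )
            values = [apply_unsigned_policy(r.sign, cfg) for r in elist]
            ql, conflict = resolve_values(values, cfg)
            cells[(gene, hyp.label)] = Cell(ql, conflict, elist, annotated=seen)
    return QLMatrix(genes, hyp_labels, cells)


def build_quantitative(ql: QLMatrix, expr: list[GeneExpression]) -> QuantSummary:
    """Weight each defined cell by its gene's expression value and summarise.

    QT[i,j] = QL[i,j] · GE[i]; per hypothesis, pro = Σ QT>0, anti = Σ QT<0,
    net = Σ QT (so net = pro + anti exactly).
    """
    ge = {e.gene_id: e.value for e in expr}
    missing = [g for g in ql.genes if g not in ge]
    if missing:
        raise KeyError(f"genes missing from expression list: {missing}")
    qt: dict[tuple[str, str], float] = {}
    pro = {h: 0.0 for h in ql.hypotheses}
    anti = {h: 0.0 for h in ql.hypotheses}
    net = {h: 0.0 for h in ql.hypotheses}
    for gene in ql.genes:
        for hyp in ql.hypotheses:
            cell = ql.cells[(gene, hyp)]
            if not cell.defined:
                continue
            value = int(cell.ql) * ge[gene]
            qt[(gene, hyp)] = value
            if value > 0:
                pro[hyp] += value
            elif value < 0:
                anti[hyp] += value
            net[hyp] += value
    return QuantSummary(list(ql.genes), list(ql.hypotheses), qt, pro, anti, net)


def parse_edits(source: Union[str, IO[str]]) -> list[EditRecord]:
    """Parse an edits file: ``gene_id<TAB>hypothesis_label<TAB>{-1|0|1}``."""
    text = source if isinstance(source, str) else source.read()
    out: list[EditRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise EditError(f"line {lineno}: expected 3 tab-separated fields")
        gene, hyp, value_str = (p.strip() for p in parts)
        try:
            value = int(value_str)
        except ValueError:
            raise EditError(f"line {lineno}: bad effect value {value_str!r}") from None
        if value not in (-1, 0, 1):
            raise EditError(f"line {lineno}: effect value must be -1, 0 or 1")
        out.append(EditRecord(gene, hyp, value))
    return out


def apply_edits(ql: QLMatrix, edits: Iterable[EditRecord]) -> QLMatrix:
    """Return a new matrix with user overrides applied (in order; last wins).

    An edit replaces the cell's QL, marks it edited, clears the conflict
    flag, and keeps the original effect list for audit.
    """
    cells = {
        key: replace(cell, effects=cell.effects) for key, cell in ql.cells.items()
    }
    for edit in edits:
        key = (edit.gene_id, edit.hypothesis)
        if edit.gene_id not in ql.genes:
            raise EditError(f"edit references unknown gene {edit.gene_id!r}")
        if edit.hypothesis not in ql.hypotheses:
            raise EditError(f"edit references unknown hypothesis {edit.hypothesis!r}")
        old = cells[key]
        cells[key] = Cell(
            ql=edit.new_ql,
            conflict=False,
            effects=old.effects,
            edited=True,
            annotated=old.annotated,
        )
    return QLMatrix(list(ql.genes), list(ql.hypotheses), cells)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def _render_ql(cell: Cell) -> str:
    if not cell.defined:
        return ""
    if cell.conflict and not cell.edited:
        return "+1/-1"
    return f"{int(cell.ql):+d}" if cell.ql else "0"


def _fmt(x: float) -> str:
    return format(x, ".12g")


def qualitative_tsv(ql: QLMatrix) -> str:
    """Genes × hypotheses TSV; conflict cells render as ``+1/-1``."""
    lines = ["gene\t" + "\t".join(ql.hypotheses)]
    for gene in ql.genes:
        row = [gene] + [_render_ql(ql.cells[(gene, h)]) for h in ql.hypotheses]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def quantitative_tsv(qs: QuantSummary) -> str:
    """Genes × hypotheses QT table with Sum of Pro / Sum of Anti / Net rows."""
    lines = ["gene\t" + "\t".join(qs.hypotheses)]
    for gene in qs.genes:
        row = [gene]
        for hyp in qs.hypotheses:
            value = qs.qt.get((gene, hyp))
            row.append("" if value is None else _fmt(value))
        lines.append("\t".join(row))
    for label, sums in (
        ("Sum of Pro", qs.pro_sum),
        ("Sum of Anti", qs.anti_sum),
        ("Net", qs.net),
    ):
        lines.append("\t".join([label] + [_fmt(sums[h]) for h in qs.hypotheses]))
    return "\n".join(lines) + "\n"


def net_effect_chart(qs: QuantSummary, path: Union[str, Path]) -> None:
    """Horizontal bar chart of net effects: positive green, negative red."""
    import matplotlib

    matplotlib.use("Agg")
    # fixed hashsalt + no date metadata -> byte-identical SVG across reruns
    matplotlib.rcParams["svg.hashsalt"] = "goeffects"
    import matplotlib.pyplot as plt

    labels = list(qs.hypotheses)
    values = [qs.net[h] for h in labels]
    height = max(1.5, 0.5 * len(labels) + 1)
    fig, ax = plt.subplots(figsize=(7, height))
    if labels:
        colors = ["#2ca02c" if v >= 0 else "#d62728" for v in values]
        ax.barh(range(len(labels)), values, color=colors)
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels)
        ax.invert_yaxis()
    ax.axvline(0, color="black", linewidth=0.8)
    ax.set_xlabel("net effect")
    fig.tight_layout()
    fig.savefig(str(path), format="svg", metadata={"Date": None})
    plt.close(fig)


def read_qualitative_tsv(
    source: Union[str, IO[str]], cfg: ScoringConfig = ScoringConfig()
) -> QLMatrix:
    """Parse a qualitative TSV back into a matrix (for the edit workflow).

    ``+1/-1`` cells are conflict sets and are re-resolved under *cfg*;
    effect lists are not recoverable from the table and come back empty.
    """
    text = source if isinstance(source, str) else source.read()
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        return QLMatrix([], [], {})
    hypotheses = lines[0].split("\t")[1:]
    genes: list[str] = []
    cells: dict[tuple[str, str], Cell] = {}
    for raw in lines[1:]:
        fields = raw.split("\t")
        gene = fields[0]
        genes.append(gene)
        values = fields[1:] + [""] * (len(hypotheses) - (len(fields) - 1))
        for hyp, token in zip(hypotheses, values):
            token = token.strip()
            if not token:
                cells[(gene, hyp)] = Cell(ql=UNDEFINED)
            elif "/" in token:
                ql, conflict = resolve_values(
                    [int(v) for v in token.split("/")], cfg
                )
                cells[(gene, hyp)] = Cell(ql=ql, conflict=conflict)
            else:
                cells[(gene, hyp)] = Cell(ql=int(token))
    return QLMatrix(genes, hypotheses, cells)


def read_quantitative_tsv(
    source: Union[str, IO[str]],
) -> tuple[QuantSummary, dict[str, dict[str, float]]]:
    """Parse a quantitative TSV; returns (summary, written-summary-rows).

    The first element recomputes pro/anti/net from the data rows; the second
    holds the three summary rows exactly as written, so callers can check
    self-consistency.
    """
    text = source if isinstance(source, str) else source.read()
    lines = [l for l in text.splitlines() if l.strip()]
    hypotheses = lines[0].split("\t")[1:]
    genes: list[str] = []
    qt: dict[tuple[str, str], float] = {}
    written: dict[str, dict[str, float]] = {}
    for raw in lines[1:]:
        fields = raw.split("\t")
        label = fields[0]
        values = fields[1:] + [""] * (len(hypotheses) - (len(fields) - 1))
        if label in ("Sum of Pro", "Sum of Anti", "Net"):
            written[label] = {
                h: float(v) for h, v in zip(hypotheses, values) if v.strip()
            }
            continue
        genes.append(label)
        for hyp, token in zip(hypotheses, values):
            if token.strip():
                qt[(label, hyp)] = float(token)
    pro = {h: sum(v for (g, hh), v in qt.items() if hh == h and v > 0) for h in hypotheses}
    anti = {h: sum(v for (g, hh), v in qt.items() if hh == h and v < 0) for h in hypotheses}
    net = {h: sum(v for (g, hh), v in qt.items() if hh == h) for h in hypotheses}
    return QuantSummary(genes, hypotheses, qt, pro, anti, net), written


def write_outputs(
    ql: QLMatrix, qs: QuantSummary, out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Write the qualitative TSV, quantitative TSV and net-effect SVG chart.

    Returns a name → path mapping for the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "qualitative": out / "qualitative.tsv",
        "quantitative": out / "quantitative.tsv",
        "chart": out / "net_effects.svg",
    }
    paths["qualitative"].write_text(qualitative_tsv(ql))
    paths["quantitative"].write_text(quantitative_tsv(qs))
    net_effect_chart(qs, paths["chart"])
    return paths
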