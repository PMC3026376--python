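"""End-to-end orchestration: files in, qualitative/quantitative tables out."""

from __future__ import annotations

import logging
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .annotations import parse_annotations, write_gene_info
from .effects import ScoringConfig
from .hypothesis import build_hypothesis_set, read_hgt, write_hgt
from .ontology import parse_obo
from .tables import (
    apply_edits,
    build_qualitative,
    build_quantitative,
    net_effect_chart,
    parse_edits,
    parse_expression,
    qualitative_tsv,
    quantitative_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    obo: Path
    annotations: Path
    annotation_format: str  # "gaf" | "idmap"
    expression: Path
    scale: str  # "fold_change" | "log2_ratio" | "difference"
    out_dir: Path
    hgt: Optional[Path] = None
    hypotheses: Optional[Path] = None
    edits: Optional[Path] = None
    scoring: ScoringConfig = ScoringConfig()
    case_insensitive: bool = False


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Parse inputs, build both matrices, apply edits, write all outputs.

    Outputs (qualitative.tsv, quantitative.tsv, net_effects.svg,
    gene_info.csv, hypothesis_terms.hgt) are staged in a temporary directory
    and moved into place together, so a failing stage leaves no partial
    results behind.
    """
    if cfg.hgt is None and cfg.hypotheses is None:
        raise ValueError("either an HGT file or a hypothesis file is required")

    dag = parse_obo(Path(cfg.obo).read_text())
    aset = parse_annotations(
        Path(cfg.annotations).read_text(),
        cfg.annotation_format,
        dag,
        case_insensitive=cfg.case_insensitive,
    )
    expr = parse_expression(Path(cfg.expression).read_text(), cfg.scale)
    if cfg.case_insensitive:
        expr = [
            type(e)(e.gene_id.lower(), e.raw_value, e.scale, e.value) for e in expr
        ]

    if cfg.hgt is not None:
        hset = read_hgt(Path(cfg.hgt).read_text(), dag)
    else:
        labels = Path(cfg.hypotheses).read_text().splitlines()
        hset = build_hypothesis_set(dag, labels, select="all")
        empty = [t.label for t in hset if not t.go_ids]
        if empty:
            logger.warning("no GO ids found for hypothesis terms: %s", empty)
        hset.terms = [t for t in hset.terms if t.go_ids]

    ql = build_qualitative(expr, aset, hset, dag, cfg.scoring)
    n_conflicts = sum(1 for c in ql.cells.values() if c.conflict)
    n_undefined = sum(1 for c in ql.cells.values() if not c.defined)
    logger.info(
        "%d genes x %d hypotheses: %d conflicts, %d undefined cells",
        len(ql.genes), len(ql.hypotheses), n_conflicts, n_undefined,
    )
    if cfg.edits is not None:
        ql = apply_edits(ql, parse_edits(Path(cfg.edits).read_text()))
    qs = build_quantitative(ql, expr)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {
        "qualitative": "qualitative.tsv",
        "quantitative": "quantitative.tsv",
        "chart": "net_effects.svg",
        "gene_info": "gene_info.csv",
        "hgt": "hypothesis_terms.hgt",
    }
    with tempfile.TemporaryDirectory(dir=out_dir) as staging:
        stage = Path(staging)
        (stage / names["qualitative"]).write_text(qualitative_tsv(ql))
        (stage / names["quantitative"]).write_text(quantitative_tsv(qs))
        net_effect_chart(qs, stage / names["chart"])
        (stage / names["gene_info"]).write_text(
            write_gene_info(aset, [(e.gene_id, e.value) for e in expr])
        )
        (stage / names["hgt"]).write_text(write_hgt(hset))
        paths = {}
        for key, name in names.items():
            shutil.move(str(stage / name), str(out_dir / name))
            paths[key] = out_dir / name
    return paths
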