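"""Expression parsing, matrix assembly, edits, summaries and writers."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goeffects.annotations import parse_annotations
from goeffects.effects import ScoringConfig
from goeffects.hypothesis import HypothesisSet, HypothesisTerm
from goeffects.ontology import parse_obo
from goeffects.tables import (
    Cell,
    EditError,
    EditRecord,
    ExpressionDomainError,
    ExpressionFormatError,
    GeneExpression,
    QLMatrix,
    apply_edits,
    build_qualitative,
    build_quantitative,
    net_effect_chart,
    parse_edits,
    parse_expression,
    qualitative_tsv,
    quantitative_tsv,
    read_qualitative_tsv,
    read_quantitative_tsv,
)

from .conftest import ANTI_APOPTOSIS, APOPTOSIS, NEG_REGULATION, POS_REGULATION, REGULATION


class TestParseExpression:
    def test_fold_change_converts_to_log2(self):
        (ge,) = parse_expression("IL6,2.0", "fold_change")
        assert ge.value == pytest.approx(1.0)
        (ge,) = parse_expression("IL6,1.0", "fold_change")
        assert ge.value == 0.0

    def test_fold_change_must_be_positive(self):
        with pytest.raises(ExpressionDomainError):
            parse_expression("IL6,-1.5", "fold_change")

    def test_log2_ratio_passes_through(self):
        (ge,) = parse_expression("IL6,-1.5", "log2_ratio")
        assert ge.value == -1.5

    def test_order_preserved_and_duplicates_rejected(self):
        genes = [e.gene_id for e in parse_expression("b,1\na,2\nc,3", "difference")]
        assert genes == ["b", "a", "c"]
        with pytest.raises(ExpressionFormatError, match="duplicate"):
            parse_expression("a,1\na,2", "difference")

    @pytest.mark.parametrize("bad", ["IL6 2.0", "IL6,abc"])
    def test_malformed_lines_name_the_line(self, bad):
        with pytest.raises(ExpressionFormatError, match="line 1"):
            parse_expression(bad, "log2_ratio")


PROLIF_OBO = """\
[Term]
id: GO:0008283
name: cell proliferation

[Term]
id: GO:0008284
name: positive regulation of cell proliferation
is_a: GO:0008283

[Term]
id: GO:0008285
name: negative regulation of cell proliferation
is_a: GO:0008283
"""


class TestBuildQualitative:
    def test_unannotated_gene_row_is_undefined(self, apoptosis_dag):
        expr = parse_expression("ghost,1.0", "log2_ratio")
        aset = parse_annotations("", "gaf", apoptosis_dag)
        hset = HypothesisSet([HypothesisTerm("apoptosis", [APOPTOSIS])])
        ql = build_qualitative(expr, aset, hset, apoptosis_dag)
        assert not ql.cell("ghost", "apoptosis").defined

    def test_conflicting_proliferation_annotations_flag_conflict(self):
        dag = parse_obo(PROLIF_OBO)
        expr = parse_expression("IL6,1.0", "log2_ratio")
        aset = parse_annotations("IL6,GO:0008284\nIL6,GO:0008285", "idmap", dag)
        hset = HypothesisSet(
            [HypothesisTerm("cell proliferation", ["GO:0008284", "GO:0008285"])]
        )
        ql = build_qualitative(expr, aset, hset, dag)
        cell = ql.cell("IL6", "cell proliferation")
        assert (cell.ql, cell.conflict) == (+1, True)
        line = qualitative_tsv(ql).splitlines()[1]
        assert line.split("\t")[1] == "+1/-1"

    def test_two_by_two_matches_sign_oracle(self, apoptosis_dag):
        expr = parse_expression("g1,1\ng2,1", "log2_ratio")
        aset = parse_annotations(
            f"g1,{NEG_REGULATION}\ng2,{ANTI_APOPTOSIS}", "idmap", apoptosis_dag
        )
        hset = HypothesisSet(
            [
                HypothesisTerm("regulation", [REGULATION]),
                HypothesisTerm("apoptosis", [APOPTOSIS]),
            ]
        )
        cfg = ScoringConfig(unsigned_policy="no_effect")
        ql = build_qualitative(expr, aset, hset, apoptosis_dag, cfg)
        # g1 "negative regulation of apoptosis" generalises to "regulation of"
        assert ql.cell("g1", "regulation").ql == -1
        assert not ql.cell("g1", "apoptosis").defined
        # g2 "anti-apoptosis" generalises to "apoptosis"
        assert ql.cell("g2", "apoptosis").ql == -1
        assert not ql.cell("g2", "regulation").defined


def unit_matrix(cells: dict[tuple[str, str], object]) -> QLMatrix:
    genes = sorted({g for g, _ in cells})
    hyps = sorted({h for _, h in cells})
    full = {
        (g, h): Cell(ql=cells.get((g, h), "undefined"))
        for g in genes
        for h in hyps
    }
    return QLMatrix(genes, hyps, full)


class TestBuildQuantitative:
    def test_qt_is_product_of_ql_and_expression(self):
        ql = unit_matrix({("g1", "h"): +1, ("g2", "h"): -1})
        expr = [
            GeneExpression("g1", 2.5, "log2_ratio", 2.5),
            GeneExpression("g2", -2.0, "log2_ratio", -2.0),
        ]
        qs = build_quantitative(ql, expr)
        assert qs.qt[("g1", "h")] == 2.5
        assert qs.qt[("g2", "h")] == 2.0  # down-regulated inhibitor adds up
        assert qs.net["h"] == 4.5

    def test_missing_gene_raises_by_name(self):
        ql = unit_matrix({("g1", "h"): +1})
        with pytest.raises(KeyError, match="g1"):
            build_quantitative(ql, [])

    def test_undefined_cells_enter_no_sum(self):
        ql = unit_matrix({("g1", "h"): +1})  # g2 row absent -> undefined
        ql.genes.append("g2")
        ql.cells[("g2", "h")] = Cell(ql="undefined")
        expr = [
            GeneExpression("g1", 1.0, "log2_ratio", 1.0),
            GeneExpression("g2", 9.0, "log2_ratio", 9.0),
        ]
        qs = build_quantitative(ql, expr)
        assert qs.net["h"] == 1.0 and ("g2", "h") not in qs.qt

    def test_zero_ql_contributes_explicit_zero(self):
        ql = unit_matrix({("g1", "h"): 0})
        qs = build_quantitative(ql, [GeneExpression("g1", 3.0, "log2_ratio", 3.0)])
        assert qs.qt[("g1", "h")] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_net_equals_pro_plus_anti_on_random_matrices(self, seed):
        # 20 seeds x 50 draws = 1000 random matrices
        rng = random.Random(seed)
        for _ in range(50):
            genes = [f"g{i}" for i in range(rng.randint(1, 6))]
            hyps = [f"h{j}" for j in range(rng.randint(1, 4))]
            cells = {
                (g, h): Cell(ql=rng.choice([+1, -1, 0, "undefined"]))
                for g in genes
                for h in hyps
            }
            expr = [
                GeneExpression(g, 0.0, "log2_ratio", round(rng.uniform(-5, 5), 3))
                for g in genes
            ]
            qs = build_quantitative(QLMatrix(genes, hyps, cells), expr)
            for h in hyps:
                assert qs.net[h] == pytest.approx(
                    qs.pro_sum[h] + qs.anti_sum[h], abs=1e-9
                )

    def test_unit_weights_count_cells(self):
        cells = {("g1", "h"): +1, ("g2", "h"): +1, ("g3", "h"): -1}
        ql = unit_matrix(cells)
        expr = [GeneExpression(g, 1.0, "log2_ratio", 1.0) for g in ql.genes]
        qs = build_quantitative(ql, expr)
        assert qs.net["h"] == 2 - 1

    def test_scaling_expression_scales_all_outputs_linearly(self):
        rng = random.Random(5)
        genes = [f"g{i}" for i in range(5)]
        cells = {
            (g, "h"): Cell(ql=rng.choice([+1, -1, 0])) for g in genes
        }
        base = [GeneExpression(g, 0, "log2_ratio", rng.uniform(-3, 3)) for g in genes]
        c = 2.75
        scaled = [GeneExpression(e.gene_id, 0, e.scale, e.value * c) for e in base]
        ql = QLMatrix(genes, ["h"], cells)
        qs1, qs2 = build_quantitative(ql, base), build_quantitative(ql, scaled)
        for key in qs1.qt:
            assert qs2.qt[key] == pytest.approx(c * qs1.qt[key])
        assert qs2.pro_sum["h"] == pytest.approx(c * qs1.pro_sum["h"])
        assert qs2.anti_sum["h"] == pytest.approx(c * qs1.anti_sum["h"])
        assert qs2.net["h"] == pytest.approx(c * qs1.net["h"])


class TestEdits:
    def test_edit_overrides_conflict_cell(self):
        ql = unit_matrix({("IL-6", "apoptosis"): +1})
        ql.cells[("IL-6", "apoptosis")].conflict = True
        edited = apply_edits(ql, [EditRecord("IL-6", "apoptosis", -1)])
        cell = edited.cell("IL-6", "apoptosis")
        assert (cell.ql, cell.conflict, cell.edited) == (-1, False, True)

    def test_empty_edit_list_is_identity(self):
        ql = unit_matrix({("g", "h"): +1})
        assert apply_edits(ql, []) == ql

    def test_last_edit_wins(self):
        ql = unit_matrix({("g", "h"): +1})
        out = apply_edits(
            ql, [EditRecord("g", "h", 0), EditRecord("g", "h", -1)]
        )
        assert out.cell("g", "h").ql == -1

    def test_unknown_references_raise(self):
        ql = unit_matrix({("g", "h"): +1})
        with pytest.raises(EditError, match="nope"):
            apply_edits(ql, [EditRecord("nope", "h", 0)])
        with pytest.raises(EditError, match="missing"):
            apply_edits(ql, [EditRecord("g", "missing", 0)])

    def test_parse_edits_format(self):
        edits = parse_edits("# c\nIL-6\tapoptosis\t-1\n")
        assert edits == [EditRecord("IL-6", "apoptosis", -1)]
        with pytest.raises(EditError):
            parse_edits("IL-6\tapoptosis\t5")
        with pytest.raises(EditError):
            parse_edits("IL-6 apoptosis -1")

    def test_edits_commute_with_quantitative_build(self):
        ql = unit_matrix({("g1", "h"): +1, ("g2", "h"): -1})
        expr = [
            GeneExpression("g1", 0, "log2_ratio", 2.0),
            GeneExpression("g2", 0, "log2_ratio", 3.0),
        ]
        edits = [EditRecord("g2", "h", +1)]
        via_edit = build_quantitative(apply_edits(ql, edits), expr)
        direct = build_quantitative(
            unit_matrix({("g1", "h"): +1, ("g2", "h"): +1}), expr
        )
        assert via_edit.qt == direct.qt and via_edit.net == direct.net


class TestWriters:
    def test_quantitative_tsv_summary_rows_self_consistent(self):
        rng = random.Random(11)
        genes = [f"g{i}" for i in range(4)]
        cells = {
            (g, h): Cell(ql=rng.choice([+1, -1, 0, "undefined"]))
            for g in genes
            for h in ("h1", "h2")
        }
        ql = QLMatrix(genes, ["h1", "h2"], cells)
        expr = [GeneExpression(g, 0, "log2_ratio", rng.uniform(-2, 2)) for g in genes]
        qs = build_quantitative(ql, expr)
        text = quantitative_tsv(qs)
        recomputed, written = read_quantitative_tsv(text)
        for h in qs.hypotheses:
            assert written["Sum of Pro"][h] == pytest.approx(recomputed.pro_sum[h])
            assert written["Sum of Anti"][h] == pytest.approx(recomputed.anti_sum[h])
            assert written["Net"][h] == pytest.approx(recomputed.net[h])

    def test_qualitative_tsv_round_trip(self):
        ql = unit_matrix({("g1", "h1"): +1, ("g2", "h2"): -1, ("g1", "h2"): 0})
        again = read_qualitative_tsv(qualitative_tsv(ql))
        assert again.genes == ql.genes and again.hypotheses == ql.hypotheses
        for key, cell in ql.cells.items():
            assert again.cells[key].ql == cell.ql

    def test_empty_matrix_writes_header_only(self):
        ql = QLMatrix([], ["h1"], {})
        assert qualitative_tsv(ql) == "gene\th1\n"

    def test_chart_is_svg_with_green_and_red_bars(self, tmp_path):
        ql = unit_matrix({("g1", "h1"): +1, ("g1", "h2"): -1})
        expr = [GeneExpression("g1", 0, "log2_ratio", 1.0)]
        qs = build_quantitative(ql, expr)
        out = tmp_path / "net.svg"
        net_effect_chart(qs, out)
        svg = out.read_text()
        assert svg.lstrip().startswith("<?xml")
        assert "2ca02c" in svg and "d62728" in svg

    def test_chart_with_zero_bars(self, tmp_path):
        qs = build_quantitative(QLMatrix([], [], {}), [])
        out = tmp_path / "empty.svg"
        net_effect_chart(qs, out)
        assert out.exists()
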