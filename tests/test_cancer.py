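"""Catalog handling, stage means, trend classification, co-occurrence."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiac_atlas as ca
from cardiac_atlas.cancer import classify_trend
from cardiac_atlas.staging import StageAssignment


def _catalog_files(tmp_path, onc_rows, tsg_rows):
    onc = tmp_path / "onc.tsv"
    tsg = tmp_path / "tsg.tsv"
    onc.write_text("".join(f"{s}\t{r}\n" for s, r in onc_rows))
    tsg.write_text("".join(f"{s}\t{r}\n" for s, r in tsg_rows))
    return onc, tsg


def _cells(counts, stages, symbols=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    symbols = symbols or [f"G{j}" for j in range(g)]
    genes = pd.DataFrame({"gene_id": [f"id{j}" for j in range(g)],
                          "symbol": symbols})
    table = pd.DataFrame({"barcode": [f"b{i}" for i in range(n)],
                          "time_point": "day0", "cell_line": "", "stage": ""})
    cells = ca.CellMatrix(raw=sp.csr_matrix(counts), genes=genes,
                          cell_table=table)
    assign = StageAssignment(cluster=np.zeros(n, dtype=int))
    assign.stage = np.asarray(stages)
    assign.stage_order = sorted(set(stages),
                                key=["I", "II", "III", "IV", "V"].index)
    return cells, assign


class TestLoadCatalog:
    def test_basic_roles(self, tmp_path):
        onc, tsg = _catalog_files(tmp_path, [("MYC", "oncogene")],
                                  [("TP53", "TSG")])
        cat = ca.load_catalog(onc, tsg)
        assert cat.oncogenes == {"MYC"} and cat.tsgs == {"TP53"}
        assert cat.role_of("myc") == "oncogene"

    def test_symbol_in_both_files_is_dual(self, tmp_path):
        onc, tsg = _catalog_files(tmp_path, [("WT1", "oncogene")],
                                  [("WT1", "TSG")])
        cat = ca.load_catalog(onc, tsg)
        assert cat.dual == {"WT1"} and cat.role_of("WT1") == "dual"

    def test_malformed_row_reports_line_number(self, tmp_path):
        onc = tmp_path / "bad.tsv"
        onc.write_text("MYC\toncogene\nBADLINE\n")
        tsg = tmp_path / "tsg.tsv"
        tsg.write_text("TP53\tTSG\n")
        with pytest.raises(ValueError, match="line 2"):
            ca.load_catalog(onc, tsg)

    def test_generated_catalogs_match_panel(self, tiny_dataset):
        _, _, catalogs = tiny_dataset
        panel = ca.default_panel()
        onc = set(catalogs["oncogenes"]["symbol"])
        assert set(panel.catalog("oncogene")) <= onc
        assert "MYC" in onc and "MALAT1" in onc
        assert "TP53" in set(catalogs["tsgs"]["symbol"])


class TestOverlapMarkers:
    def test_intersection_with_roles(self, tmp_path):
        onc, tsg = _catalog_files(tmp_path, [("B", "oncogene")], [("Z", "TSG")])
        cat = ca.load_catalog(onc, tsg)
        table = pd.DataFrame(
            {"gene": ["A", "B"], "stage": ["I", "II"], "stat": 1.0, "p": 0.01,
             "p_adj": 0.01, "lfc": 1.0, "tested": True, "is_marker": True}
        )
        res = ca.overlap_markers(ca.MarkerResult(table=table), cat)
        assert res["gene"].tolist() == ["B"]
        assert res["role"].tolist() == ["oncogene"]

    def test_disjoint_sets_empty_no_error(self, tmp_path):
        onc, tsg = _catalog_files(tmp_path, [("X", "oncogene")], [("Y", "TSG")])
        cat = ca.load_catalog(onc, tsg)
        table = pd.DataFrame(
            {"gene": ["A"], "stage": ["I"], "stat": 1.0, "p": 0.01,
             "p_adj": 0.01, "lfc": 1.0, "tested": True, "is_marker": True}
        )
        assert ca.overlap_markers(ca.MarkerResult(table=table), cat).empty


class TestStageMeans:
    def test_arithmetic_mean_per_stage(self):
        cells, assign = _cells([[0], [2], [4]], ["I", "I", "I"])
        prof = ca.stage_means(cells, assign)
        assert prof.loc["G0", "I"] == 2.0

    def test_absent_gene_all_zero(self):
        cells, assign = _cells([[1, 0], [3, 0]], ["I", "II"])
        prof = ca.stage_means(cells, assign)
        assert (prof.loc["G1"] == 0).all()

    def test_matches_brute_force_on_small_instance(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(3, size=(10, 4))
        stages = ["I"] * 3 + ["II"] * 3 + ["III"] * 4
        cells, assign = _cells(counts, stages)
        prof = ca.stage_means(cells, assign)
        for j in range(4):
            for lab, sel in (("I", slice(0, 3)), ("II", slice(3, 6)),
                             ("III", slice(6, 10))):
                manual = sum(counts[sel, j]) / len(counts[sel, j])
                assert prof.loc[f"G{j}", lab] == pytest.approx(manual,
                                                               abs=1e-12)


class TestClassifyTrend:
    @pytest.fixture
    def profile(self):
        return pd.DataFrame(
            {
                "I": [0.1, 2.0, 4.0, 0.0],
                "II": [0.5, 2.0, 3.0, 0.0],
                "III": [1.2, 2.0, 2.0, 0.0],
                "IV": [5.0, 2.0, 1.0, 0.0],
                "V": [12.0, 2.0, 0.5, 0.0],
            },
            index=["UP", "FLAT", "DOWN", "ZERO"],
        )

    def test_strictly_increasing_with_tiers(self, profile):
        call = classify_trend(profile, "UP")
        assert call.trend_class == "continuous_up"
        assert call.tier == "gt10_stageV"

    def test_constant_profile_is_other(self, profile):
        call = classify_trend(profile, "FLAT")
        assert call.trend_class == "other" and call.tier == "ge1"

    def test_strictly_decreasing(self, profile):
        call = classify_trend(profile, "DOWN")
        assert call.trend_class == "continuous_down"

    def test_unknown_gene_raises(self, profile):
        with pytest.raises(KeyError, match="NOPE"):
            classify_trend(profile, "NOPE")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           means=st.lists(st.floats(0.01, 100), min_size=5, max_size=5))
    def test_scale_equivariance(self, scale, means):
        """Multiplying means and both tiers by c > 0 keeps every class."""
        prof1 = pd.DataFrame([means], index=["g"],
                             columns=["I", "II", "III", "IV", "V"])
        prof2 = prof1 * scale
        cfg1 = ca.TrendConfig()
        cfg2 = ca.TrendConfig(expr_tier1=cfg1.expr_tier1 * scale,
                              expr_tier2=cfg1.expr_tier2 * scale)
        c1 = classify_trend(prof1, "g", cfg1)
        c2 = classify_trend(prof2, "g", cfg2)
        assert c1.trend_class == c2.trend_class and c1.tier == c2.tier

    def test_tier_partition_conserves_counts(self, small_run):
        """below1 + ge1 + gt10_stageV partitions the expressed catalog genes."""
        trends = small_run["trends"]
        tiers = trends["tier"].value_counts()
        assert tiers.sum() == len(trends)
        classes = trends["trend_class"].value_counts()
        assert classes.sum() == len(trends)


class TestTrendSignificance:
    def test_constant_expression_p_one(self):
        cells, assign = _cells([[2], [2], [2], [2]], ["I", "I", "II", "II"])
        assert ca.trend_significance(cells, assign, "G0") == 1.0

    def test_reversed_stage_order_same_p(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson([1, 2, 4, 8], size=(40, 4)).T.reshape(-1, 1)
        stages = sum([[s] * 40 for s in ["I", "II", "III", "IV"]], [])
        cells, assign = _cells(counts, stages)
        p_fwd = ca.trend_significance(cells, assign, "G0")
        assign.stage_order = assign.stage_order[::-1]
        p_rev = ca.trend_significance(cells, assign, "G0")
        assert p_fwd == pytest.approx(p_rev, rel=1e-9)
        assert p_fwd < 0.001  # strong planted trend

    def test_malat1_like_up_trend_significant(self, small_run):
        p = ca.trend_significance(small_run["cells"], small_run["assignment"],
                                  "MALAT1")
        assert p < 0.001


class TestPositivityAndCooccurrence:
    def test_positivity_thresholds(self):
        cells, _ = _cells([[0], [1], [5]], ["I", "I", "I"])
        pos = ca.positivity(cells, "G0")
        assert pos.tolist() == [False, True, True]

    def test_hand_built_six_cell_tally(self):
        #            TNNT2 MYC TP53
        counts = [
            [3, 2, 1],   # double pos, TP53 expressing
            [4, 1, 0],   # double pos, TP53 silent
            [2, 0, 5],   # TNNT2+ only
            [0, 3, 1],   # MYC+ only
            [5, 6, 0],   # double pos, TP53 silent
            [0, 0, 0],   # negative
        ]
        cells, assign = _cells(counts, ["V"] * 6,
                               symbols=["TNNT2", "MYC", "TP53"])
        res = ca.cooccurrence(cells, assign, "V")
        assert res.n_stage_cells == 6
        assert res.n_tnnt2_pos == 4
        assert res.n_tnnt2_myc_pos == 3
        assert res.n_tp53_expressing_among_double_pos == 1
        assert res.n_tp53_silent_among_double_pos == 2
        assert res.pct_tp53_silent == 66.7

    def test_no_myc_positive_cells_all_zero(self):
        counts = [[3, 0, 1], [2, 0, 0]]
        cells, assign = _cells(counts, ["V"] * 2,
                               symbols=["TNNT2", "MYC", "TP53"])
        res = ca.cooccurrence(cells, assign, "V")
        assert res.n_tnnt2_myc_pos == 0
        assert res.n_tp53_silent_among_double_pos == 0

    def test_missing_panel_gene_named(self):
        cells, assign = _cells([[1, 1]], ["V"], symbols=["TNNT2", "MYC"])
        with pytest.raises(KeyError, match="TP53"):
            ca.cooccurrence(cells, assign, "V")

    def test_invariant_to_cell_order_and_normalization(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.0, size=(50, 3))
        cells, assign = _cells(counts, ["V"] * 50,
                               symbols=["TNNT2", "MYC", "TP53"])
        base = ca.cooccurrence(cells, assign, "V")
        perm = rng.permutation(50)
        cells2, assign2 = _cells(counts[perm], ["V"] * 50,
                                 symbols=["TNNT2", "MYC", "TP53"])
        ca.normalize_to_median(cells2) if (counts[perm].sum(1) > 0).all() else None
        shuffled = ca.cooccurrence(cells2, assign2, "V")
        assert base.to_dict() == shuffled.to_dict()
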