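import numpy as np
import pandas as pd
import pytest

import polytarget as pt
from polytarget.errors import ConfigError, DataError
from polytarget.genome import HomoeologMap
from polytarget.integrate import (
    TargetCall,
    classify_direct_indirect,
    collapse_to_homoeologs,
    read_deg_table,
    round1,
    select_consistent_degs,
    summarize_classification,
    write_deg_table,
)


def deg_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "line", "stage", "log2fc", "fdr"])


class TestReadDegTable:
    def test_three_gene_fixture(self, tmp_path):
        p = tmp_path / "deg.tsv"
        p.write_text(
            "gene_id\tline\tstage\tlog2fc\tfdr\n"
            "g1\tA\twhite\t-1.5\t0.01\n"
            "g2\tA\twhite\t0.2\t0.8\n"
            "g3\tB\tred\t2.0\t0.001\n"
        )
        df = read_deg_table(p)
        assert sorted(df["gene_id"]) == ["g1", "g2", "g3"]

    def test_duplicate_contrast_is_error(self, tmp_path):
        p = tmp_path / "deg.tsv"
        p.write_text(
            "gene_id\tline\tstage\tlog2fc\tfdr\n"
            "g1\tA\twhite\t-1.5\t0.01\n"
            "g1\tA\twhite\t-1.4\t0.02\n"
        )
        with pytest.raises(DataError, match="duplicate"):
            read_deg_table(p)

    def test_non_numeric_reports_line(self, tmp_path):
        p = tmp_path / "deg.tsv"
        p.write_text(
            "gene_id\tline\tstage\tlog2fc\tfdr\ng1\tA\twhite\toops\t0.01\n"
        )
        with pytest.raises(DataError, match="line 2"):
            read_deg_table(p)

    def test_large_table_roundtrips(self, tmp_path, rng):
        rows = [
            (f"g{i:05d}", line, stage,
             float(rng.normal(0, 2)), float(rng.uniform(0, 1)))
            for i in range(2500)
            for line in ("A", "B")
            for stage in ("white", "red")
        ]
        df = deg_frame(rows)
        p = tmp_path / "big.tsv"
        write_deg_table(df, p)
        again = read_deg_table(p)
        assert len(again) == 10_000
        assert np.allclose(again["log2fc"], df["log2fc"], rtol=1e-5)


class TestSelectConsistentDegs:
    def test_qualifying_in_both_lines_any_stage(self):
        df = deg_frame([
            ("g1", "A", "white", -1.2, 0.01),
            ("g1", "B", "white", -1.2, 0.01),
        ])
        sel = select_consistent_degs(df)
        assert list(sel.index) == ["g1"] and sel.loc["g1", "direction"] == "down"

    def test_subthreshold_fold_change_not_selected(self):
        df = deg_frame([
            ("g1", "A", "white", -0.9, 0.01),
            ("g1", "B", "white", -0.9, 0.01),
        ])
        assert len(select_consistent_degs(df)) == 0

    def test_single_line_fails_consistency(self):
        df = deg_frame([
            ("g1", "A", "white", 1.5, 0.01),
            ("g1", "B", "white", 0.1, 0.9),
        ])
        assert len(select_consistent_degs(df)) == 0
        assert list(select_consistent_degs(df, require_both_lines=False).index) == ["g1"]

    def test_thresholds_inclusive(self):
        df = deg_frame([
            ("g1", "A", "white", 1.0, 0.05),
            ("g1", "B", "white", -1.0, 0.05),
        ])
        sel = select_consistent_degs(df)
        assert sel.loc["g1", "direction"] == "mixed"

    def test_both_stages_rule_stricter(self):
        df = deg_frame([
            ("g1", "A", "white", -2.0, 0.01),
            ("g1", "A", "red", -0.2, 0.6),
            ("g1", "B", "white", -2.0, 0.01),
            ("g1", "B", "red", -2.0, 0.01),
        ])
        assert len(select_consistent_degs(df, stage_rule="any_stage")) == 1
        assert len(select_consistent_degs(df, stage_rule="both_stages")) == 0

    def test_unknown_stage_rule(self):
        with pytest.raises(ConfigError):
            select_consistent_degs(deg_frame([("g", "A", "w", 1.0, 0.01)]),
                                   stage_rule="sometimes")

    def test_direction_invariant_to_contrast_order(self, rng):
        rows = [
            ("g1", line, stage, float(rng.choice([-2.0, -1.5])), 0.01)
            for line in "AB" for stage in ("white", "red")
        ]
        df = deg_frame(rows)
        shuffled = df.sample(frac=1, random_state=1)
        a = select_consistent_degs(df)
        b = select_consistent_degs(shuffled)
        pd.testing.assert_frame_equal(a, b)


def call(gene, sel=True, bound=None, direction="down", group=None):
    return TargetCall(gene, "selected" if sel else "not_selected", bound,
                      direction if sel else "NA", group)


class TestClassification:
    def test_bound_selected_is_direct_at_all_levels_by_nesting(self):
        calls = classify_direct_indirect(
            {"g1": "down"},
            {"VL1": {"g1": []}, "VL2": {"g1": []}, "VL3": {"g1": []}},
        )
        (c,) = calls
        assert c.cls == "direct"
        assert all(c.direct_at(l) for l in pt.LEVELS)

    def test_selected_unbound_is_indirect(self):
        (c,) = classify_direct_indirect({"g1": "up"}, {"VL1": {}})
        assert c.cls == "indirect" and c.direction == "up"

    def test_unselected_unbound_is_neither(self):
        calls = classify_direct_indirect({}, {"VL1": {}}, universe=["g1"])
        assert calls[0].cls == "neither"

    def test_partition_invariant(self, rng):
        genes = [f"g{i}" for i in range(200)]
        sel = {g: "down" for g in genes if rng.random() < 0.4}
        bound = {g: [] for g in genes if rng.random() < 0.3}
        calls = classify_direct_indirect(sel, {"VL1": bound}, universe=genes)
        summ = summarize_classification(calls)
        assert summ.n_direct["VL1"] + summ.n_indirect["VL1"] == summ.n_selected_degs
        for level in pt.LEVELS:
            direct = [c for c in calls if c.direct_at(level)]
            assert (summ.n_down[level] + summ.n_up[level] + summ.n_mixed[level]
                    == len(direct))

    def test_direct_sets_nest_across_levels(self, rng):
        genes = [f"g{i}" for i in range(300)]
        sel = {g: "down" for g in genes if rng.random() < 0.5}
        maps = {"VL1": {}, "VL2": {}, "VL3": {}}
        for g in genes:
            r = rng.random()
            if r < 0.1:
                maps["VL3"][g] = []
            if r < 0.2:
                maps["VL2"][g] = []
            if r < 0.4:
                maps["VL1"][g] = []
        calls = classify_direct_indirect(sel, maps, universe=genes)
        d = {l: {c.gene_id for c in calls if c.direct_at(l)} for l in pt.LEVELS}
        assert d["VL3"] <= d["VL2"] <= d["VL1"]


class TestHomoeologCollapse:
    def test_four_genes_one_group_all_direct(self):
        hmap = HomoeologMap({f"g{i}": "H1" for i in range(4)})
        calls = [call(f"g{i}", bound="VL3") for i in range(4)]
        out = collapse_to_homoeologs(calls, hmap)
        assert out["direct_VL1"] == out["direct_VL3"] == 1

    def test_empty_calls_zero_counts(self):
        out = collapse_to_homoeologs([], HomoeologMap({}))
        assert out["direct_VL1"] == 0 and out["indirect"] == 0

    def test_matches_set_of_groups_oracle(self, rng):
        hmap = HomoeologMap({f"g{i}": f"H{i % 17}" for i in range(100)})
        calls = []
        for i in range(100):
            bound = rng.choice([None, "VL1", "VL2", "VL3"])
            calls.append(call(f"g{i}", sel=bool(rng.random() < 0.5),
                              bound=None if bound is None else str(bound)))
        out = collapse_to_homoeologs(calls, hmap)
        for level in pt.LEVELS:
            expect = {hmap.get(c.gene_id) for c in calls if c.direct_at(level)}
            assert out[f"direct_{level}"] == len(expect)
        expect_ind = {hmap.get(c.gene_id) for c in calls if c.cls == "indirect"}
        assert out["indirect"] == len(expect_ind)


class TestSummaryArithmetic:
    def test_direct_share_of_selected_degs(self):
        calls = [call(f"d{i}", bound="VL1") for i in range(934)]
        calls += [call(f"i{i}") for i in range(6109 - 934)]
        summ = summarize_classification(calls)
        assert summ.n_selected_degs == 6109
        assert summ.pct_direct["VL1"] == 15.3
        assert summ.pct_indirect["VL1"] == 84.7

    def test_down_up_split_percentages(self):
        calls = [call(f"d{i}", bound="VL1", direction="down") for i in range(581)]
        calls += [call(f"u{i}", bound="VL1", direction="up") for i in range(369)]
        summ = summarize_classification(calls)
        assert summ.pct_down["VL1"] == 61.2 and summ.pct_up["VL1"] == 38.8

    def test_zero_direct_is_zero_not_na(self):
        calls = [call(f"i{i}") for i in range(10)]
        summ = summarize_classification(calls)
        assert summ.pct_direct["VL1"] == 0.0

    def test_zero_selected_gives_na(self):
        calls = [call("g", sel=False, bound="VL1")]
        summ = summarize_classification(calls)
        assert summ.pct_direct["VL1"] is None

    @pytest.mark.parametrize("x,expected", [(15.25, 15.3), (8.2501, 8.3),
                                            (61.15789, 61.2), (0.04, 0.0)])
    def test_half_up_rounding(self, x, expected):
        assert round1(x) == expected
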