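"""Descriptives, balanced estimation, Tukey contrasts, Friedman, biclustering."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster import hierarchy

from scanbody_congruence import study_stats
from scanbody_congruence.datasets import load_ios_study_cells
from scanbody_congruence.errors import IncompleteBlocksError, ParameterError
from scanbody_congruence.synthetic_scanbody import SB_LABELS


def make_table(cell_values: dict) -> pd.DataFrame:
    rows = []
    for (scanner, sb), vals in cell_values.items():
        for j, v in enumerate(vals, start=1):
            rows.append({"scanner": scanner, "sb": sb, "model": j, "mean_abs_dev_um": v})
    return pd.DataFrame(rows)


class TestDescriptives:
    def test_cell_mean(self):
        table = make_table({("a", "S1"): np.arange(20.0, 30.0)})
        cells = study_stats.describe_cells(table)
        assert cells.loc[0, "mean"] == pytest.approx(24.5)
        assert cells.loc[0, "n"] == 10

    def test_single_replicate_cell_reported_absent(self):
        table = make_table({("a", "S1"): [25.0, 26.0], ("a", "S2"): [30.0]})
        cells = study_stats.describe_cells(table)
        assert set(cells["sb"]) == {"S1"}

    def test_report_cell_format(self):
        out = study_stats.format_cell(25.4, 3.5, 25.0, 23.2, 27.0)
        assert out == "25.4 (3.5); 25.0; (23.2–27.0)"

    def test_duplicate_rows_rejected(self):
        table = make_table({("a", "S1"): [25.0, 26.0]})
        bad = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(ParameterError):
            study_stats.describe_cells(bad)


class TestOutlierFlags:
    def test_gross_outlier_flagged_by_robust_z(self):
        vals = [30, 31, 32, 33, 34, 35, 36, 37, 38, 380.0]
        table = make_table({("itero", "S1"): vals})
        flags = study_stats.flag_outliers(table)
        assert flags.sum() == 1
        assert table.loc[flags, "mean_abs_dev_um"].iloc[0] == 380.0

    def test_rule_none_flags_nothing(self):
        table = make_table({("a", "S1"): [1.0, 2.0, 100.0]})
        assert study_stats.flag_outliers(table, rule="none").sum() == 0

    def test_manual_rule_flags_exactly_the_named_row(self):
        table = make_table({("itero", "S1"): [30.0] * 10, ("itero", "S2"): [30.0] * 10})
        flags = study_stats.flag_outliers(
            table, rule="manual", manual=[("itero", "S1", 7)]
        )
        assert flags.sum() == 1
        row = table.loc[flags].iloc[0]
        assert (row["scanner"], row["sb"], row["model"]) == ("itero", "S1", 7)

    def test_clean_cells_not_flagged(self, rng):
        table = make_table(
            {("a", sb): rng.normal(30, 2, 10) for sb in SB_LABELS}
        )
        assert study_stats.flag_outliers(table).sum() == 0


class TestScannerEstimates:
    def test_balanced_identity_on_reference_cells(self):
        """Scanner estimate = unweighted mean of its six cell means."""
        est = study_stats.scanner_estimates(load_ios_study_cells())
        by = est.set_index("scanner")["estimate_um"]
        assert study_stats.round_half_up(by["PRIMESCAN"], 1) == 25.5
        assert study_stats.round_half_up(by["EMERALD_S"], 1) == 38.3
        # total observation-level SDs (within + between cells)
        sd = est.set_index("scanner")["sd_total_um"]
        assert study_stats.round_half_up(sd["PRIMESCAN"], 1) == pytest.approx(5.0)
        assert study_stats.round_half_up(sd["EMERALD_S"], 1) == pytest.approx(7.9, abs=0.11)

    def test_constant_table_gives_zero_width_ci(self):
        cells = pd.DataFrame(
            {"scanner": ["a"] * 6, "sb": list(SB_LABELS), "mean": [30.0] * 6}
        )
        est = study_stats.scanner_estimates(cells)
        assert est.loc[0, "estimate_um"] == 30.0
        assert est.loc[0, "ci95_low"] == pytest.approx(30.0)
        assert est.loc[0, "ci95_high"] == pytest.approx(30.0)


class TestScannerContrasts:
    def test_reference_pairwise_estimates(self):
        con = study_stats.scanner_contrasts(load_ios_study_cells())
        got = {
            row["pair"]: study_stats.round_half_up(row["estimate_um"], 2)
            for _, row in con.iterrows()
        }
        assert got["PRIMESCAN - CS3700"] == -1.58
        assert got["PRIMESCAN - MEDIT_I500"] == -4.37
        assert got["PRIMESCAN - EMERALD_S"] == -12.80
        assert got["CS3700 - MEDIT_I500"] == -2.78
        assert got["CS3700 - EMERALD_S"] == -11.22
        assert got["MEDIT_I500 - EMERALD_S"] == -8.43

    def test_adjusted_p_never_below_unadjusted(self):
        con = study_stats.scanner_contrasts(load_ios_study_cells())
        assert (con["p_adjusted"] >= con["p_unadjusted"] - 1e-12).all()
        assert con["p_adjusted"].between(0, 1).all()

    def test_antisymmetry_under_scanner_reordering(self):
        cells = load_ios_study_cells()
        fwd = study_stats.scanner_contrasts(cells)
        rev = study_stats.scanner_contrasts(cells.iloc[::-1].reset_index(drop=True))
        f = fwd.set_index("pair")["estimate_um"]
        r = rev.set_index("pair")["estimate_um"]
        for pair, est in f.items():
            a, b = pair.split(" - ")
            assert r[f"{b} - {a}"] == pytest.approx(-est, abs=1e-12)

    def test_identical_scanners_give_zero_and_p_one(self):
        cells = pd.DataFrame(
            {
                "scanner": ["a"] * 6 + ["b"] * 6,
                "sb": list(SB_LABELS) * 2,
                "mean": [25.0, 26, 30, 28, 24, 23] * 2,
            }
        )
        con = study_stats.scanner_contrasts(cells)
        assert con.loc[0, "estimate_um"] == 0.0
        assert con.loc[0, "p_adjusted"] == 1.0

    def test_ci_contains_estimate(self):
        con = study_stats.scanner_contrasts(load_ios_study_cells())
        assert (con["ci95_low"] <= con["estimate_um"]).all()
        assert (con["estimate_um"] <= con["ci95_high"]).all()


class TestSbContrasts:
    def test_reference_within_scanner_estimates(self):
        sbc = study_stats.sb_contrasts(load_ios_study_cells())
        sbc = sbc.set_index(["scanner", "pair"])["estimate_um"]
        assert study_stats.round_half_up(sbc[("PRIMESCAN", "S3 - S2")], 2) == 8.40
        assert study_stats.round_half_up(sbc[("EMERALD_S", "S4 - S2")], 2) == 17.40

    def test_fifteen_pairs_per_scanner(self):
        sbc = study_stats.sb_contrasts(load_ios_study_cells())
        assert sbc.groupby("scanner").size().eq(15).all()
        assert not any(p.split(" - ")[0] == p.split(" - ")[1] for p in sbc["pair"])


class TestFriedman:
    def test_forced_ranks_closed_form(self):
        """3 models x 3 blocks with ranks (1,2,3) everywhere: the statistic
        is 12/(b k (k+1)) sum R_j^2 - 3 b (k+1) = 6, p = chi2.sf(6, 2)."""
        blocks = np.array([[1.0, 2, 3], [4, 5, 6], [1, 3, 9]])
        stat, p = study_stats.friedman_statistic(blocks)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(0.0498, abs=1e-3)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, (6, rng.integers(3, 7)))
            stat, p = study_stats.friedman_statistic(x)
            ref = sps.friedmanchisquare(*[x[:, j] for j in range(x.shape[1])])
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(30, 4, (6, 5))
        s1, _ = study_stats.friedman_statistic(x)
        s2, _ = study_stats.friedman_statistic(np.exp(x / 10.0))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_identical_models_give_zero_statistic(self):
        table = make_table({("a", sb): [30.0, 30.0, 30.0] for sb in SB_LABELS})
        out = study_stats.friedman_by_scanner(table)
        assert out.loc[0, "statistic"] == 0.0
        assert out.loc[0, "p_raw"] == 1.0

    def test_incomplete_blocks_name_missing_cells(self):
        table = make_table({("a", sb): [30.0, 31.0] for sb in SB_LABELS})
        table = table.drop(table[(table.sb == "S3") & (table.model == 2)].index)
        with pytest.raises(IncompleteBlocksError, match="S3"):
            study_stats.friedman_by_scanner(table)

    def test_holm_arithmetic(self):
        adj = study_stats.holm_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])
        table = make_table(
            {(s, sb): np.random.default_rng(3).normal(30, 2, 4) for s in "abc" for sb in SB_LABELS}
        )
        out = study_stats.friedman_by_scanner(table)
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()


class TestBicluster:
    def test_identical_rows_merge_at_zero_height(self):
        m = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3], [5, 6, 7]],
                         index=["a", "b", "c"], columns=["x", "y", "z"])
        res = study_stats.bicluster(m)
        assert res.row_linkage[0, 2] == pytest.approx(0.0)

    def test_two_by_two_merge_heights_hand_computed(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["r1", "r2"], columns=["c1", "c2"])
        res = study_stats.bicluster(m)
        assert res.row_linkage[0, 2] == pytest.approx(5.0)  # euclidean((0,0),(3,4))
        assert res.col_linkage[0, 2] == pytest.approx(1.0)  # euclidean((0,3),(0,4))

    def test_reference_matrix_isolates_high_deviation_positions(self):
        """On the benchmark cell-mean matrix the column dendrogram's final
        merge separates {S3, S4} — the positions with the largest deviations
        for four of five scanners — from the other four scanbodies."""
        mat = study_stats.cell_matrix(load_ios_study_cells(), "mean")
        res = study_stats.bicluster(mat)
        two = hierarchy.fcluster(res.col_linkage, t=2, criterion="maxclust")
        groups = {}
        for col, g in zip(mat.columns, two):
            groups.setdefault(g, set()).add(col)
        assert {"S3", "S4"} in groups.values()

    def test_merge_heights_non_decreasing(self):
        mat = study_stats.cell_matrix(load_ios_study_cells(), "sd")
        res = study_stats.bicluster(mat)
        assert np.all(np.diff(res.row_linkage[:, 2]) >= -1e-12)
        assert np.all(np.diff(res.col_linkage[:, 2]) >= -1e-12)

    def test_non_finite_matrix_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ParameterError):
            study_stats.bicluster(m)


def test_rounding_is_half_up():
    assert study_stats.round_half_up(2.345, 2) == 2.35
    assert study_stats.round_half_up(-1.585, 2) == -1.59
    assert study_stats.round_half_up(29.87, 1) == 29.9
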