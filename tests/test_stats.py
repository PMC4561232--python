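"""Dose-response statistics: correlation, eta-squared, Tukey letters, Ward, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from soilecotox.stats import (
    DegenerateDataError,
    DegreesOfFreedomError,
    LayoutError,
    dose_correlation,
    eta_squared,
    pca_variance,
    tukey_letters,
    ward_cluster,
)

DOSES5 = (0.0, 0.075, 2.25, 11.25, 22.5)


class TestDoseCorrelation:
    def test_perfect_linearity(self):
        res = dose_correlation(DOSES5, [3 * d + 1 for d in DOSES5])
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_urease_day90_row(self, enzyme_table):
        col = enzyme_table.query("variable == 'urease' and time == 90").sort_values("dose")
        res = dose_correlation(col["dose"], col["value"])
        assert round(res.r, 3) == -0.993
        assert res.n == 5
        assert res.significant  # p ~ 7e-4 < 0.01

    def test_errors(self):
        with pytest.raises(DegenerateDataError):
            dose_correlation([0, 1], [1, 2])
        with pytest.raises(DegenerateDataError):
            dose_correlation([0, 1, 2], [5, 5, 5])
        with pytest.raises(DegenerateDataError):
            dose_correlation([0, 1, 2], [1, 2])


def brute_force_two_way_ss(values: np.ndarray):
    """Independent decomposition by explicit loops (means grid, no replication)."""
    n_rows, n_cols = values.shape
    grand = values.sum() / values.size
    row_means = [values[i, :].sum() / n_cols for i in range(n_rows)]
    col_means = [values[:, j].sum() / n_rows for j in range(n_cols)]
    ss_rows = sum(n_cols * (m - grand) ** 2 for m in row_means)
    ss_cols = sum(n_rows * (m - grand) ** 2 for m in col_means)
    ss_total = sum(
        (values[i, j] - grand) ** 2 for i in range(n_rows) for j in range(n_cols)
    )
    return ss_rows, ss_cols, ss_total


class TestEtaSquared:
    def test_alkaline_phosphatase_grid_against_brute_force(self, enzyme_table):
        sub = enzyme_table[enzyme_table["variable"] == "alkaline_phosphatase"]
        partition = eta_squared(sub)
        grid = sub.pivot_table(index="dose", columns="time", values="value").to_numpy()
        ss_dose, ss_time, ss_total = brute_force_two_way_ss(grid)
        assert partition.ss["dose"] == pytest.approx(ss_dose, rel=1e-12)
        assert partition.ss["time"] == pytest.approx(ss_time, rel=1e-12)
        assert partition.ss_total == pytest.approx(ss_total, rel=1e-12)
        # frozen oracle values for this grid
        assert partition.ss["dose"] == pytest.approx(0.04732773, abs=1e-7)
        assert partition.ss_total == pytest.approx(7.80032973, abs=1e-7)

    def test_components_sum_to_total(self, enzyme_table):
        for variable, sub in enzyme_table.groupby("variable"):
            partition = eta_squared(sub)
            assert sum(partition.ss.values()) == pytest.approx(
                partition.ss_total, rel=1e-9
            )
            assert all(0 <= v <= 1 for v in partition.eta_squared.values())

    def test_additive_grid_has_no_interaction(self):
        rows = [
            (d, t, 2.0 * i + 0.5 * j)
            for i, d in enumerate(DOSES5)
            for j, t in enumerate((30, 60, 90))
        ]
        partition = eta_squared(pd.DataFrame(rows, columns=["dose", "time", "value"]))
        assert partition.eta_squared["interaction"] == pytest.approx(0.0, abs=1e-12)

    def test_time_only_grid_gives_full_time_share(self):
        rows = [(d, t, float(t)) for d in DOSES5 for t in (30, 60, 90)]
        partition = eta_squared(pd.DataFrame(rows, columns=["dose", "time", "value"]))
        assert partition.eta_squared_percent["time"] == pytest.approx(100.0)
        assert partition.eta_squared_percent["dose"] == pytest.approx(0.0, abs=1e-9)

    def test_swapping_factor_labels_swaps_components(self, enzyme_table):
        sub = enzyme_table[enzyme_table["variable"] == "catalase"]
        swapped = sub.rename(columns={"dose": "time", "time": "dose"})
        a, b = eta_squared(sub), eta_squared(swapped)
        assert a.ss["dose"] == pytest.approx(b.ss["time"], rel=1e-12)
        assert a.ss["time"] == pytest.approx(b.ss["dose"], rel=1e-12)

    def test_incomplete_grid_rejected(self):
        rows = [(0.0, 30, 1.0), (0.0, 60, 2.0), (1.0, 30, 3.0)]
        with pytest.raises(LayoutError, match="incomplete"):
            eta_squared(pd.DataFrame(rows, columns=["dose", "time", "value"]))

    def test_replicated_layout_adds_error_stratum(self):
        rng = np.random.default_rng(11)
        rows = [
            (d, t, 1.0 + 0.1 * d - 0.01 * t + rng.normal(0, 0.05))
            for d in (0.0, 1.0, 2.0)
            for t in (30, 60)
            for _ in range(4)
        ]
        partition = eta_squared(pd.DataFrame(rows, columns=["dose", "time", "value"]))
        assert partition.replicated
        assert set(partition.ss) == {"dose", "time", "interaction", "error"}
        assert sum(partition.eta_squared.values()) == pytest.approx(1.0, rel=1e-9)


OFFSETS = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])


class TestTukeyLetters:
    def test_identically_distributed_groups_share_one_letter(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(0.0, 1.0, 5) for k in "abcde"}
        display = tukey_letters(groups, alpha=0.01)
        assert set(display.letters.values()) == {"a"}

    def test_well_separated_groups_get_distinct_letters(self):
        groups = {"g1": OFFSETS * 0.1, "g2": OFFSETS * 0.1 + 50, "g3": OFFSETS * 0.1 + 100}
        display = tukey_letters(groups, alpha=0.01)
        assert [display.letters[g] for g in ("g1", "g2", "g3")] == ["a", "b", "c"]

    def test_only_extremes_differ_gives_bridging_pattern(self):
        # constructed so q(step 1) < q_crit(3, 12, 0.01) < q(step 2)
        groups = {"low": OFFSETS, "mid": OFFSETS + 1.0, "high": OFFSETS + 2.0}
        display = tukey_letters(groups, alpha=0.01)
        assert [display.letters[g] for g in ("low", "mid", "high")] == ["a", "ab", "b"]

    def test_single_replicate_group_rejected(self):
        with pytest.raises(DegreesOfFreedomError, match="lonely"):
            tukey_letters({"lonely": [1.0], "other": [1.0, 2.0]})

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_letters_agree_with_pairwise_oracle(self, seed):
        # share a letter iff the Tukey comparison is non-significant
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 7)
        groups = {
            f"g{i}": rng.normal(rng.uniform(0, 4), 1.0, 6) for i in range(k)
        }
        display = tukey_letters(groups, alpha=0.05)
        for gi in groups:
            for gj in groups:
                if gi >= gj:
                    continue
                share = bool(set(display.letters[gi]) & set(display.letters[gj]))
                non_significant = display.p_values.loc[gi, gj] >= 0.05
                assert share == non_significant, (gi, gj)


class TestWardCluster:
    def test_identical_profiles_merge_at_zero(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]],
                                index=["a", "b", "c"])
        result = ward_cluster(profiles)
        assert result.heights[0] == pytest.approx(0.0, abs=1e-12)
        assert result.top_split() in (
            (frozenset({"a", "b"}), frozenset({"c"})),
            (frozenset({"c"}), frozenset({"a", "b"})),
        )

    def test_coincident_pair_merges_first(self):
        profiles = pd.DataFrame(
            [[0.0, 0.0], [5.0, 5.0], [5.0, 5.0]], index=["far", "p1", "p2"]
        )
        result = ward_cluster(profiles, standardize=False)
        first_merge = set(result.linkage[0, :2].astype(int))
        assert first_merge == {1, 2}

    def test_microbial_profiles_isolate_fungi(self, counts_table):
        profiles = counts_table.pivot_table(
            index="variable", columns=["dose", "time"], values="value"
        )
        result = ward_cluster(profiles)
        split = result.top_split()
        assert frozenset({"fungi"}) in split
        assert frozenset({"organotrophic_bacteria", "actinomycetes"}) in split

    def test_heights_non_decreasing_and_order_invariant(self, counts_table):
        profiles = counts_table.pivot_table(
            index="variable", columns=["dose", "time"], values="value"
        )
        result = ward_cluster(profiles)
        assert (np.diff(result.heights) >= -1e-12).all()
        shuffled = ward_cluster(profiles.iloc[::-1])
        assert np.allclose(np.sort(result.heights), np.sort(shuffled.heights))
        assert set(result.top_split()) == set(shuffled.top_split())

    def test_constant_feature_dropped_with_warning(self):
        profiles = pd.DataFrame(
            {"varying": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]},
            index=["a", "b", "c"],
        )
        with pytest.warns(UserWarning, match="flat"):
            result = ward_cluster(profiles)
        assert result.dropped_features == ("flat",)


class TestPCAVariance:
    def test_rank_one_matrix_loads_on_first_component(self):
        base = np.arange(1.0, 7.0)
        matrix = np.column_stack([base, 2 * base, -3 * base])
        result = pca_variance(matrix, method="covariance")
        assert result.percent[0] == pytest.approx(100.0)

    def test_orthogonal_standardized_columns_share_evenly(self):
        # Hadamard columns: zero mean, mutually orthogonal -> identity correlation
        matrix = hadamard(8)[:, 1:6].astype(float)
        result = pca_variance(matrix, method="correlation")
        assert np.allclose(result.percent, 20.0)

    def test_percentages_sum_to_100_and_non_increasing(self, resistance_table_fx):
        cases = resistance_table_fx.pivot_table(
            index=["dose", "time"], columns="variable", values="value"
        )
        result = pca_variance(cases)
        assert sum(result.percent) == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(result.percent) <= 1e-12).all()

    def test_matches_eigendecomposition_oracle(self, resistance_table_fx):
        cases = resistance_table_fx.pivot_table(
            index=["dose", "time"], columns="variable", values="value"
        ).to_numpy()
        result = pca_variance(cases, method="correlation")
        eigenvalues = np.sort(np.linalg.eigvalsh(np.corrcoef(cases, rowvar=False)))[::-1]
        assert np.allclose(result.percent, 100.0 * eigenvalues / eigenvalues.sum())

    def test_case_order_invariance(self, resistance_table_fx):
        cases = resistance_table_fx.pivot_table(
            index=["dose", "time"], columns="variable", values="value"
        ).to_numpy()
        rng = np.random.default_rng(5)
        shuffled = cases[rng.permutation(len(cases))]
        assert np.allclose(
            pca_variance(cases).percent, pca_variance(shuffled).percent
        )

    def test_zero_variance_variable_named(self):
        matrix = pd.DataFrame({"live": [1.0, 2.0, 3.0], "dead": [4.0, 4.0, 4.0]})
        with pytest.raises(DegenerateDataError, match="dead"):
            pca_variance(matrix)
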