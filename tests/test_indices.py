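"""Biological indices (CD, EP, RS, RL) and the PEC dissipation model."""

import math

import numpy as np
import pandas as pd
import pytest

from soilecotox.indices import (
    DomainError,
    EmergenceProfile,
    MissingControlError,
    PairedDisturbance,
    UndefinedIndexError,
    UnderdeterminedError,
    colony_development_index,
    dose_linear_prediction,
    ecophysiological_index,
    effect_delta,
    fit_pec,
    predict_pec,
    resilience_index,
    resilience_table,
    resistance_index,
    resistance_table,
    summarize_index,
    DecayParams,
)


def profile(*counts):
    return EmergenceProfile(tuple(counts))


class TestColonyDevelopment:
    def test_all_first_day_gives_maximum(self):
        assert colony_development_index(profile(100, *[0] * 9)).value == 100.0

    def test_all_last_day_gives_minimum(self):
        assert colony_development_index(profile(*[0] * 9, 50)).value == 10.0

    def test_uniform_profile_equals_harmonic_sum(self):
        # brute-force: p_d = 1/10 each day, CD = 100 * sum(0.1/d) = 10 * H_10
        expected = 10.0 * sum(1.0 / d for d in range(1, 11))
        got = colony_development_index(profile(*[10] * 10)).value
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(29.289682539682538, rel=1e-9)

    def test_all_zero_profile_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            colony_development_index(profile(*[0] * 10))

    def test_window_length_enforced(self):
        with pytest.raises(DomainError):
            EmergenceProfile((1, 2, 3))
        assert EmergenceProfile((1, 2, 3), window=3).total == 6


class TestEcophysiological:
    def test_single_day_concentration_gives_zero(self):
        assert ecophysiological_index(profile(0, 0, 40, *[0] * 7)).value == 0.0

    def test_uniform_profile_gives_one(self):
        assert ecophysiological_index(profile(*[10] * 10)).value == pytest.approx(1.0)

    def test_two_even_days(self):
        # -2 * 0.5 * log10(0.5)
        expected = -2 * 0.5 * math.log10(0.5)
        got = ecophysiological_index(profile(50, 50, *[0] * 8)).value
        assert got == pytest.approx(expected, rel=1e-12)
        assert round(got, 6) == 0.301030

    def test_count_scaling_leaves_cd_and_ep_unchanged(self):
        base = profile(3, 1, 4, 1, 5, 9, 2, 6, 5, 3)
        scaled = profile(*(7 * c for c in base.counts))
        assert colony_development_index(base).value == pytest.approx(
            colony_development_index(scaled).value
        )
        assert ecophysiological_index(base).value == pytest.approx(
            ecophysiological_index(scaled).value
        )


class TestResistance:
    def test_undisturbed_gives_one(self):
        assert resistance_index(PairedDisturbance(5.0, 5.0)).value == 1.0

    def test_complete_suppression_gives_zero(self):
        assert resistance_index(PairedDisturbance(5.0, 0.0)).value == 0.0

    def test_dehydrogenase_day30_cells(self):
        # direct formula on the control/top-dose activities
        c0, p0 = 5.310, 5.087
        d0 = abs(c0 - p0)
        expected = 1 - 2 * d0 / (c0 + d0)
        got = resistance_index(PairedDisturbance(c0, p0)).value
        assert got == pytest.approx(expected, rel=1e-12)
        assert round(got, 6) == 0.919393

    def test_nonpositive_control_rejected(self):
        with pytest.raises(DomainError):
            PairedDisturbance(0.0, 1.0)


class TestResilience:
    def test_full_recovery(self):
        pair = PairedDisturbance(2.0, 1.0, 2.0, 2.0)  # D0=1, Dx=0
        assert resilience_index(pair).value == 1.0

    def test_unchanged_disturbance_gives_zero(self):
        pair = PairedDisturbance(2.0, 1.0, 3.0, 2.0)  # |Dx| == |D0|
        assert resilience_index(pair).value == 0.0

    def test_growing_disturbance(self):
        pair = PairedDisturbance(2.0, 1.0, 5.0, 2.0)  # D0=1, Dx=3
        assert resilience_index(pair).value == pytest.approx(-0.5)

    def test_no_disturbance_is_flagged_missing(self):
        result = resilience_index(PairedDisturbance(2.0, 2.0, 3.0, 3.0))
        assert result.is_missing
        assert "undefined" in result.note

    def test_new_disturbance_warns_and_returns_minus_one(self):
        with pytest.warns(UserWarning, match="follow-up"):
            result = resilience_index(PairedDisturbance(2.0, 2.0, 3.0, 2.0))
        assert result.value == -1.0


class TestIndexTables:
    def test_resistance_table_matches_direct_formula(self, enzyme_table):
        rs = resistance_table(enzyme_table)
        cell = rs.query("variable == 'dehydrogenases' and dose == 22.5 and time == 30")
        assert cell["value"].iloc[0] == pytest.approx(0.919393, abs=5e-7)
        assert len(rs) == 60  # 5 enzymes x 4 doses x 3 times

    def test_resilience_table_matches_direct_formula(self, enzyme_table):
        rl = resilience_table(enzyme_table, t0=30, tx=90)
        d0 = 0.360 - 0.335
        dx = 0.334 - 0.331
        expected = 2 * d0 / (d0 + dx) - 1
        cell = rl.query("variable == 'catalase' and dose == 0.075")
        assert cell["value"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_missing_control_is_reported(self, enzyme_table):
        no_control = enzyme_table[enzyme_table["dose"] > 0]
        with pytest.raises(MissingControlError, match="dose 0"):
            resistance_table(no_control)


class TestPECModel:
    @staticmethod
    def grid_search_oracle(table, span=0.5, steps=101, rounds=8):
        """Brute-force least squares over (ln f, k) by iterative refinement."""
        dose = table["dose"].to_numpy(float)
        t = table["time"].to_numpy(float)
        y = np.log(table["value"].to_numpy(float) / dose)
        lnf_c, k_c = np.mean(y), 0.01
        width_f, width_k = span, 0.02
        for _ in range(rounds):
            lnf_grid = np.linspace(lnf_c - width_f, lnf_c + width_f, steps)
            k_grid = np.linspace(max(k_c - width_k, 1e-6), k_c + width_k, steps)
            sse = (
                (y[None, None, :] - (lnf_grid[:, None, None] - k_grid[None, :, None] * t)) ** 2
            ).sum(axis=2)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            lnf_c, k_c = lnf_grid[i], k_grid[j]
            width_f /= 10
            width_k /= 10
        return math.exp(lnf_c), k_c

    def test_fit_agrees_with_grid_search_oracle(self, pec_table):
        fit = fit_pec(pec_table)
        f_oracle, k_oracle = self.grid_search_oracle(pec_table)
        assert fit.f == pytest.approx(f_oracle, abs=1e-6)
        assert fit.k == pytest.approx(k_oracle, abs=1e-6)
        # half-life on the order of three months
        assert 80.0 < fit.dt50 < 90.0

    def test_noiseless_grid_recovers_parameters_exactly(self):
        f, k = 0.05, 0.01
        rows = [
            (d, t, f * d * math.exp(-k * t))
            for d in (0.075, 2.25, 11.25, 22.5)
            for t in (30, 60, 90)
        ]
        fit = fit_pec(pd.DataFrame(rows, columns=["dose", "time", "value"]))
        assert fit.f == pytest.approx(f, rel=1e-10)
        assert fit.k == pytest.approx(k, rel=1e-10)
        assert fit.log_rmse < 1e-12

    def test_single_time_point_is_underdetermined(self):
        table = pd.DataFrame({"dose": [1.0, 2.0], "time": [30, 30], "value": [0.1, 0.2]})
        with pytest.raises(UnderdeterminedError):
            fit_pec(table)

    def test_nonpositive_concentration_rejected(self):
        table = pd.DataFrame({"dose": [1.0, 1.0], "time": [30, 60], "value": [0.1, 0.0]})
        with pytest.raises(DomainError):
            fit_pec(table)

    def test_predictions(self):
        params = DecayParams(f=0.065, k=0.0082)
        assert predict_pec(params, 0.0, 50.0) == 0.0
        with pytest.raises(DomainError):
            predict_pec(params, -1.0, 10.0)
        # half-life identity
        base = predict_pec(params, 11.25, 40.0)
        assert predict_pec(params, 11.25, 40.0 + params.dt50) == pytest.approx(
            base / 2, rel=1e-12
        )

    def test_single_row_fit_predicts_doubled_dose(self, pec_table):
        row = pec_table[pec_table["dose"] == 11.25]
        fit = fit_pec(row)
        assert round(predict_pec(fit.params, 22.5, 30.0), 3) == 1.466

    def test_dose_linearity_prediction_is_exact(self, pec_table):
        assert dose_linear_prediction(pec_table, 11.25, 22.5, 30) == pytest.approx(
            1.4660, abs=1e-12
        )


class TestEffectDelta:
    def test_fungal_reduction_at_top_dose(self, counts_table):
        delta = effect_delta(counts_table, "fungi", 22.5, 90)
        assert delta.direction == "reduction"
        assert delta.magnitude == pytest.approx(0.426, abs=1e-9)

    def test_actinomycete_increase_at_field_rate(self, counts_table):
        delta = effect_delta(counts_table, "actinomycetes", 0.075, 30)
        assert delta.direction == "increase"
        assert delta.magnitude == pytest.approx(0.215, abs=1e-9)

    def test_control_against_itself_is_zero(self, counts_table):
        delta = effect_delta(counts_table, "fungi", 0.0, 30)
        assert delta.delta == 0.0
        assert delta.direction == "no change"

    def test_missing_control_raises(self, counts_table):
        treated_only = counts_table[counts_table["dose"] > 0]
        with pytest.raises(MissingControlError):
            effect_delta(treated_only, "fungi", 22.5, 90)


class TestSummaries:
    def test_resistance_fixture_grand_means(self, resistance_table_fx):
        summary = summarize_index(resistance_table_fx, by="variable")
        assert round(summary.group_means["dehydrogenases"], 3) == 0.874
        assert round(summary.group_means["urease"], 3) == 0.646
        assert summary.ranking[0] == "dehydrogenases"
        assert summary.ranking[-1] == "urease"

    def test_single_cell_summary(self):
        frame = pd.DataFrame({"variable": ["x"], "value": [0.5]})
        summary = summarize_index(frame)
        assert summary.group_means["x"] == 0.5
        assert summary.minimum == summary.maximum == 0.5

    def test_flagged_missing_group_reported_not_zeroed(self):
        frame = pd.DataFrame(
            {"variable": ["a", "a", "b"], "value": [0.2, 0.4, float("nan")]}
        )
        summary = summarize_index(frame)
        assert summary.missing_groups == ("b",)
        assert "b" not in summary.ranking
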