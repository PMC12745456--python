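"""Regimen analysis: durations above target, steady troughs, cohort summaries."""

import numpy as np
import pytest

import fixsim as fx
from fixsim.exceptions import ConfigError, InvalidRegimenError

from conftest import typical_individual


class TestDurationAbove:
    def test_typical_adult_published_durations(self, theta):
        """The 70-kg typical adult reproduces the published half-day durations."""
        for dose, expected in [(25.0, 7.5), (40.0, 11.0), (100.0, 20.0)]:
            ind = typical_individual(theta, 70.0, dose)
            d = fx.duration_above(ind, 70.0, fx.Regimen(dose_per_kg=dose), [5.0])
            assert d[5.0] == expected, f"{dose} IU/kg"

    def test_unreachable_threshold(self, theta):
        ind = typical_individual(theta, 70.0, 25.0)
        d = fx.duration_above(ind, 70.0, fx.Regimen(dose_per_kg=25.0), [1000.0])
        assert d[1000.0] == 0.0

    def test_monotone_in_dose_and_threshold(self, theta):
        durs = []
        for dose in (25.0, 50.0, 75.0, 100.0):
            ind = typical_individual(theta, 70.0, dose)
            d = fx.duration_above(
                ind, 70.0, fx.Regimen(dose_per_kg=dose), [1.0, 3.0, 5.0], grid=False
            )
            assert d[1.0] >= d[3.0] >= d[5.0]
            durs.append(d[5.0])
        assert np.all(np.diff(durs) > 0.0)

    def test_requires_single_dose_mode(self, theta):
        ind = typical_individual(theta, 70.0, 50.0)
        with pytest.raises(InvalidRegimenError):
            fx.duration_above(ind, 70.0, fx.Regimen(dose_per_kg=50.0, interval_days=7))


class TestSteadyTrough:
    def test_typical_adult_weekly(self, theta):
        """50 IU/kg weekly in the typical 70-kg adult: trough just above 19."""
        ind = typical_individual(theta, 70.0, 50.0)
        t = fx.steady_trough(ind, 70.0, fx.Regimen(dose_per_kg=50.0, interval_days=7))
        assert t == pytest.approx(19.07, abs=0.1)

    def test_washout_limit(self, theta):
        ind = typical_individual(theta, 70.0, 50.0)
        t = fx.steady_trough(ind, 70.0, fx.Regimen(dose_per_kg=50.0, interval_days=5000))
        assert t < 1e-6

    def test_increasing_in_dose(self, theta):
        troughs = []
        for dose in (25.0, 50.0, 75.0, 100.0):
            ind = typical_individual(theta, 70.0, dose)
            troughs.append(
                fx.steady_trough(ind, 70.0, fx.Regimen(dose_per_kg=dose, interval_days=14))
            )
        assert np.all(np.diff(troughs) > 0.0)


class TestSummarizeRegimen:
    def test_degenerate_cohort_collapses(self, theta):
        """One patient, no IIV: every percentile equals the deterministic value."""
        omega0 = fx.IIVParameters(0.0, 0.0, 0.0)
        cohort = fx.generate_cohort({">=18": 1}, seed=0, omega=omega0)
        p = cohort.patients[0]
        reg = fx.Regimen(dose_per_kg=50.0, interval_days=7)
        s = fx.summarize_regimen(cohort, reg, n_replicates=20, seed=1, omega=omega0)
        expected = fx.steady_trough(p.individual_params(50.0), p.weight, reg)
        assert s.trough_median == pytest.approx(expected, rel=1e-12)
        assert s.trough_pi90[0] == pytest.approx(expected, rel=1e-12)
        assert s.trough_pi90[1] == pytest.approx(expected, rel=1e-12)

    def test_attainment_ordering(self, theta):
        cohort = fx.generate_cohort({">=18": 200}, seed=2)
        s = fx.summarize_regimen(
            cohort, fx.Regimen(dose_per_kg=50.0, interval_days=14), n_replicates=20, seed=3
        )
        assert 0.0 <= s.pct_above[5.0] <= s.pct_above[3.0] <= s.pct_above[1.0] <= 100.0
        lo, hi = s.trough_pi90
        assert lo <= s.trough_median <= hi

    def test_age_group_trough_ordering(self):
        """Per-kg clearance ordering makes troughs rise with age group."""
        cohorts = fx.study_cohorts(seed=4, scale=4)
        reg = fx.Regimen(dose_per_kg=50.0, interval_days=7)
        medians = [
            fx.summarize_regimen(cohorts[g], reg, n_replicates=30, seed=5).trough_median
            for g in ("0-<6", "6-<12", "12-<18", ">=18")
        ]
        assert medians[0] < medians[1] < medians[2] <= medians[3] * 1.05

    def test_deterministic_under_seed(self):
        cohort = fx.generate_cohort({">=18": 50}, seed=6)
        reg = fx.Regimen(dose_per_kg=100.0, interval_days=21)
        a = fx.summarize_regimen(cohort, reg, n_replicates=40, seed=7)
        b = fx.summarize_regimen(cohort, reg, n_replicates=40, seed=7)
        assert a == b

    def test_replicate_count_validated(self):
        cohort = fx.generate_cohort({">=18": 2}, seed=0)
        with pytest.raises(ConfigError):
            fx.summarize_regimen(cohort, fx.Regimen(50.0, 7), n_replicates=0)


class TestTables:
    def test_trough_table_structure(self):
        cohorts = fx.study_cohorts(seed=8)
        df = fx.build_trough_table(cohorts, n_replicates=5, seed=9)
        assert len(df) == 8 * 5  # 8 regimens x 5 age-group columns
        assert set(df["age_group"]) == set(fx.regimens.TABLE_GROUPS)

    def test_duration_table_half_day_grid(self):
        cohorts = fx.study_cohorts(seed=10)
        df = fx.build_duration_table(
            cohorts, doses=(50.0,), n_replicates=5, seed=11
        )
        vals = np.concatenate([df["median_days"], df["p25_days"]])
        np.testing.assert_allclose(vals * 2.0, np.round(vals * 2.0), atol=1e-12)

    def test_ethnicity_comparison_no_model_effect(self):
        """Same generator settings: only labels and sampling noise differ."""
        jp = fx.generate_cohort({">=18": 150}, seed=12, japanese=True)
        nonjp = fx.generate_cohort({">=18": 150}, seed=12, japanese=False)
        comp = fx.ethnicity_comparison(
            jp, nonjp, fx.Regimen(dose_per_kg=100.0, interval_days=21), n_replicates=40,
            seed=13,
        )
        a, b = comp["japanese"], comp["non_japanese"]
        assert a.cmax_median == pytest.approx(b.cmax_median, rel=0.1)
        assert a.auc_median == pytest.approx(b.auc_median, rel=0.1)
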