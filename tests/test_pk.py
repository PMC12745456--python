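"""Closed-form two-compartment kinetics against invariants and an ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fixsim as fx
from fixsim.exceptions import InvalidParameterError, InvalidRegimenError

from conftest import ode_concentration


class TestDisposition:
    def test_reference_parameters_slow_rate(self, ref_pk):
        """The adult reference parameters give a ~5.5-day terminal half-life."""
        d = fx.disposition_constants(ref_pk)
        assert d.lambda2 == pytest.approx(0.00527, rel=5e-3)
        assert d.lambda1 > d.lambda2 > 0

    def test_matches_rate_matrix_eigenvalues(self, ref_pk):
        """Macro rates are the eigenvalues of the micro rate-constant matrix."""
        k10 = ref_pk.cl / ref_pk.vc
        k12 = ref_pk.q / ref_pk.vc
        k21 = ref_pk.q / ref_pk.vp
        A = np.array([[-(k10 + k12), k21], [k12, -k21]])
        eig = np.sort(-np.linalg.eigvals(A))
        d = fx.disposition_constants(ref_pk)
        assert d.lambda2 == pytest.approx(eig[0], rel=1e-12)
        assert d.lambda1 == pytest.approx(eig[1], rel=1e-12)

    def test_one_compartment_limit(self):
        """Q = 0 collapses to one compartment: lambda1 = CL/Vc, no slow mode."""
        d = fx.disposition_constants(fx.PKParameters(cl=0.5, vc=50.0, q=0.0, vp=10.0))
        assert d.lambda1 == pytest.approx(0.01, rel=1e-12)
        assert d.lambda2 == 0.0
        assert d.coef_b == 0.0
        assert d.coef_a == pytest.approx(1.0 / 50.0, rel=1e-12)

    @given(
        cl=st.floats(0.05, 5.0),
        vc=st.floats(5.0, 200.0),
        q=st.floats(0.0, 5.0),
        vp=st.floats(1.0, 100.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_invariant(self, cl, vc, q, vp):
        """Bolus coefficients always partition 1/Vc and rates are ordered."""
        d = fx.disposition_constants(fx.PKParameters(cl=cl, vc=vc, q=q, vp=vp))
        assert d.lambda1 >= d.lambda2 >= 0.0
        assert d.coef_a + d.coef_b == pytest.approx(1.0 / vc, rel=1e-9)

    @pytest.mark.parametrize("cl,vc", [(-1.0, 50.0), (0.0, 50.0), (0.5, 0.0)])
    def test_invalid_parameters_rejected(self, cl, vc):
        with pytest.raises(InvalidParameterError):
            fx.PKParameters(cl=cl, vc=vc, q=0.2, vp=10.0)


class TestSingleDose:
    def test_bolus_limit_peak(self, theta):
        """As infusion time -> 0, the peak approaches dose / Vc."""
        pk = fx.typical_parameters(theta, 70.0, 100.0)  # Vc ~ 79.9 dL
        dose = fx.DoseEvent(time=0.0, amount=7000.0, infusion_duration=1e-6)
        peak = fx.single_dose_profile(pk, dose, [1e-6])[0]
        assert peak == pytest.approx(7000.0 / pk.vc, rel=1e-4)
        assert peak == pytest.approx(87.6, rel=2e-3)

    def test_causality(self, ref_pk):
        dose = fx.DoseEvent(time=24.0, amount=3500.0)
        prof = fx.single_dose_profile(ref_pk, dose, [0.0, 12.0, 23.9, 25.0])
        assert np.all(prof[:3] == 0.0)
        assert prof[3] > 0.0

    @pytest.mark.parametrize(
        "weight,dose_per_kg",
        [(70.0, 50.0), (70.0, 100.0), (16.5, 50.0), (40.0, 25.0)],
    )
    def test_matches_ode_oracle(self, theta, weight, dose_per_kg):
        """Closed form agrees with adaptive ODE integration to <= 0.1%."""
        pk = fx.typical_parameters(theta, weight, dose_per_kg)
        dose = fx.DoseEvent(time=0.0, amount=dose_per_kg * weight)
        times = np.linspace(0.05, 504.0, 60)
        closed = fx.single_dose_profile(pk, dose, times)
        oracle = ode_concentration(pk, [dose], times)
        assert np.max(np.abs(closed - oracle) / oracle) < 1e-3

    @given(
        cl=st.floats(0.1, 2.0),
        vc=st.floats(10.0, 150.0),
        q=st.floats(0.01, 2.0),
        vp=st.floats(2.0, 80.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_ode_on_random_parameters(self, cl, vc, q, vp):
        pk = fx.PKParameters(cl=cl, vc=vc, q=q, vp=vp)
        dose = fx.DoseEvent(time=0.0, amount=3000.0)
        times = np.linspace(0.5, 336.0, 25)
        closed = fx.single_dose_profile(pk, dose, times)
        oracle = ode_concentration(pk, [dose], times)
        scale = np.maximum(oracle, 1e-9 * oracle.max())
        assert np.max(np.abs(closed - oracle) / scale) < 1e-3

    def test_nonnegative_and_monotone_after_infusion(self, ref_pk):
        dose = fx.DoseEvent(time=0.0, amount=3500.0)
        t = np.linspace(fx.DEFAULT_INFUSION_DURATION_H, 1000.0, 400)
        prof = fx.single_dose_profile(ref_pk, dose, t)
        assert np.all(prof >= 0.0)
        assert np.all(np.diff(prof) <= 0.0)


class TestSuperposition:
    def test_equals_sum_of_shifted_profiles(self, ref_pk):
        tau = 168.0
        d1 = fx.DoseEvent(time=0.0, amount=3500.0)
        d2 = fx.DoseEvent(time=tau, amount=3500.0)
        t = np.linspace(tau + 1.0, 3.0 * tau, 40)
        total = fx.superpose(ref_pk, [d1, d2], t)
        parts = fx.single_dose_profile(ref_pk, d1, t) + fx.single_dose_profile(
            ref_pk, d2, t
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12)

    def test_single_dose_identity_and_empty(self, ref_pk):
        d = fx.DoseEvent(time=0.0, amount=3500.0)
        t = np.linspace(0.0, 300.0, 20)
        np.testing.assert_array_equal(
            fx.superpose(ref_pk, [d], t), fx.single_dose_profile(ref_pk, d, t)
        )
        assert np.all(fx.superpose(ref_pk, [], t) == 0.0)

    def test_unsorted_doses_rejected(self, ref_pk):
        with pytest.raises(InvalidRegimenError):
            fx.superpose(
                ref_pk,
                [fx.DoseEvent(time=24.0, amount=100.0), fx.DoseEvent(time=0.0, amount=100.0)],
                [50.0],
            )

    def test_weekly_doses_match_ode(self, ref_pk):
        doses = [fx.DoseEvent(time=168.0 * k, amount=3500.0) for k in range(7)]
        times = np.linspace(1.0, 7 * 168.0, 50)
        closed = fx.superpose(ref_pk, doses, times)
        oracle = ode_concentration(ref_pk, doses, times)
        assert np.max(np.abs(closed - oracle) / oracle) < 1e-3


class TestSteadyState:
    def test_matches_long_superposition(self, ref_pk):
        """Accumulation factors equal simulating 30 weekly doses (last interval)."""
        tau, amount = 168.0, 3500.0
        t_in = np.linspace(1.0, tau, 30)
        ss = fx.steady_state_profile(ref_pk, amount, tau, times_in_interval=t_in)
        doses = [fx.DoseEvent(time=tau * k, amount=amount) for k in range(30)]
        brute = fx.superpose(ref_pk, doses, 29.0 * tau + t_in)
        assert np.max(np.abs(ss - brute) / brute) < 5e-3

    def test_no_accumulation_limit(self, ref_pk):
        """tau -> infinity reduces the steady state to a single dose."""
        t_in = np.linspace(1.0, 504.0, 20)
        ss = fx.steady_state_profile(ref_pk, 3500.0, 1e7, times_in_interval=t_in)
        single = fx.single_dose_profile(
            ref_pk, fx.DoseEvent(time=0.0, amount=3500.0), t_in
        )
        np.testing.assert_allclose(ss, single, rtol=1e-9)

    def test_auc_equals_dose_over_clearance(self, ref_pk):
        """AUC over one steady-state interval is dose/CL (clearance identity)."""
        tau, amount = 168.0, 7000.0
        t_in = np.linspace(0.0, tau, 20001)
        prof = fx.steady_state_profile(ref_pk, amount, tau, times_in_interval=t_in)
        auc = np.trapezoid(prof, t_in)
        assert auc == pytest.approx(amount / ref_pk.cl, rel=2e-3)
        m = fx.exposure_metrics(ref_pk, amount, tau)
        assert m.auc_ss == pytest.approx(12727.0, rel=1e-3)

    def test_exposure_ordering_and_washout(self, ref_pk):
        m = fx.exposure_metrics(ref_pk, 3500.0, 168.0)
        assert m.cmax >= m.ctrough > 0.0
        far = fx.exposure_metrics(ref_pk, 3500.0, 24_000.0)
        assert far.ctrough < 1e-6

    def test_invalid_interval_rejected(self, ref_pk):
        with pytest.raises(InvalidRegimenError):
            fx.steady_state_profile(ref_pk, 3500.0, -7.0)
        with pytest.raises(InvalidRegimenError):
            fx.steady_state_profile(ref_pk, 3500.0, 168.0, times_in_interval=[200.0])
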