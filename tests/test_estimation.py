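"""Laplace objective, fitting, LRT cutoffs and the pcVPC table."""

import numpy as np
import pandas as pd
import pytest

import fixsim as fx
from fixsim.estimation import DEFAULT_FIXED
from fixsim.exceptions import ConfigError


@pytest.fixture(scope="module")
def small_dataset(sigma):
    """20 patients, 8 samples each, residual noise per the late-study group."""
    cohort = fx.generate_cohort(
        {"0-<6": 2, "6-<12": 3, "12-<18": 1, ">=18": 14}, seed=100
    )
    times = [0.0, 1.0, 8.0, 24.0, 72.0, 168.0, 336.0, 504.0]
    return fx.simulate_dataset(cohort, 50.0, times, sigma=sigma, seed=101)


class TestObjectiveFunction:
    def test_reduces_to_weighted_deviance_without_iiv(self, theta, small_dataset):
        """With omega = 0 the Laplace OFV equals the closed-form log-scale
        weighted deviance, computed here independently with pandas/numpy."""
        omega0 = fx.IIVParameters(0.0, 0.0, 0.0)
        sig = fx.ResidualError(0.0, 0.0, 0.0, 1.5)  # additive-only, group 2
        got = fx.objective_function(small_dataset, theta, omega0, sig)

        obs = small_dataset[small_dataset["EVID"] == 0]
        expected = 0.0
        for pid, g in obs.groupby("ID"):
            row = small_dataset[small_dataset["ID"] == pid].iloc[0]
            wt = row["WT"]
            pk = fx.typical_parameters(theta, wt, 50.0)
            fex = fx.single_dose_profile(
                pk, fx.DoseEvent(time=0.0, amount=50.0 * wt), g["TIME"].to_numpy()
            )
            pred = np.maximum(fex + theta.base_activity, 1e-3)
            v = (1.5 / pred) ** 2
            r = np.log(np.maximum(g["DV"].to_numpy(), 1e-3)) - np.log(pred)
            expected += np.sum(np.log(2 * np.pi * v) + r * r / v)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_independent_individuals_add(self, theta, omega, sigma, small_dataset):
        """Duplicating every individual under new IDs doubles the OFV."""
        single = fx.objective_function(small_dataset, theta, omega, sigma)
        clone = small_dataset.copy()
        clone["ID"] = clone["ID"] + 1000
        doubled = pd.concat([small_dataset, clone], ignore_index=True)
        assert fx.objective_function(doubled, theta, omega, sigma) == pytest.approx(
            2.0 * single, rel=1e-9
        )

    def test_likelihood_prefers_generating_parameters(self, theta, omega, sigma):
        """On a large simulated dataset the OFV at the truth beats a 30%
        clearance perturbation."""
        cohort = fx.generate_cohort({">=18": 200}, seed=102)
        times = [0.0, 1.0, 8.0, 24.0, 72.0, 168.0, 336.0, 504.0]
        df = fx.simulate_dataset(cohort, 50.0, times, sigma=sigma, seed=103)
        at_truth = fx.objective_function(df, theta, omega, sigma)
        from dataclasses import replace

        perturbed = replace(theta, cl_70=theta.cl_70 * 1.3)
        assert at_truth < fx.objective_function(df, perturbed, omega, sigma)


class TestFit:
    def test_noiseless_single_individual_curve_fit(self, theta):
        """Rich noiseless data from one subject: CL, Vc, Q, Vp to <= 0.5%."""
        omega0 = fx.IIVParameters(0.0, 0.0, 0.0)
        cohort = fx.generate_cohort({">=18": 1}, seed=104, omega=omega0)
        times = [0.5, 1, 2, 4, 8, 16, 24, 48, 72, 120, 168, 240, 336, 420, 504]
        df = fx.simulate_dataset(cohort, 50.0, times, sigma=None, seed=105)
        from dataclasses import replace

        start = replace(
            theta, cl_70=theta.cl_70 * 1.3, vc_ref=theta.vc_ref * 0.7,
            q=theta.q * 1.3, vp_70=theta.vp_70 * 0.7,
        )
        small_sigma = fx.ResidualError(0.0, 0.0, 0.02, 0.0)
        res = fx.fit(
            df, start, omega0, small_sigma,
            fixed=DEFAULT_FIXED + ("base_activity", "prop_sd_group2", "add_sd_group2"),
        )
        assert res.converged
        assert res.theta.cl_70 == pytest.approx(theta.cl_70, rel=5e-3)
        assert res.theta.vc_ref == pytest.approx(theta.vc_ref, rel=5e-3)
        assert res.theta.q == pytest.approx(theta.q, rel=5e-3)
        assert res.theta.vp_70 == pytest.approx(theta.vp_70, rel=5e-3)

    def test_reports_standard_errors(self, theta, sigma, small_dataset):
        """Hessian-based SEs come back finite for the estimated parameters."""
        omega0 = fx.IIVParameters(0.0, 0.0, 0.0)
        res = fx.fit(
            small_dataset, theta, omega0, sigma,
            fixed=DEFAULT_FIXED + ("q", "vp_70"),
            maxiter=30, compute_se=True,
        )
        assert set(res.standard_errors) >= {"cl_70", "vc_ref", "base_activity"}
        for name, se in res.standard_errors.items():
            assert np.isfinite(se) and se >= 0.0, name


class TestLRT:
    def test_chi_squared_cutoffs_to_four_decimals(self):
        """Forward 6.6349 (p=0.01), backward 10.8276 (p=0.001) at df=1."""
        fwd = fx.lrt_decision(10.0, 0.0, df=1, stage="forward")
        bwd = fx.lrt_decision(10.0, 0.0, df=1, stage="backward")
        assert fwd.cutoff == pytest.approx(6.6349, abs=5e-5)
        assert bwd.cutoff == pytest.approx(10.8276, abs=5e-5)

    def test_backward_threshold_rule(self):
        assert fx.lrt_decision(11.0, 0.0, df=1, stage="backward").significant
        assert not fx.lrt_decision(10.0, 0.0, df=1, stage="backward").significant

    def test_negative_delta_warns_not_significant(self):
        with pytest.warns(UserWarning):
            out = fx.lrt_decision(5.0, 6.0, df=1, stage="forward")
        assert not out.significant
        assert out.delta_ofv == pytest.approx(-1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            fx.lrt_decision(1.0, 0.0, df=0)
        with pytest.raises(ConfigError):
            fx.lrt_decision(1.0, 0.0, stage="sideways")


class TestPcVpc:
    def test_correction_factor_one_for_homogeneous_cohort(self, theta, omega, sigma):
        """Identical covariates => equal population predictions => the
        corrected observed percentiles equal the raw ones."""
        omega0 = fx.IIVParameters(0.0, 0.0, 0.0)
        cohort = fx.generate_cohort({">=18": 12}, seed=106, omega=omega0)
        # same weight for everyone: rebuild patients at the median weight
        from dataclasses import replace as dc_replace

        w = float(np.median(cohort.weights))
        patients = tuple(dc_replace(p, weight=w) for p in cohort.patients)
        cohort = fx.Cohort(patients=patients, seed=cohort.seed)
        times = [24.0, 168.0, 504.0]
        df = fx.simulate_dataset(cohort, 50.0, times, sigma=sigma, seed=107)
        tab = fx.pcvpc(df, theta, omega, sigma, n_simulations=50, bins=3, seed=108)
        obs = df[df["EVID"] == 0]
        for _, row in tab.iterrows():
            raw = obs[obs["TIME"] == row["t_mid_h"]]["DV"]
            assert row["obs_p50"] == pytest.approx(float(np.median(raw)), rel=1e-9)

    def test_table_structure(self, theta, omega, sigma, small_dataset):
        tab = fx.pcvpc(small_dataset, theta, omega, sigma, n_simulations=40, bins=5, seed=109)
        for col in (
            "obs_p5", "obs_p50", "obs_p95",
            "sim_p5_median", "sim_p50_median", "sim_p95_median",
            "sim_p50_lo", "sim_p50_hi", "n_obs",
        ):
            assert col in tab.columns
        assert (tab["n_obs"] > 0).all()
        assert (tab["obs_p5"] <= tab["obs_p50"]).all()
        assert (tab["obs_p50"] <= tab["obs_p95"]).all()
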