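"""Shared fixtures: reference model blocks and an independent ODE oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import fixsim as fx


@pytest.fixture(scope="session")
def theta() -> fx.FixedEffects:
    return fx.reference_fixed_effects()


@pytest.fixture(scope="session")
def omega() -> fx.IIVParameters:
    return fx.reference_iiv()


@pytest.fixture(scope="session")
def sigma() -> fx.ResidualError:
    return fx.reference_residual_error()


@pytest.fixture(scope="session")
def ref_pk(theta) -> fx.PKParameters:
    """Typical two-compartment parameters of the 70-kg reference patient."""
    return fx.typical_parameters(theta, 70.0, 50.0)


def typical_individual(theta, weight: float, dose_per_kg: float) -> fx.IndividualParams:
    """Individual at the typical (median) parameters for given covariates."""
    pk = fx.typical_parameters(theta, weight, dose_per_kg)
    return fx.IndividualParams(
        cl=pk.cl, vc=pk.vc, q=pk.q, vp=pk.vp, base=theta.base_activity
    )


def ode_profile(pk: fx.PKParameters, doses, times, rtol=1e-10, atol=1e-12):
    """Numerically integrate the two-compartment infusion ODE system.

    Independent oracle for the closed-form evaluator: central/peripheral
    amounts A1, A2 follow

        dA1/dt = rate_in(t) - (k10 + k12) A1 + k21 A2
        dA2/dt = k12 A1 - k21 A2,   C = A1 / Vc

    integrated segment-by-segment between infusion switch points so the
    piecewise-constant input never crosses a discontinuity inside a solver
    step.
    """
    times = np.asarray(times, dtype=float)
    k10 = pk.cl / pk.vc
    k12 = pk.q / pk.vc
    k21 = pk.q / pk.vp if pk.vp > 0 else 0.0

    breaks = sorted(
        {0.0}
        | {d.time for d in doses}
        | {d.time + d.infusion_duration for d in doses}
        | {float(times.max())}
    )
    breaks = [b for b in breaks if b <= float(times.max())]
    if breaks[-1] < float(times.max()):
        breaks.append(float(times.max()))

    def rhs(t, y, rate):
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    y = np.zeros(2)
    out = np.zeros_like(times)
    out[times <= breaks[0]] = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        rate = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.time <= lo and lo < d.time + d.infusion_duration
        )
        mask = (times > lo) & (times <= hi)
        t_eval = np.concatenate([times[mask], [hi]])
        sol = solve_ivp(
            rhs,
            (lo, hi),
            y,
            t_eval=np.unique(t_eval),
            args=(rate,),
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        lookup = dict(zip(sol.t, sol.y[0]))
        for i in np.where(mask)[0]:
            out[i] = lookup[times[i]]
        y = sol.y[:, -1]
    return out


def ode_concentration(pk, doses, times, **kw):
    """Activity (IU/dL) from the ODE oracle: central amount over Vc."""
    return ode_profile(pk, doses, times, **kw) / pk.vc
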