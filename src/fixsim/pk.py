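"""Closed-form two-compartment intravenous-infusion kinetics.

The disposition of factor IX activity after intravenous dosing is described by
a linear two-compartment model parameterized by clearance ``CL`` (dL/h),
central volume ``Vc`` (dL), inter-compartmental clearance ``Q`` (dL/h) and
peripheral volume ``Vp`` (dL).  All evaluation goes through the macro-constant
(biexponential) solution: the concentration after a unit intravenous bolus is

    C(t) = A * exp(-lambda1 * t) + B * exp(-lambda2 * t)

where ``lambda1 >= lambda2`` are the roots of

    lambda^2 - (k10 + k12 + k21) * lambda + k10 * k21 = 0

with micro rate constants ``k10 = CL/Vc``, ``k12 = Q/Vc``, ``k21 = Q/Vp``,
and ``A + B = 1/Vc`` so that ``C(0) = 1/Vc``.  Zero-order infusions, dose
superposition and steady state under repeated dosing all follow analytically
from the two exponential modes; steady state uses the accumulation factor
``1/(1 - exp(-lambda * tau))`` per mode.  The closed form is exact for linear
kinetics, which makes it both the reference evaluator and fast enough for
Monte-Carlo cohort work (the module also exposes private array kernels used by
the regimen engine).

Units are IU, dL and hours throughout; activities come out in IU/dL, which
for factor IX is numerically identical to percent of normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidParameterError, InvalidRegimenError

#: Default infusion duration: a 10-minute intravenous infusion.
DEFAULT_INFUSION_DURATION_H = 1.0 / 6.0

# Relative eigenvalue gap below which the biexponential is numerically
# degenerate and the model collapses to one compartment with pooled volume.
_DEGENERATE_GAP = 1e-10


@dataclass(frozen=True)
class PKParameters:
    """Structural two-compartment parameters for one (typical or individual) subject.

    Attributes
    ----------
    cl : float
        Clearance, dL/h.  Strictly positive.
    vc : float
        Central volume of distribution, dL.  Strictly positive.
    q : float
        Inter-compartmental clearance, dL/h.  Non-negative; ``q == 0``
        degenerates to a one-compartment model.
    vp : float
        Peripheral volume of distribution, dL.  Strictly positive whenever
        ``q > 0``.
    """

    cl: float
    vc: float
    q: float
    vp: float

    def __post_init__(self) -> None:
        if not (self.cl > 0.0):
            raise InvalidParameterError(f"CL must be > 0, got {self.cl}")
        if not (self.vc > 0.0):
            raise InvalidParameterError(f"Vc must be > 0, got {self.vc}")
        if self.q < 0.0:
            raise InvalidParameterError(f"Q must be >= 0, got {self.q}")
        if self.q > 0.0 and not (self.vp > 0.0):
            raise InvalidParameterError(
                f"Vp must be > 0 when Q > 0, got Vp={self.vp}"
            )
        if self.vp < 0.0:
            raise InvalidParameterError(f"Vp must be >= 0, got {self.vp}")


@dataclass(frozen=True)
class Disposition:
    """Macro-constant re-parameterization of the two-compartment model.

    ``lambda1 >= lambda2 >= 0`` are the fast and slow disposition rate
    constants (1/h); ``coef_a`` and ``coef_b`` partition a unit bolus so that
    ``coef_a + coef_b == 1/Vc`` (units IU/dL per IU dosed).
    """

    lambda1: float
    lambda2: float
    coef_a: float
    coef_b: float


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order intravenous infusion.

    ``time`` is hours since the first dose, ``amount`` is IU, and
    ``infusion_duration`` defaults to the 10-minute infusion used for
    regimen simulation.
    """

    time: float
    amount: float
    infusion_duration: float = DEFAULT_INFUSION_DURATION_H

    def __post_init__(self) -> None:
        if self.time < 0.0:
            raise InvalidRegimenError(f"dose time must be >= 0, got {self.time}")
        if not (self.amount > 0.0):
            raise InvalidRegimenError(f"dose amount must be > 0, got {self.amount}")
        if not (self.infusion_duration > 0.0):
            raise InvalidRegimenError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summary for one subject and regimen."""

    cmax: float       # IU/dL, activity at end of infusion at steady state
    ctrough: float    # IU/dL, activity at the end of the dosing interval
    auc_ss: float     # IU*h/dL, area under one steady-state interval = dose/CL


# ---------------------------------------------------------------------------
# array kernels (also used by the cohort/regimen engine)
# ---------------------------------------------------------------------------

def _macro_arrays(cl, vc, q, vp):
    """Vectorized macro constants (lambda1, lambda2, coef_a, coef_b).

    Accepts scalars or broadcastable arrays.  Handles the one-compartment
    limit (``q == 0``) and the repeated-root degeneracy (relative eigenvalue
    gap < 1e-10), which is resolved as one compartment with pooled volume.
    """
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    q = np.asarray(q, dtype=float)
    vp = np.asarray(vp, dtype=float)

    k10 = cl / vc
    k12 = q / vc
    vp_safe = np.where(vp > 0.0, vp, 1.0)
    k21 = np.where(vp > 0.0, q / vp_safe, 0.0)

    s = k10 + k12 + k21
    prod = k10 * k21
    disc = np.maximum(s * s - 4.0 * prod, 0.0)
    root = np.sqrt(disc)
    lam1 = 0.5 * (s + root)
    lam2 = 0.5 * (s - root)

    degenerate = (lam1 - lam2) <= _DEGENERATE_GAP * lam1
    denom = np.where(degenerate, 1.0, (lam1 - lam2) * vc)
    coef_a = np.where(degenerate, 1.0 / (vc + vp), (lam1 - k21) / denom)
    coef_b = np.where(degenerate, 0.0, (k21 - lam2) / denom)
    lam1 = np.where(degenerate, cl / (vc + vp), lam1)
    lam2 = np.where(degenerate, 0.0, lam2)
    return lam1, lam2, coef_a, coef_b


def _infusion_term(lam, coef, rate, dur, t):
    """One exponential mode of a zero-order infusion started at t=0.

    ``C_mode(t) = rate*coef/lam * (1 - exp(-lam*min(t,dur))) * exp(-lam*max(t-dur,0))``
    with the ``lam -> 0`` limit ``rate*coef*min(t,dur)``.  Zero for ``t <= 0``.
    All arguments broadcast.
    """
    t = np.asarray(t, dtype=float)
    tcap = np.minimum(np.maximum(t, 0.0), dur)
    tail = np.maximum(t - dur, 0.0)
    lam_safe = np.where(lam > 0.0, lam, 1.0)
    val = np.where(
        lam > 0.0,
        rate * coef / lam_safe * (-np.expm1(-lam_safe * tcap)) * np.exp(-lam_safe * tail),
        rate * coef * tcap,
    )
    return np.where(t > 0.0, val, 0.0)


def _single_dose_arrays(lam1, lam2, coef_a, coef_b, amount, dur, t):
    """Exogenous activity of a single infusion for vectorized parameters."""
    rate = amount / dur
    return (_infusion_term(lam1, coef_a, rate, dur, t)
            + _infusion_term(lam2, coef_b, rate, dur, t))


def _ss_term(lam, coef, rate, dur, tau, t):
    """One exponential mode of the within-interval steady-state profile.

    Valid for ``0 <= t <= tau``; each mode of the single-dose solution is
    scaled by its accumulation factor ``1/(1 - exp(-lam*tau))``.  Modes with
    ``lam == 0`` must carry ``coef == 0`` (they would accumulate without
    bound) and contribute nothing.
    """
    t = np.asarray(t, dtype=float)
    lam_safe = np.where(lam > 0.0, lam, 1.0)
    e_tau = np.exp(-lam_safe * tau)
    af = 1.0 / (-np.expm1(-lam_safe * tau))
    base = rate * coef / lam_safe
    pulse = -np.expm1(-lam_safe * dur)          # 1 - exp(-lam*dur)
    decay = np.exp(-lam_safe * (t - dur))       # only used where t >= dur
    during = base * ((-np.expm1(-lam_safe * t)) + e_tau * af * pulse * decay)
    after = base * af * pulse * decay
    return np.where(lam > 0.0, np.where(t <= dur, during, after), 0.0)


def _ss_value_arrays(lam1, lam2, coef_a, coef_b, amount, tau, dur, t):
    """Steady-state activity at within-interval time(s) ``t`` (vectorized)."""
    rate = amount / dur
    return (_ss_term(lam1, coef_a, rate, dur, tau, t)
            + _ss_term(lam2, coef_b, rate, dur, tau, t))


# ---------------------------------------------------------------------------
# public scalar API
# ---------------------------------------------------------------------------

def disposition_constants(pk: PKParameters) -> Disposition:
    """Macro disposition constants of a two-compartment model.

    Returns the biexponential rates and unit-bolus coefficients; the
    coefficients satisfy ``coef_a + coef_b == 1/Vc``.  With ``Q == 0`` the
    result degenerates to one compartment (``lambda2 == coef_b == 0``).
    """
    lam1, lam2, a, b = _macro_arrays(pk.cl, pk.vc, pk.q, pk.vp)
    return Disposition(float(lam1), float(lam2), float(a), float(b))


def single_dose_profile(
    pk: PKParameters, dose: DoseEvent, times: Sequence[float]
) -> np.ndarray:
    """Exogenous activity (IU/dL) of one infusion at the requested times.

    Times before the start of the infusion return 0 (causality); the profile
    is continuous at the end of infusion and decays to 0 as ``t -> inf``.
    """
    times = np.asarray(times, dtype=float)
    lam1, lam2, a, b = _macro_arrays(pk.cl, pk.vc, pk.q, pk.vp)
    return _single_dose_arrays(
        lam1, lam2, a, b, dose.amount, dose.infusion_duration, times - dose.time
    )


def superpose(
    pk: PKParameters, doses: Sequence[DoseEvent], times: Sequence[float]
) -> np.ndarray:
    """Total exogenous activity of a sequence of doses (linear superposition).

    ``doses`` must be sorted by time; an empty list yields an all-zero profile.
    """
    times = np.asarray(times, dtype=float)
    if len(doses) == 0:
        return np.zeros_like(times)
    dose_times = [d.time for d in doses]
    if any(t1 > t2 for t1, t2 in zip(dose_times, dose_times[1:])):
        raise InvalidRegimenError("doses must be sorted by time")
    lam1, lam2, a, b = _macro_arrays(pk.cl, pk.vc, pk.q, pk.vp)
    total = np.zeros_like(times)
    for d in doses:
        total += _single_dose_arrays(
            lam1, lam2, a, b, d.amount, d.infusion_duration, times - d.time
        )
    return total


def steady_state_profile(
    pk: PKParameters,
    dose_amount: float,
    tau: float,
    infusion_duration: float = DEFAULT_INFUSION_DURATION_H,
    times_in_interval: Sequence[float] | None = None,
) -> np.ndarray:
    """Within-interval steady-state profile under repeated dosing every ``tau`` h.

    Each exponential mode of the single-dose solution is multiplied by its
    accumulation factor ``1/(1 - exp(-lambda*tau))``.  ``times_in_interval``
    must lie in ``[0, tau]``; the default is a 200-point grid over the interval.
    """
    if not (tau > 0.0):
        raise InvalidRegimenError(f"dosing interval must be > 0, got {tau}")
    if not (dose_amount > 0.0):
        raise InvalidRegimenError(f"dose amount must be > 0, got {dose_amount}")
    if not (0.0 < infusion_duration <= tau):
        raise InvalidRegimenError(
            f"infusion duration must lie in (0, tau], got {infusion_duration}"
        )
    if times_in_interval is None:
        times_in_interval = np.linspace(0.0, tau, 200)
    t = np.asarray(times_in_interval, dtype=float)
    if np.any(t < 0.0) or np.any(t > tau):
        raise InvalidRegimenError("times_in_interval must lie within [0, tau]")
    lam1, lam2, a, b = _macro_arrays(pk.cl, pk.vc, pk.q, pk.vp)
    return _ss_value_arrays(lam1, lam2, a, b, dose_amount, tau, infusion_duration, t)


def exposure_metrics(
    pk: PKParameters,
    dose_amount: float,
    tau: float,
    infusion_duration: float = DEFAULT_INFUSION_DURATION_H,
) -> ExposureMetrics:
    """Steady-state Cmax, Ctrough and AUC over one dosing interval.

    ``Cmax`` is the activity at the end of infusion, ``Ctrough`` the activity
    at ``t == tau``, and ``AUC_ss == dose/CL`` (exact for linear kinetics).
    """
    prof = steady_state_profile(
        pk, dose_amount, tau, infusion_duration, [infusion_duration, tau]
    )
    return ExposureMetrics(
        cmax=float(prof[0]),
        ctrough=float(prof[1]),
        auc_ss=dose_amount / pk.cl,
    )
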