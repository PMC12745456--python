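"""Covariate model: body weight and weight-adjusted dose to typical PK parameters.

The final covariate model retains two continuous covariates, entering as
power laws on the natural scale (equivalently, linear effects on the
log-transformed parameters):

    CL = theta_CL * (WT / 70)^0.528
    Vc = theta_Vc * (WT / 70)^0.771 * (DOSE_PER_KG / 50)^0.281
    Vp = theta_Vp * (WT / 70)^0.771
    Q  = theta_Q

centered at a 70-kg reference patient and a 50 IU/kg reference
weight-adjusted dose.  Age is deliberately not a covariate: after accounting
for body weight it carries no additional information, and it enters the
package only through the weight distributions of the cohort generator.
Ethnicity likewise has no parameter effect and survives only as a cohort
label.

Because the clearance exponent is below 1, per-kilogram clearance decreases
monotonically with weight — the mechanism behind the faster per-kg clearance
(and lower troughs) in young children.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .exceptions import ConfigError, InvalidCovariateError
from .pk import PKParameters

#: Reference body weight (kg) at which the typical volumes and clearance apply.
REF_WEIGHT_KG = 70.0
#: Reference weight-adjusted dose (IU/kg) for the central-volume dose effect.
REF_DOSE_PER_KG = 50.0


@dataclass(frozen=True)
class FixedEffects:
    """Population typical values and covariate exponents of the final model.

    ``base_activity`` is the typical endogenous baseline (IU/dL); ``cl_70``,
    ``vc_ref``, ``q`` and ``vp_70`` are the typical disposition parameters at
    the reference covariates; the three exponents scale clearance and volumes
    with body weight and central volume with weight-adjusted dose.
    """

    base_activity: float
    cl_70: float
    vc_ref: float
    q: float
    vp_70: float
    exp_wt_cl: float
    exp_wt_v: float
    exp_dose_vc: float

    def __post_init__(self) -> None:
        for name in ("base_activity", "cl_70", "vc_ref", "vp_70"):
            if not (getattr(self, name) > 0.0):
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.q < 0.0:
            raise ConfigError(f"q must be >= 0, got {self.q}")
        import math

        for name in ("exp_wt_cl", "exp_wt_v", "exp_dose_vc"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


def typical_parameters(
    theta: FixedEffects, weight: float, dose_per_kg: float = REF_DOSE_PER_KG
) -> PKParameters:
    """Typical two-compartment parameters for a patient of given weight and dose.

    At the reference covariates (70 kg, 50 IU/kg) the output equals the
    typical values exactly; scaling weight by ``s`` scales CL by
    ``s**exp_wt_cl`` and the volumes by ``s**exp_wt_v``.
    """
    if not (weight > 0.0):
        raise InvalidCovariateError(f"weight must be > 0 kg, got {weight}")
    if not (dose_per_kg > 0.0):
        raise InvalidCovariateError(
            f"weight-adjusted dose must be > 0 IU/kg, got {dose_per_kg}"
        )
    wt_frac = weight / REF_WEIGHT_KG
    return PKParameters(
        cl=theta.cl_70 * wt_frac ** theta.exp_wt_cl,
        vc=theta.vc_ref
        * wt_frac ** theta.exp_wt_v
        * (dose_per_kg / REF_DOSE_PER_KG) ** theta.exp_dose_vc,
        q=theta.q,
        vp=theta.vp_70 * wt_frac ** theta.exp_wt_v,
    )


def per_kg_clearance(theta: FixedEffects, weight: float) -> float:
    """Typical clearance per kilogram of body weight (dL/h/kg).

    Strictly decreasing in weight whenever ``exp_wt_cl < 1``.
    """
    if not (weight > 0.0):
        raise InvalidCovariateError(f"weight must be > 0 kg, got {weight}")
    return theta.cl_70 * (weight / REF_WEIGHT_KG) ** theta.exp_wt_cl / weight


def weight_for_per_kg_clearance(
    theta: FixedEffects,
    target: float,
    lo: float = 0.5,
    hi: float = 500.0,
) -> float:
    """Back-solve the body weight whose typical per-kg clearance equals ``target``.

    Used to calibrate age-group weight distributions so that a group's median
    typical per-kg clearance matches a published post-hoc median.  Raises
    :class:`ConfigError` when no root exists in the plausible weight bracket.
    """
    if not (target > 0.0):
        raise ConfigError(f"per-kg clearance target must be > 0, got {target}")

    def f(w: float) -> float:
        return per_kg_clearance(theta, w) - target

    if f(lo) * f(hi) > 0.0:
        raise ConfigError(
            f"per-kg clearance {target} not attainable for weights in "
            f"[{lo}, {hi}] kg"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
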