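"""Composition of total observed FIX activity.

The observed activity FTOT is the sum of three non-negative components:

    FTOT = FEX + BASE + FPP

* ``FEX`` — exogenous activity from the administered drug (the kinetic model);
* ``BASE`` — the patient's endogenous baseline, constrained to <= 2 IU/dL
  (study inclusion required moderate-to-severe disease);
* ``FPP`` — residual activity from the FIX product the patient received
  before the first study dose, decaying mono-exponentially from the observed
  pre-first-dose level BSE with the same CL/Vc as the study drug:

      FPP(t) = BSE * exp(-(CL/Vc) * t)

  and hard-zeroed once it falls below the smallest of (BSE, the screening
  activity, 2 IU/dL).  The zeroing time is computed analytically, so the
  rule is stateless and deterministic.

Regimen simulations of new dosing scenarios report the exogenous component
only (troughs in the summary tables are "exogenous FIX activity"); BASE and
FPP matter for fitting observed datasets, where they keep the endogenous and
carry-over contributions out of the drug's parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError

#: Endogenous baseline cap (IU/dL) implied by the study inclusion criteria.
MAX_BASE_IU_DL = 2.0

#: Zeroing floor for prior-product activity (IU/dL), approximating the
#: assay's practical lower limit.
FPP_FLOOR_IU_DL = 2.0


@dataclass(frozen=True)
class BaselineState:
    """Baseline-related activity levels for one patient (all IU/dL).

    ``base`` is the endogenous activity BASE, ``bse`` the observed activity
    immediately before the first study dose, and ``screening`` the screening
    visit activity.
    """

    base: float
    bse: float = 0.0
    screening: float = 0.0

    def __post_init__(self) -> None:
        if self.base < 0.0:
            raise ConfigError(f"BASE must be >= 0, got {self.base}")
        if self.bse < 0.0:
            raise ConfigError(f"BSE must be >= 0, got {self.bse}")
        if self.screening < 0.0:
            raise ConfigError(f"screening activity must be >= 0, got {self.screening}")


def fpp_zero_time(state: BaselineState, cl: float, vc: float) -> float:
    """Time (h) after which prior-product activity is reported as zero.

    The threshold is ``min(BSE, screening, 2 IU/dL)``; the crossing time of
    the exponential decay is solved in closed form.  Returns 0 when there is
    no prior-product activity and ``inf`` when the threshold is 0 (the decay
    never reaches it).
    """
    if state.bse <= 0.0:
        return 0.0
    threshold = min(state.bse, state.screening, FPP_FLOOR_IU_DL)
    if threshold <= 0.0:
        return math.inf
    k = cl / vc
    return math.log(state.bse / threshold) / k


def prior_product_activity(state: BaselineState, cl: float, vc: float, t):
    """Decaying prior-product activity FPP at time(s) ``t`` hours (IU/dL).

    Uses the same CL and Vc as the study drug.  Values are hard-zeroed for
    all times past the analytic threshold-crossing time.
    """
    if not (cl > 0.0 and vc > 0.0):
        raise ConfigError(f"CL and Vc must be > 0, got CL={cl}, Vc={vc}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be >= 0")
    if state.bse <= 0.0:
        out = np.zeros_like(t_arr)
        return float(out) if np.isscalar(t) else out
    t_star = fpp_zero_time(state, cl, vc)
    val = state.bse * np.exp(-(cl / vc) * t_arr)
    val = np.where(t_arr <= t_star, val, 0.0)
    return float(val) if np.isscalar(t) else val


def total_activity(fex, base, fpp):
    """Total observed activity FTOT = FEX + BASE + FPP (all IU/dL, non-negative)."""
    fex_a = np.asarray(fex, dtype=float)
    base_a = np.asarray(base, dtype=float)
    fpp_a = np.asarray(fpp, dtype=float)
    if np.any(fex_a < 0.0) or np.any(base_a < 0.0) or np.any(fpp_a < 0.0):
        raise ValueError("activity components must be >= 0")
    out = fex_a + base_a + fpp_a
    if np.isscalar(fex) and np.isscalar(base) and np.isscalar(fpp):
        return float(out)
    return out
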