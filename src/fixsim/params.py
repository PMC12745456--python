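"""Published population estimates for the rIX-FP activity model.

Point estimates from the final published population-PK analysis of rIX-FP
(albumin-fused recombinant factor IX), pooled over five clinical studies of
113 previously treated hemophilia B patients.  These are the package-wide
defaults for simulation and the simulation truth for estimator-recovery
experiments.

Notes on interpretation:

* the typical values are centered at a 70-kg patient and a 50 IU/kg
  weight-adjusted dose;
* the unit of the inter-compartmental clearance is dL/h (the source table
  carries an obvious misprint in that unit);
* the IIV entries are *variances* of the log-scale random effects, whereas
  the proportional residual components are standard deviations (their CV%
  column equals SD x 100);
* the per-kg clearance medians are medians of individual post-hoc estimates,
  used here to calibrate the age-group weight distributions of the virtual
  cohort generator.
"""

from __future__ import annotations

from .covariates import FixedEffects
from .population import IIVParameters, ResidualError


def reference_fixed_effects() -> FixedEffects:
    """Typical values and covariate exponents of the final model."""
    return FixedEffects(
        base_activity=0.992,  # IU/dL
        cl_70=0.550,          # dL/h at 70 kg
        vc_ref=65.7,          # dL at 70 kg and 50 IU/kg
        q=0.208,              # dL/h
        vp_70=19.5,           # dL at 70 kg
        exp_wt_cl=0.528,
        exp_wt_v=0.771,
        exp_dose_vc=0.281,
    )


def reference_iiv() -> IIVParameters:
    """Variances of the log-normal IIV on CL, Vc and BASE."""
    return IIVParameters(omega2_cl=0.0386, omega2_vc=0.0562, omega2_base=0.176)


def reference_residual_error() -> ResidualError:
    """Combined residual error by study group (proportional SD, additive IU/dL)."""
    return ResidualError(
        prop_sd_group1=0.181,
        add_sd_group1=0.683,
        prop_sd_group2=0.371,
        add_sd_group2=1.20,
    )


#: Median individual post-hoc clearance per kg body weight (dL/h/kg) by age
#: group; calibration targets for the cohort generator's weight medians.
PER_KG_CL_MEDIANS = {
    "0-<6": 0.0155,
    "6-<12": 0.0114,
    "12-<18": 0.0103,
    ">=18": 0.00822,
}

#: Median post-hoc per-kg clearance for the pooled >=12-year stratum.
PER_KG_CL_MEDIAN_GE12 = 0.00836
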