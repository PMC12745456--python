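"""What fraction of patients attain a 5 IU/dL trough on each regimen?

A median trough near 5 IU/dL means roughly half the population sits below
the target, so attainment percentages are the more honest planning figure.
This script resamples inter-individual variability over Monte-Carlo
replicates and reports the percentage of patient-replicate troughs above
1/3/5 IU/dL for the under-6 and adult groups.
"""

import fixsim as fx

cohorts = fx.study_cohorts(seed=0, scale=10)

print("% of simulated troughs above each cutoff:")
print(f"{'regimen':>16} {'group':>8} {'>1':>7} {'>3':>7} {'>5':>7}")
for dose, interval in [(50, 7), (50, 10), (50, 14), (75, 14), (100, 21)]:
    reg = fx.Regimen(dose_per_kg=dose, interval_days=interval)
    for label in ("0-<6", ">=18"):
        s = fx.summarize_regimen(cohorts[label], reg, n_replicates=200, seed=2)
        p = s.pct_above
        print(
            f"{dose:>4} IU/kg q{interval:>2}d {label:>8}"
            f" {p[1.0]:>6.1f} {p[3.0]:>6.1f} {p[5.0]:>6.1f}"
        )

print()
print("Reading: extending 50 IU/kg from weekly to every 14 days drops 5 IU/dL")
print("attainment to ~half of adults and to essentially no children under 6.")
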