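"""When do repeated wearable nights beat one reference night?

Per metric: bias and s.d. of the wearable-vs-reference differences, the
uncertainty of an M-night within-subject mean (standard error, falling as
1/sqrt(M)), and the crossover night — the smallest M at which averaging M
wearable nights is more reliable than a single reference night.  Also the
REM-period agreement table: how often each scoring finds the night's
first REM period within 100 minutes of sleep onset.
"""

from sleepval import (
    CohortConfig,
    METRIC_NAMES,
    cohort_metrics_table,
    crossover_night,
    paired_comparison,
    rem_agreement_summary,
    simulate_cohort,
    uncertainty_curve,
)

dataset = simulate_cohort(CohortConfig(seed=42))
table = cohort_metrics_table(dataset)

print(f"{'metric':<18}{'bias':>8}{'sd':>8}{'u_ear(1)':>10}{'u_S1(1)':>9}"
      f"{'crossover':>11}")
for metric in METRIC_NAMES:
    comp = paired_comparison(table, metric, "S1", "aut_ear_cons")
    wearable = uncertainty_curve(table, metric, "aut_ear_cons")
    reference = uncertainty_curve(table, metric, "S1")
    night = crossover_night(wearable, reference)
    print(f"{metric:<18}{comp.bias:>8.2f}{comp.sd_diff:>8.2f}"
          f"{wearable.uncertainty_by_M[1]:>10.2f}"
          f"{reference.uncertainty_by_M[1]:>9.2f}"
          f"{str(night):>11}")
print("\nbias/sd: wearable minus reference, per night; crossover: nights of")
print("wearable averaging needed to beat one reference night's uncertainty.")

rem = rem_agreement_summary(dataset, [("S1", "S2"), ("S1", "aut_ear_cons")])
print("\nfirst-REM-period agreement (fractions of nights):")
print(rem.to_string(index=False))
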