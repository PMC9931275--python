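"""Compute the eight standard sleep metrics from hypnograms.

A tiny hand-readable night first, then the long-format metric table for a
whole cohort (the input to every reliability analysis downstream).
"""

from sleepval import (
    CohortConfig,
    Hypnogram,
    cohort_metrics_table,
    compute_sleep_metrics,
    simulate_cohort,
)

night = Hypnogram.from_stages(
    ["W", "W", "N1", "N2", "N2", "N3", "R", "W", "R", "W"]
)
m = compute_sleep_metrics(night)
print("hand-readable night:", " ".join(night.stages()))
print(f"  TST  {m.tst_min:.1f} min   (time asleep)")
print(f"  SOL  {m.sol_min:.1f} min   (lights out -> first sleep epoch)")
print(f"  SE   {m.sleep_efficiency:.2f}      (TST / recording time)")
print(f"  WASO {m.waso_min:.1f} min   (wake between first and last sleep)")
print(f"  REM latency {m.rem_latency_min:.1f} min, REM% {m.rem_pct:.1f}, "
      f"N2% {m.n2_pct:.1f}, N3% {m.n3_pct:.1f}  (% of sleep epochs)")

table = cohort_metrics_table(simulate_cohort(CohortConfig(seed=42)))
print(f"\ncohort metric table: {len(table)} rows "
      "(subject, night, scorer, metric, value); undefined values are NaN")
print(table.head(8).to_string(index=False))
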