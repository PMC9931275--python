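"""Generate the default synthetic validation cohort and save it as CSV.

The default world mimics a wearable-validation study: 20 subjects sleep 4
nights each; every night is labelled by two technician-grade scorers (S1,
S2), one automatic PSG-based scorer and three automatic ear-EEG scorers.
The noiseless truth is stored under the reserved scorer id "TRUTH".
"""

from sleepval import CohortConfig, simulate_cohort, write_cohort_csv

dataset = simulate_cohort(CohortConfig(seed=42))
write_cohort_csv(dataset, "cohort.csv")

night = dataset.records[("s01", 1, "TRUTH")]
print(f"scorers:            {dataset.scorer_ids}")
print(f"subjects x nights:  {len(dataset.subjects)} x 4 -> {len(dataset.nights)} nights")
print(f"night (s01, 1):     {night.n_epochs} epochs = {night.total_time_min / 60:.1f} h")
print(f"first 20 epochs:    {' '.join(night.stages()[:20])}")
print("wrote cohort.csv    (one row per scored 30-s epoch)")
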