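"""Epoch-by-epoch agreement between scorers: Cohen's kappa and confusions.

Pooled kappa concatenates all co-scored epochs (the convention behind
headline interrater numbers); the per-night summary shows how much
agreement varies from night to night.  Values around 0.8 are "almost
perfect" agreement, 0.6-0.8 "substantial".
"""

from sleepval import (
    CohortConfig,
    confusion_matrix,
    per_night_kappa_summary,
    pooled_kappa,
    simulate_cohort,
)

dataset = simulate_cohort(CohortConfig(seed=42))

for pair in [("S1", "S2"), ("S1", "aut_psg_cons"), ("S1", "aut_ear_cons")]:
    kappa = pooled_kappa(dataset, *pair)
    summary = per_night_kappa_summary(dataset, *pair)
    print(
        f"{pair[0]:>3} vs {pair[1]:<12} pooled kappa = {kappa:.3f}   "
        f"per-night median = {summary.median:.2f}, "
        f"mean = {summary.mean:.2f} +- {summary.sd:.2f} s.d."
    )

comp = confusion_matrix(
    dataset.records[("s01", 1, "S1")], dataset.records[("s01", 1, "aut_ear_cons")]
)
print(f"\nnight (s01, 1), S1 vs aut_ear_cons: {comp.percent_agreement:.0%} of "
      f"{comp.n_epochs} epochs agree, kappa = {comp.kappa:.2f}")
print("confusion counts (rows = S1, cols = wearable):")
print(comp.confusion_frame())
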