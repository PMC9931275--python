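"""Per-night sleep metrics derived from a hypnogram.

Eight metrics are computed, the set typically reported in clinical
practice:

* **TST** (total sleep time): minutes spent in R, N1, N2 or N3.
* **SOL** (sleep onset latency): minutes from lights out to the first
  sleep epoch.  The first sleep epoch may be R (sleep-onset REM counts).
* **SE** (sleep efficiency): TST divided by total recording time
  (lights out to lights on).
* **WASO** (wake after sleep onset): wake minutes strictly between the
  first and the last sleep epoch.  Only W counts; U counts nowhere.
* **REM latency**: minutes from sleep onset to the first R epoch;
  undefined when no R epoch occurs at or after onset.
* **REM% / N2% / N3%**: epochs in the stage divided by the number of
  sleep epochs, as a percentage.  N1% is deliberately not computed —
  N1 scoring is notoriously unreliable for humans and machines alike,
  so the comparison would carry little information.

U (unclassified) epochs are neither sleep nor wake: they are excluded
from TST, WASO and all percentage denominators, but they do extend the
recording time and therefore the SE denominator.

Undefined values (no sleep all night, no REM all night) are returned as
NaN and propagate as missing data into downstream statistics — a missed
REM period is a categorical event, not a latency of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import N2, N3, R, W, CohortDataset, Hypnogram

#: Canonical metric names, in reporting order.
METRIC_NAMES: tuple[str, ...] = (
    "tst_min",
    "sol_min",
    "sleep_efficiency",
    "waso_min",
    "rem_latency_min",
    "rem_pct",
    "n2_pct",
    "n3_pct",
)


@dataclass(frozen=True)
class SleepMetrics:
    """The eight per-night metric values; NaN marks an undefined value."""

    tst_min: float
    sol_min: float
    sleep_efficiency: float
    waso_min: float
    rem_latency_min: float
    rem_pct: float
    n2_pct: float
    n3_pct: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_sleep_metrics(h: Hypnogram) -> SleepMetrics:
    """Compute the eight sleep metrics for one night."""
    labels = h.labels
    em = h.epoch_minutes
    is_sleep = (labels >= R) & (labels <= N3)
    sleep_idx = np.flatnonzero(is_sleep)
    n_sleep = int(sleep_idx.size)

    if n_sleep == 0:
        # A night with no sleep epoch: onset never happened, so latencies
        # are missing rather than zero.
        return SleepMetrics(
            tst_min=0.0,
            sol_min=float("nan"),
            sleep_efficiency=0.0,
            waso_min=0.0,
            rem_latency_min=float("nan"),
            rem_pct=float("nan"),
            n2_pct=float("nan"),
            n3_pct=float("nan"),
        )

    onset = int(sleep_idx[0])
    last = int(sleep_idx[-1])
    tst = n_sleep * em
    waso = int(np.count_nonzero(labels[onset : last + 1] == W)) * em

    rem_after_onset = np.flatnonzero(labels[onset:] == R)
    rem_latency = float(rem_after_onset[0]) * em if rem_after_onset.size else float("nan")

    return SleepMetrics(
        tst_min=tst,
        sol_min=onset * em,
        sleep_efficiency=tst / h.total_time_min,
        waso_min=waso,
        rem_latency_min=rem_latency,
        rem_pct=100.0 * np.count_nonzero(labels == R) / n_sleep,
        n2_pct=100.0 * np.count_nonzero(labels == N2) / n_sleep,
        n3_pct=100.0 * np.count_nonzero(labels == N3) / n_sleep,
    )


def cohort_metrics_table(dataset: CohortDataset) -> pd.DataFrame:
    """Long-format metric table for every hypnogram in the cohort.

    Columns ``subject, night, scorer, metric, value``; one row per
    (hypnogram, metric), undefined values as NaN; rows ordered by
    (subject, night, scorer, metric position).
    """
    rows: list[tuple[str, int, str, str, float]] = []
    for (subject, night, scorer) in sorted(dataset.records):
        m = compute_sleep_metrics(dataset.records[(subject, night, scorer)])
        for name, value in m.as_dict().items():
            rows.append((subject, night, scorer, name, value))
    return pd.DataFrame(
        rows, columns=["subject", "night", "scorer", "metric", "value"]
    )
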