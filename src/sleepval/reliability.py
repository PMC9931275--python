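"""Reliability analysis: bias, precision, and the value of extra nights.

Two questions drive this module.  First, how well does an alternative
scoring reproduce the reference scorer's sleep metrics night by night?
That is answered with the *bias* (mean difference, alternative minus
reference) and the *s.d. of the differences*, optionally normalised by
the spread of the metric under the reference scoring so that different
metrics can share one plot.

Second, when is averaging M nights of a noisier wearable more reliable
than a single reference night?  For each subject n let sigma_n^2 be the
variance of the metric over that subject's nights.  The uncertainty of a
within-subject mean of M nights is

    uncertainty(M) = sqrt( mean_n(sigma_n^2) / M )

the standard error of the mean, averaged over subjects.  This is
equivalent to resampling M nights per subject and taking the standard
deviation of the resampled means.  The *crossover night* is the smallest
M at which the wearable's uncertainty(M) drops strictly below the
reference scorer's uncertainty(1).  The *population spread* — the
standard deviation of per-subject mean values — gives the between-subject
scale against which these uncertainties can be judged.

REM latency needs special care: when a scorer misses the first REM period
entirely, the latency it reports jumps by roughly a full sleep cycle.
Those events are treated categorically — a night *agrees* when both
scorings find REM within a window (default 100 minutes) after their own
sleep onset — rather than being averaged into the latency statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import R, SLEEP_CODES, CohortDataset, Hypnogram
from .errors import (
    EmptyComparisonError,
    InsufficientDataError,
    SleepvalError,
    UndefinedOnsetError,
)

logger = logging.getLogger(__name__)

REM_CATEGORIES = ("agree", "a_missed_first", "b_missed_first", "both_late")


@dataclass(frozen=True)
class PairedMetricComparison:
    """Night-matched comparison of one metric between two scorings."""

    metric_name: str
    reference_values: np.ndarray
    alternative_values: np.ndarray
    bias: float
    sd_diff: float
    normalized_bias: float
    normalized_sd: float

    @property
    def n_pairs(self) -> int:
        return int(self.reference_values.size)


@dataclass(frozen=True)
class UncertaintyCurve:
    """Within-subject standard error of a metric as nights accumulate."""

    metric_name: str
    scorer_id: str
    per_subject_variances: np.ndarray
    uncertainty_by_M: dict[int, float]
    population_spread: float


@dataclass(frozen=True)
class RemAgreementRecord:
    """Did both scorings find the first REM period?

    ``category`` is ``agree`` when both scorings contain an R epoch within
    ``window_min`` minutes after their own sleep onset, ``a_missed_first``
    / ``b_missed_first`` when only one does, and ``both_late`` when
    neither does.  ``latency_delay_min`` is the absolute REM-latency
    difference when both latencies are defined, else NaN.
    """

    category: str
    latency_delay_min: float
    night_id: tuple[str, int] | None = None


def _metric_pivot(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise InsufficientDataError(f"metric {metric!r} not present in table")
    return sub.pivot_table(
        index=["subject", "night"],
        columns="scorer",
        values="value",
        dropna=False,
    )


def paired_comparison(
    metric_table: pd.DataFrame,
    metric: str,
    reference: str,
    alternative: str,
) -> PairedMetricComparison:
    """Bias and s.d. of night-wise metric differences.

    Nights where either value is undefined are dropped (pairwise
    deletion).  ``bias = mean(alternative - reference)``; ``sd_diff`` uses
    the n-1 denominator.  The normalised quantities divide |bias| and
    sd_diff by the standard deviation of the metric under the reference
    scoring over the same complete pairs.
    """
    pivot = _metric_pivot(metric_table, metric)
    for scorer in (reference, alternative):
        if scorer not in pivot.columns:
            raise InsufficientDataError(
                f"scorer {scorer!r} has no values for metric {metric!r}"
            )
    pair = pivot[[reference, alternative]].dropna()
    if len(pair) < 2:
        raise InsufficientDataError(
            f"metric {metric!r}: only {len(pair)} complete pairs for "
            f"({reference!r}, {alternative!r}); need at least 2"
        )
    ref = pair[reference].to_numpy(dtype=float)
    alt = pair[alternative].to_numpy(dtype=float)
    diffs = alt - ref
    bias = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    ref_sd = float(ref.std(ddof=1))
    if ref_sd > 0:
        norm_bias, norm_sd = abs(bias) / ref_sd, sd_diff / ref_sd
    else:  # metric constant under the reference: normalisation undefined
        norm_bias, norm_sd = float("nan"), float("nan")
    return PairedMetricComparison(
        metric_name=metric,
        reference_values=ref,
        alternative_values=alt,
        bias=bias,
        sd_diff=sd_diff,
        normalized_bias=norm_bias,
        normalized_sd=norm_sd,
    )


def uncertainty_curve(
    metric_table: pd.DataFrame,
    metric: str,
    scorer: str,
    max_M: int = 4,
    ddof: int = 1,
) -> UncertaintyCurve:
    """Uncertainty of the M-night within-subject mean, M = 1..max_M.

    Each subject contributes the variance sigma_n^2 (denominator
    ``n - ddof``) of its defined nightly values; subjects with fewer than
    two such nights are excluded with a warning.  The curve is
    ``sqrt(mean_n sigma_n^2 / M)`` and therefore obeys the 1/sqrt(M) law
    exactly.  ``population_spread`` is the n-1 standard deviation of the
    included subjects' mean values.
    """
    pivot = _metric_pivot(metric_table, metric)
    if scorer not in pivot.columns:
        raise InsufficientDataError(
            f"scorer {scorer!r} has no values for metric {metric!r}"
        )
    variances: list[float] = []
    means: list[float] = []
    for subject, values in pivot[scorer].groupby(level="subject"):
        v = values.dropna().to_numpy(dtype=float)
        if v.size < 2:
            logger.warning(
                "subject %r excluded from uncertainty curve for %s/%s: only "
                "%d defined night(s)",
                subject,
                metric,
                scorer,
                v.size,
            )
            continue
        variances.append(float(v.var(ddof=ddof)))
        means.append(float(v.mean()))
    if not variances:
        raise InsufficientDataError(
            f"no subject has >= 2 defined nights for metric {metric!r}, "
            f"scorer {scorer!r}"
        )
    mean_var = float(np.mean(variances))
    curve = {m: math.sqrt(mean_var / m) for m in range(1, max_M + 1)}
    spread = (
        float(np.std(means, ddof=1)) if len(means) >= 2 else float("nan")
    )
    return UncertaintyCurve(
        metric_name=metric,
        scorer_id=scorer,
        per_subject_variances=np.asarray(variances),
        uncertainty_by_M=curve,
        population_spread=spread,
    )


def crossover_night(
    wearable: UncertaintyCurve, reference: UncertaintyCurve
) -> int | None:
    """Smallest M where the wearable's M-night mean beats one reference night.

    Strict inequality against ``reference.uncertainty_by_M[1]``; ``None``
    when no available M qualifies.
    """
    if wearable.metric_name != reference.metric_name:
        raise SleepvalError(
            f"cannot compare curves for different metrics: "
            f"{wearable.metric_name!r} vs {reference.metric_name!r}"
        )
    target = reference.uncertainty_by_M[1]
    for m in sorted(wearable.uncertainty_by_M):
        if wearable.uncertainty_by_M[m] < target:
            return m
    return None


def _onset_index(h: Hypnogram) -> int:
    sleep = np.flatnonzero(
        (h.labels >= min(SLEEP_CODES)) & (h.labels <= max(SLEEP_CODES))
    )
    if sleep.size == 0:
        raise UndefinedOnsetError("hypnogram contains no sleep epoch")
    return int(sleep[0])


def _rem_latency_min(h: Hypnogram) -> float:
    onset = _onset_index(h)
    rem = np.flatnonzero(h.labels[onset:] == R)
    return float(rem[0]) * h.epoch_minutes if rem.size else float("nan")


def rem_period_agreement(
    a: Hypnogram,
    b: Hypnogram,
    window_min: float = 100.0,
    night_id: tuple[str, int] | None = None,
) -> RemAgreementRecord:
    """Categorise whether both scorings found REM within the window.

    Each scoring is tested against its *own* sleep onset: it counts as
    finding REM when its REM latency is strictly below ``window_min``
    minutes.  Undefined sleep onset in either scoring raises
    :class:`UndefinedOnsetError`.
    """
    lat_a = _rem_latency_min(a)
    lat_b = _rem_latency_min(b)
    in_a = not math.isnan(lat_a) and lat_a < window_min
    in_b = not math.isnan(lat_b) and lat_b < window_min
    if in_a and in_b:
        category = "agree"
    elif in_b:
        category = "a_missed_first"
    elif in_a:
        category = "b_missed_first"
    else:
        category = "both_late"
    delay = (
        abs(lat_a - lat_b)
        if not (math.isnan(lat_a) or math.isnan(lat_b))
        else float("nan")
    )
    return RemAgreementRecord(
        category=category, latency_delay_min=delay, night_id=night_id
    )


def rem_agreement_summary(
    dataset: CohortDataset,
    pairs: list[tuple[str, str]],
    window_min: float = 100.0,
) -> pd.DataFrame:
    """Fractions of REM-agreement categories per scorer pair.

    One row per pair with the fraction of nights in each of the four
    categories (summing to 1 over counted nights) and the night count.
    Nights where either scoring has no sleep at all are skipped; pairs
    with no usable night are skipped with a warning.
    """
    rows = []
    for scorer_a, scorer_b in pairs:
        nights = dataset.co_scored_nights(scorer_a, scorer_b)
        counts = dict.fromkeys(REM_CATEGORIES, 0)
        n_used = 0
        for subject, night in nights:
            try:
                rec = rem_period_agreement(
                    dataset.records[(subject, night, scorer_a)],
                    dataset.records[(subject, night, scorer_b)],
                    window_min=window_min,
                    night_id=(subject, night),
                )
            except UndefinedOnsetError:
                continue
            counts[rec.category] += 1
            n_used += 1
        if n_used == 0:
            logger.warning(
                "pair (%r, %r) has no usable co-scored nights; skipped",
                scorer_a,
                scorer_b,
            )
            continue
        rows.append(
            {
                "scorer_a": scorer_a,
                "scorer_b": scorer_b,
                "n_nights": n_used,
                **{c: counts[c] / n_used for c in REM_CATEGORIES},
            }
        )
    if not rows and pairs:
        raise EmptyComparisonError("no scorer pair had any usable night")
    return pd.DataFrame(
        rows,
        columns=["scorer_a", "scorer_b", "n_nights", *REM_CATEGORIES],
    )
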