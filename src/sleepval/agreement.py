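"""Epoch-by-epoch agreement between two sleep scorings.

Two labelings of the same night are compared epoch by epoch over the full
six-class vocabulary (W, R, N1, N2, N3, U) — U is a first-class category,
neither dropped nor merged with wake.  The chance-corrected agreement is
Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e)

with the expected agreement p_e computed from the observed marginals of
the two scorings; classes absent from both contribute zero to p_e.

Two pooling conventions are provided: ``pooled_kappa`` concatenates every
co-scored epoch of a cohort into one comparison (repeated measures
ignored), while ``per_night_kappa_summary`` summarises the distribution
of per-night kappa values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import STAGES, CohortDataset, Hypnogram
from .errors import AlignmentError, EmptyComparisonError

logger = logging.getLogger(__name__)

_K = len(STAGES)


@dataclass(frozen=True)
class ScoringComparison:
    """Confusion counts and agreement for one pair of labelings.

    ``confusion_counts[i, j]`` counts epochs labelled ``STAGES[i]`` by the
    first scoring and ``STAGES[j]`` by the second.
    """

    confusion_counts: np.ndarray
    n_epochs: int
    percent_agreement: float
    kappa: float

    def confusion_frame(self) -> pd.DataFrame:
        """Counts as a labelled DataFrame (rows = first scoring)."""
        return pd.DataFrame(
            self.confusion_counts, index=list(STAGES), columns=list(STAGES)
        )


def _check_aligned(a: Hypnogram, b: Hypnogram) -> None:
    if a.n_epochs != b.n_epochs:
        raise AlignmentError(
            f"hypnograms have {a.n_epochs} and {b.n_epochs} epochs; "
            "align them first (align_pair)"
        )


def confusion_counts(a: Hypnogram, b: Hypnogram) -> np.ndarray:
    """6x6 epoch-count matrix in the canonical stage order."""
    _check_aligned(a, b)
    idx = a.labels.astype(np.intp) * _K + b.labels.astype(np.intp)
    return np.bincount(idx, minlength=_K * _K).reshape(_K, _K)


def kappa_from_counts(counts: np.ndarray) -> float:
    """Cohen's kappa from a square contingency table.

    Degenerate conventions (both scorings constant): identical constants
    give kappa = 1.0, different constants give 0.0.  The paper-style data
    never triggers these; the convention is logged when used.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise EmptyComparisonError("cannot compute kappa on zero epochs")
    p_o = np.trace(counts) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        value = 1.0 if p_o >= 1.0 - 1e-15 else 0.0
        logger.info(
            "degenerate kappa: both scorings constant; returning %.1f by "
            "convention",
            value,
        )
        return value
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_matrix(a: Hypnogram, b: Hypnogram) -> ScoringComparison:
    """Full epoch-by-epoch comparison of two aligned hypnograms."""
    counts = confusion_counts(a, b)
    n = int(counts.sum())
    return ScoringComparison(
        confusion_counts=counts,
        n_epochs=n,
        percent_agreement=float(np.trace(counts) / n),
        kappa=kappa_from_counts(counts),
    )


def cohens_kappa(a: Hypnogram, b: Hypnogram) -> float:
    """Six-class Cohen's kappa between two aligned hypnograms."""
    return kappa_from_counts(confusion_counts(a, b))


def pooled_confusion(
    dataset: CohortDataset, scorer_a: str, scorer_b: str
) -> np.ndarray:
    """Entry-wise sum of per-night confusion matrices for one scorer pair."""
    nights = dataset.co_scored_nights(scorer_a, scorer_b)
    if not nights:
        raise EmptyComparisonError(
            f"no co-scored nights for scorers {scorer_a!r} and {scorer_b!r}"
        )
    total = np.zeros((_K, _K), dtype=np.int64)
    for subject, night in nights:
        total += confusion_counts(
            dataset.records[(subject, night, scorer_a)],
            dataset.records[(subject, night, scorer_b)],
        )
    return total

def pooled_kappa(dataset: CohortDataset, scorer_a: str, scorer_b: str) -> float:
    """Kappa over the concatenation of all co-scored epochs.

    This ignores the repeated-measures structure: every epoch of every
    night enters one big contingency table.  Algebraically identical to
    computing kappa from the summed per-night confusion matrices.
    """
    return kappa_from_counts(pooled_confusion(dataset, scorer_a, scorer_b))


@dataclass(frozen=True)
class KappaSummary:
    """Distribution of per-night kappa values for one scorer pair."""

    median: float
    mean: float
    sd: float  # n-1 denominator; NaN when only one night
    per_night: pd.DataFrame  # columns: subject, night, kappa


def per_night_kappa_summary(
    dataset: CohortDataset, scorer_a: str, scorer_b: str
) -> KappaSummary:
    """Median/mean/s.d. of kappa computed night by night."""
    nights = dataset.co_scored_nights(scorer_a, scorer_b)
    if not nights:
        raise EmptyComparisonError(
            f"no co-scored nights for scorers {scorer_a!r} and {scorer_b!r}"
        )
    values = [
        cohens_kappa(
            dataset.records[(s, n, scorer_a)], dataset.records[(s, n, scorer_b)]
        )
        for s, n in nights
    ]
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    per_night = pd.DataFrame(
        {
            "subject": [s for s, _ in nights],
            "night": [n for _, n in nights],
            "kappa": arr,
        }
    )
    return KappaSummary(
        median=float(np.median(arr)),
        mean=float(arr.mean()),
        sd=sd,
        per_night=per_night,
    )
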