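"""Hypnogram and cohort data model with CSV readers and writers.

A hypnogram is the sequence of sleep-stage labels assigned to consecutive
30-second epochs of one night, starting at lights out.  Six labels are
recognised: W (wake), R (REM), N1/N2/N3 (non-REM, light to deep) and U
(the scorer could not classify the epoch).  A cohort is a collection of
hypnograms indexed by (subject, night, scorer); several scorers labelling
the same night must agree on its length, since they describe the same
recording.

The single on-disk format is a long CSV with header
``subject,night,scorer,epoch,stage`` — one row per scored epoch, epoch
indices 0-based and contiguous within each (subject, night, scorer).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CohortFormatError,
    CohortIntegrityError,
    EpochIncompatibilityError,
    StageVocabularyError,
)

logger = logging.getLogger(__name__)

#: Canonical stage order used for every confusion-matrix axis.
STAGES: tuple[str, ...] = ("W", "R", "N1", "N2", "N3", "U")
STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Stages generated by the underlying sleep process (scorers may add U).
TRUE_STAGES: tuple[str, ...] = STAGES[:5]

#: Stages counted as sleep by every metric.
SLEEP_STAGES: tuple[str, ...] = ("R", "N1", "N2", "N3")

W, R, N1, N2, N3, U = range(6)
SLEEP_CODES = frozenset({R, N1, N2, N3})

COHORT_COLUMNS = ("subject", "night", "scorer", "epoch", "stage")

#: Reserved scorer id under which the simulator stores the noiseless truth.
TRUTH_SCORER = "TRUTH"


def _encode(labels: Iterable[str]) -> np.ndarray:
    out = np.empty(0, dtype=np.int8)
    try:
        out = np.fromiter((STAGE_TO_CODE[s] for s in labels), dtype=np.int8)
    except KeyError as exc:
        raise StageVocabularyError(
            f"unknown stage label {exc.args[0]!r}; expected one of {STAGES}"
        ) from None
    return out


@dataclass(frozen=True)
class Hypnogram:
    """One night's epoch-label sequence.

    Parameters
    ----------
    labels
        Integer stage codes (canonical order W, R, N1, N2, N3, U), one per
        epoch.  Use :meth:`from_stages` to build from stage strings.
    epoch_duration_s
        Epoch length in seconds; 30 s is the standard scoring epoch.

    Epoch ``i`` spans ``[i*d, (i+1)*d)`` seconds after lights out; lights-on
    is the end of the last epoch, matching a protocol that scores from
    lights out until the final wake-up.
    """

    labels: np.ndarray
    epoch_duration_s: float = 30.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if arr.min() < 0 or arr.max() >= len(STAGES):
            raise StageVocabularyError("stage codes must lie in 0..5")
        if not self.epoch_duration_s > 0:
            raise ValueError("epoch_duration_s must be positive")
        arr.setflags(write=False)
        object.__setattr__(self, "labels", arr)

    @classmethod
    def from_stages(
        cls, stages: Iterable[str], epoch_duration_s: float = 30.0
    ) -> "Hypnogram":
        return cls(_encode(stages), epoch_duration_s)

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_duration_s / 60.0

    @property
    def total_time_min(self) -> float:
        """Total recorded time, lights out to lights on, in minutes."""
        return self.n_epochs * self.epoch_minutes

    def stages(self) -> tuple[str, ...]:
        return tuple(STAGES[c] for c in self.labels)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_epochs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_duration_s == other.epoch_duration_s
            and np.array_equal(self.labels, other.labels)
        )


RecordKey = tuple[str, int, str]


@dataclass
class CohortDataset:
    """Hypnograms indexed by (subject_id, night, scorer_id).

    Nights may be missing for some (subject, scorer) pairs — absent keys,
    never padding.  All hypnograms of one (subject, night) must have equal
    length and epoch duration because they label the same recording.
    """

    records: dict[RecordKey, Hypnogram] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        shapes: dict[tuple[str, int], tuple[int, float]] = {}
        for (subject, night, scorer), h in self.records.items():
            if not (isinstance(night, (int, np.integer)) and night >= 1):
                raise CohortIntegrityError(
                    f"night index must be an integer >= 1, got {night!r}"
                )
            key = (subject, int(night))
            shape = (h.n_epochs, h.epoch_duration_s)
            if key in shapes and shapes[key] != shape:
                raise CohortIntegrityError(
                    f"scorers disagree on the shape of night {key}: "
                    f"{shapes[key]} vs {shape} (scorer {scorer!r})"
                )
            shapes.setdefault(key, shape)

    @property
    def scorer_ids(self) -> list[str]:
        return sorted({k[2] for k in self.records})

    @property
    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.records})

    @property
    def nights(self) -> list[tuple[str, int]]:
        """Sorted (subject, night) pairs present for at least one scorer."""
        return sorted({(k[0], k[1]) for k in self.records})

    def get(self, subject: str, night: int, scorer: str) -> Hypnogram | None:
        return self.records.get((subject, int(night), scorer))

    def co_scored_nights(
        self, scorer_a: str, scorer_b: str
    ) -> list[tuple[str, int]]:
        """Nights labelled by both scorers, sorted."""
        return [
            (s, n)
            for (s, n) in self.nights
            if (s, n, scorer_a) in self.records and (s, n, scorer_b) in self.records
        ]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        return self.records == other.records


def read_cohort_csv(path) -> CohortDataset:
    """Read a cohort CSV (header ``subject,night,scorer,epoch,stage``).

    Raises
    ------
    CohortFormatError
        Missing/extra columns, or a header-only file.
    StageVocabularyError
        A stage value outside {W, N1, N2, N3, R, U}; the message names the
        offending row.
    CohortIntegrityError
        Non-contiguous or non-0-based epoch indices within one
        (subject, night, scorer), or length mismatch across scorers.
    """
    df = pd.read_csv(path, dtype={"subject": str, "scorer": str, "stage": str})
    if tuple(df.columns) != COHORT_COLUMNS:
        raise CohortFormatError(
            f"expected columns {COHORT_COLUMNS}, found {tuple(df.columns)}"
        )
    if df.empty:
        raise CohortFormatError("cohort file contains a header but no data rows")
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise StageVocabularyError(
            f"row {i + 2}: unknown stage {df['stage'].iloc[i]!r} "
            f"(subject={df['subject'].iloc[i]!r}, night={df['night'].iloc[i]}, "
            f"scorer={df['scorer'].iloc[i]!r})"
        )

    records: dict[RecordKey, Hypnogram] = {}
    for (subject, night, scorer), grp in df.groupby(
        ["subject", "night", "scorer"], sort=True
    ):
        grp = grp.sort_values("epoch")
        epochs = grp["epoch"].to_numpy()
        if not np.array_equal(epochs, np.arange(len(grp))):
            raise CohortIntegrityError(
                f"epoch indices for (subject={subject!r}, night={night}, "
                f"scorer={scorer!r}) are not 0-based and contiguous"
            )
        records[(str(subject), int(night), str(scorer))] = Hypnogram(
            _encode(grp["stage"])
        )
    return CohortDataset(records)


def write_cohort_csv(dataset: CohortDataset, path) -> None:
    """Write a cohort CSV with deterministic row order.

    Rows are sorted by (subject, night, scorer, epoch); output is
    byte-identical for identical input.
    """
    frames = []
    for (subject, night, scorer) in sorted(dataset.records):
        h = dataset.records[(subject, night, scorer)]
        frames.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "night": night,
                    "scorer": scorer,
                    "epoch": np.arange(h.n_epochs),
                    "stage": list(h.stages()),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(COHORT_COLUMNS)
    )
    out.to_csv(path, index=False, lineterminator="\n")


def align_pair(a: Hypnogram, b: Hypnogram) -> tuple[Hypnogram, Hypnogram]:
    """Truncate two hypnograms of one night to their common length.

    Scorers occasionally stop at different epochs; epoch-by-epoch
    comparison uses the overlap.  A warning is logged when truncation
    occurs.  Differing epoch durations are an error, not something to
    resample away.
    """
    if a.epoch_duration_s != b.epoch_duration_s:
        raise EpochIncompatibilityError(
            f"epoch durations differ: {a.epoch_duration_s} s vs "
            f"{b.epoch_duration_s} s"
        )
    if a.n_epochs == b.n_epochs:
        return a, b
    n = min(a.n_epochs, b.n_epochs)
    logger.warning(
        "aligning hypnograms of unequal length (%d, %d); truncating to %d",
        a.n_epochs,
        b.n_epochs,
        n,
    )
    return (
        Hypnogram(a.labels[:n], a.epoch_duration_s),
        Hypnogram(b.labels[:n], b.epoch_duration_s),
    )
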