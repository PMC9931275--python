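"""Synthetic multi-night, multi-scorer cohort generator.

Real validation studies of wearable sleep staging compare several
labelings of the same nights: manual scorings of polysomnography and
automatic scorings of the wearable signal.  Raw recordings from such
studies are rarely shared, so this module generates a structurally
equivalent stand-in:

1. A *true* hypnogram per (subject, night), drawn from a first-order
   Markov chain over the five true stages (W, R, N1, N2, N3).  Bout-length
   realism comes from strong self-transition probabilities; the chain is
   deliberately not semi-Markov, since the analyses under test consume
   label sequences, not physiologically perfect architecture.
2. Per-subject and per-night variation, injected by perturbing the
   transition-matrix logits with Gaussian noise and renormalising.  This
   creates genuine within-subject night-to-night variance, which the
   reliability analysis requires.
3. *Scorers* — noisy observers of the truth.  A scorer is a 6x6
   row-stochastic confusion matrix (it may emit U, "unclassified") plus a
   REM-run miss probability: each maximal run of true R is, independently,
   wholly relabelled (default to N2) before epoch-wise confusion noise is
   applied.  A missed first REM period is thereby a coherent event, not a
   scattering of independent epoch flips.

The default scorer set mirrors a two-technician PSG study with four
automatic classifiers (one PSG-based, three ear-EEG-based); its confusion
matrices are calibrated so that pooled inter-technician kappa is ~0.83,
technician-vs-automatic-PSG ~0.80, technician-vs-ear ~0.70-0.74, the ear
scorer overestimates N2% and underestimates N3%, and it misses the first
REM period of a night with ~20% probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    R,
    STAGE_TO_CODE,
    STAGES,
    TRUE_STAGES,
    TRUTH_SCORER,
    CohortDataset,
    Hypnogram,
    RecordKey,
)
from .errors import ConfigurationError

_N_TRUE = len(TRUE_STAGES)
_N_ALL = len(STAGES)


def _check_stochastic(matrix: np.ndarray, n_rows: int, name: str) -> None:
    if np.any(matrix < 0):
        raise ConfigurationError(f"{name} has negative entries")
    sums = matrix[:n_rows].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise ConfigurationError(
            f"rows of {name} must sum to 1 within 1e-12; got {sums}"
        )


@dataclass(frozen=True)
class TransitionModel:
    """First-order Markov model of the true sleep process.

    ``initial_dist`` and ``transition`` are indexed in the canonical true
    stage order (W, R, N1, N2, N3).  Night length in epochs is drawn as
    ``round(Normal(n_epochs_mean, n_epochs_sd))`` floored at
    ``n_epochs_min`` (defaults approximate an 8-hour recording of
    30-second epochs).
    """

    initial_dist: np.ndarray
    transition: np.ndarray
    n_epochs_mean: int = 960
    n_epochs_sd: float = 60.0
    n_epochs_min: int = 600

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_dist, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        if init.shape != (_N_TRUE,) or trans.shape != (_N_TRUE, _N_TRUE):
            raise ConfigurationError(
                f"initial_dist must be ({_N_TRUE},) and transition "
                f"({_N_TRUE}, {_N_TRUE})"
            )
        _check_stochastic(init[None, :], 1, "initial_dist")
        _check_stochastic(trans, _N_TRUE, "transition")
        init.setflags(write=False)
        trans.setflags(write=False)
        object.__setattr__(self, "initial_dist", init)
        object.__setattr__(self, "transition", trans)


@dataclass(frozen=True)
class ScorerModel:
    """A noisy scorer: epoch-wise confusion plus whole-run REM misses.

    ``confusion`` is 6x6 and row-stochastic in its first five rows
    (true stage W, R, N1, N2, N3); the sixth row (U) is unused because the
    truth never contains U.  Columns span all six emitted labels.
    ``rem_run_miss_prob`` applies independently to each maximal run of
    true R; a missed run is relabelled to ``rem_miss_relabel`` before the
    confusion noise is applied.
    """

    confusion: np.ndarray
    rem_run_miss_prob: float = 0.0
    rem_miss_relabel: str = "N2"

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (_N_ALL, _N_ALL):
            raise ConfigurationError(f"confusion must be ({_N_ALL}, {_N_ALL})")
        _check_stochastic(conf, _N_TRUE, "confusion")
        if not 0.0 <= self.rem_run_miss_prob <= 1.0:
            raise ConfigurationError("rem_run_miss_prob must be in [0, 1]")
        if self.rem_miss_relabel not in TRUE_STAGES:
            raise ConfigurationError(
                f"rem_miss_relabel must be a true stage, got "
                f"{self.rem_miss_relabel!r}"
            )
        conf.setflags(write=False)
        object.__setattr__(self, "confusion", conf)


@dataclass(frozen=True)
class CohortConfig:
    """Study design: subjects x nights, scorer models, effect sizes, seed.

    ``subject_effect_sd`` and ``night_effect_sd`` are the standard
    deviations of Gaussian perturbations applied to the log of the
    (non-zero) transition probabilities, per subject and per night
    respectively; rows are renormalised afterwards.
    """

    n_subjects: int = 20
    n_nights: int = 4
    subject_effect_sd: float = 0.30
    night_effect_sd: float = 0.20
    transition_model: TransitionModel | None = None
    scorer_models: dict[str, ScorerModel] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nights < 1:
            raise ConfigurationError("n_subjects and n_nights must be >= 1")
        if self.subject_effect_sd < 0 or self.night_effect_sd < 0:
            raise ConfigurationError("effect standard deviations must be >= 0")
        if self.scorer_models is not None and TRUTH_SCORER in self.scorer_models:
            raise ConfigurationError(
                f"scorer id {TRUTH_SCORER!r} is reserved for the noiseless truth"
            )


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (power iteration)."""
    trans = np.asarray(transition, dtype=float)
    p = np.full(trans.shape[0], 1.0 / trans.shape[0])
    for _ in range(200_000):
        nxt = p @ trans
        if np.abs(nxt - p).max() < 1e-14:
            return nxt / nxt.sum()
        p = nxt
    return p / p.sum()


def simulate_true_hypnogram(
    model: TransitionModel, n_epochs: int, rng: np.random.Generator
) -> Hypnogram:
    """Draw one true hypnogram of ``n_epochs`` 30-second epochs."""
    if n_epochs < 1:
        raise ConfigurationError("n_epochs must be >= 1")
    cum = np.cumsum(model.transition, axis=1)
    cum_init = np.cumsum(model.initial_dist)
    u = rng.random(n_epochs)
    labels = np.empty(n_epochs, dtype=np.int8)
    state = int(np.searchsorted(cum_init, u[0], side="right"))
    labels[0] = state
    for i in range(1, n_epochs):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        labels[i] = state
    return Hypnogram(labels)


def _rem_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) spans of maximal true-R runs."""
    is_r = labels == R
    if not is_r.any():
        return []
    d = np.diff(is_r.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if is_r[0]:
        starts.insert(0, 0)
    if is_r[-1]:
        stops.append(len(labels))
    return list(zip(starts, stops))


def apply_scorer_noise(
    truth: Hypnogram, scorer: ScorerModel, rng: np.random.Generator
) -> Hypnogram:
    """Produce one scorer's labelling of a true hypnogram.

    Step 1: each maximal true-R run is, with probability
    ``rem_run_miss_prob``, wholly relabelled to ``rem_miss_relabel`` in a
    working copy.  Step 2: every epoch's output label is drawn from the
    confusion row of its (possibly relabelled) working stage.
    """
    labels = truth.labels
    if np.any(labels >= _N_TRUE):
        raise ConfigurationError("truth hypnogram must not contain U epochs")
    working = labels.copy()
    if scorer.rem_run_miss_prob > 0:
        relabel = STAGE_TO_CODE[scorer.rem_miss_relabel]
        for start, stop in _rem_runs(labels):
            if rng.random() < scorer.rem_run_miss_prob:
                working[start:stop] = relabel
    cum = np.cumsum(scorer.confusion, axis=1)
    u = rng.random(working.size)
    out = (cum[working] < u[:, None]).sum(axis=1).astype(np.int8)
    return Hypnogram(out, truth.epoch_duration_s)


def expected_agreement(
    confusion_a: np.ndarray, confusion_b: np.ndarray, stage_dist: np.ndarray
) -> float:
    """Closed-form expected raw agreement of two independent scorers.

    Given the true-stage distribution ``p`` and confusion matrices C_a and
    C_b, the chance that both scorers emit the same label for an epoch is
    ``sum_s p_s sum_k C_a[s, k] * C_b[s, k]``.
    """
    p = np.asarray(stage_dist, dtype=float)
    ca = np.asarray(confusion_a, dtype=float)[:_N_TRUE]
    cb = np.asarray(confusion_b, dtype=float)[:_N_TRUE]
    return float(np.einsum("s,sk,sk->", p, ca, cb))


def expected_kappa(
    confusion_a: np.ndarray, confusion_b: np.ndarray, stage_dist: np.ndarray
) -> float:
    """Closed-form expected Cohen's kappa of two independent scorers.

    Uses the exact expected observed agreement and the expected marginal
    label distributions ``p @ C``; for long nights the empirical kappa
    converges to this value (law of large numbers).
    """
    p = np.asarray(stage_dist, dtype=float)
    ca = np.asarray(confusion_a, dtype=float)[:_N_TRUE]
    cb = np.asarray(confusion_b, dtype=float)[:_N_TRUE]
    p_o = expected_agreement(ca, cb, p)
    p_e = float((p @ ca) @ (p @ cb))
    return (p_o - p_e) / (1.0 - p_e)


def _perturb_rows(matrix: np.ndarray, logit_noise: np.ndarray) -> np.ndarray:
    """Multiply non-zero entries by exp(noise) and renormalise each row.

    Structural zeros stay zero, so impossible transitions remain
    impossible for every subject and night.
    """
    out = matrix * np.exp(logit_noise)
    return out / out.sum(axis=1, keepdims=True)


def simulate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate a full synthetic cohort.

    For every (subject, night) one true hypnogram is stored under the
    reserved scorer id ``"TRUTH"`` alongside one noisy hypnogram per
    configured scorer.  Identical (config, seed) gives an identical
    dataset.
    """
    config = config or CohortConfig()
    model = config.transition_model or default_transition_model()
    scorers = (
        config.scorer_models
        if config.scorer_models is not None
        else default_scorer_models()
    )
    if TRUTH_SCORER in scorers:
        raise ConfigurationError(
            f"scorer id {TRUTH_SCORER!r} is reserved for the noiseless truth"
        )
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_subjects))
    records: dict[RecordKey, Hypnogram] = {}
    for i in range(config.n_subjects):
        subject = f"s{i + 1:0{width}d}"
        subj_noise = rng.normal(0.0, config.subject_effect_sd, (_N_TRUE, _N_TRUE))
        for night in range(1, config.n_nights + 1):
            night_noise = rng.normal(
                0.0, config.night_effect_sd, (_N_TRUE, _N_TRUE)
            )
            transition = _perturb_rows(model.transition, subj_noise + night_noise)
            night_model = replace(model, transition=transition)
            n_epochs = max(
                model.n_epochs_min,
                int(round(rng.normal(model.n_epochs_mean, model.n_epochs_sd))),
            )
            truth = simulate_true_hypnogram(night_model, n_epochs, rng)
            records[(subject, night, TRUTH_SCORER)] = truth
            for scorer_id in sorted(scorers):
                records[(subject, night, scorer_id)] = apply_scorer_noise(
                    truth, scorers[scorer_id], rng
                )
    return CohortDataset(records)


# --------------------------------------------------------------------------
# Default models: the study-like stand-in world.
# --------------------------------------------------------------------------

def default_transition_model() -> TransitionModel:
    """Truth dynamics for the default cohort.

    Strong self-transitions give realistic bout lengths (sleep-onset wake
    ~9 min, REM periods ~10 min, consolidated N2/N3 blocks).  REM is
    entered only from N2 and exits into deep sleep, so consecutive REM
    periods are separated by a long N2/N3 block — when a scorer misses a
    night's first REM period the next one usually lies well beyond the
    first 100 minutes, as in real sleep architecture.
    """
    #                 W      R      N1     N2     N3
    transition = np.array(
        [
            [0.9450, 0.0000, 0.0430, 0.0120, 0.0000],  # W
            [0.0150, 0.9500, 0.0050, 0.0000, 0.0300],  # R
            [0.0600, 0.0000, 0.6900, 0.2500, 0.0000],  # N1
            [0.0100, 0.0110, 0.0250, 0.9220, 0.0320],  # N2
            [0.0030, 0.0000, 0.0000, 0.0470, 0.9500],  # N3
        ]
    )
    initial = np.array([0.98, 0.0, 0.02, 0.0, 0.0])
    return TransitionModel(initial_dist=initial, transition=transition)


def _human_confusion() -> np.ndarray:
    # Technician-grade scorer: near-perfect wake recognition (technicians
    # do not mark consolidated pre-onset wake as sleep), disagreement
    # concentrated on N1 and on the timing of the N2/N3 transition,
    # essentially no spurious REM, U essentially unused.
    #                  W      R      N1     N2     N3     U
    return np.array(
        [
            [0.9900, 0.0005, 0.0060, 0.0025, 0.0000, 0.0010],  # W
            [0.0060, 0.9580, 0.0160, 0.0190, 0.0000, 0.0010],  # R
            [0.0520, 0.0030, 0.8450, 0.0990, 0.0000, 0.0010],  # N1
            [0.0040, 0.0030, 0.0230, 0.9370, 0.0320, 0.0010],  # N2
            [0.0020, 0.0000, 0.0000, 0.0670, 0.9300, 0.0010],  # N3
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],  # U (unused)
        ]
    )


def _auto_psg_confusion() -> np.ndarray:
    # Automatic scorer on full polysomnography: slightly below technician
    # accuracy, small N2-ward pull, occasional unclassifiable epochs.
    #                  W      R      N1     N2     N3     U
    return np.array(
        [
            [0.9760, 0.0020, 0.0120, 0.0060, 0.0000, 0.0040],  # W
            [0.0090, 0.9380, 0.0220, 0.0270, 0.0000, 0.0040],  # R
            [0.0600, 0.0090, 0.7950, 0.1320, 0.0000, 0.0040],  # N1
            [0.0050, 0.0060, 0.0260, 0.9210, 0.0380, 0.0040],  # N2
            [0.0030, 0.0000, 0.0000, 0.0930, 0.9000, 0.0040],  # N3
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],  # U (unused)
        ]
    )


def _auto_ear_confusion() -> np.ndarray:
    # Wearable (ear-EEG) automatic scorer: lower accuracy overall, a
    # systematic N3 -> N2 shift (N2 overestimated, N3 underestimated),
    # some wake mistaken for light sleep (missed brief awakenings), and
    # near-zero spurious REM from non-REM stages.
    #                  W      R      N1     N2     N3     U
    return np.array(
        [
            [0.9600, 0.0010, 0.0160, 0.0150, 0.0000, 0.0080],  # W
            [0.0200, 0.8700, 0.0380, 0.0640, 0.0000, 0.0080],  # R
            [0.1000, 0.0010, 0.6400, 0.2510, 0.0000, 0.0080],  # N1
            [0.0110, 0.0010, 0.0450, 0.8870, 0.0480, 0.0080],  # N2
            [0.0050, 0.0000, 0.0000, 0.1950, 0.7920, 0.0080],  # N3
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],  # U (unused)
        ]
    )


def default_scorer_models() -> dict[str, ScorerModel]:
    """The six default scorers of the study-like stand-in.

    ``S1``/``S2`` are independent technician-grade scorers; the four
    automatic scorers are one PSG-based classifier and three ear-EEG-based
    classifiers (trained on different label sources in the real study —
    here they share one wearable noise model and differ only in their
    random draws).  Human scorers miss a REM period occasionally; the
    wearable scorer does so with probability 0.2.
    """
    human = _human_confusion()
    ear = _auto_ear_confusion()
    return {
        "S1": ScorerModel(confusion=human, rem_run_miss_prob=0.08),
        "S2": ScorerModel(confusion=human.copy(), rem_run_miss_prob=0.08),
        "aut_psg_cons": ScorerModel(
            confusion=_auto_psg_confusion(), rem_run_miss_prob=0.10
        ),
        "aut_ear_1": ScorerModel(confusion=ear, rem_run_miss_prob=0.20),
        "aut_ear_2": ScorerModel(confusion=ear.copy(), rem_run_miss_prob=0.20),
        "aut_ear_cons": ScorerModel(confusion=ear.copy(), rem_run_miss_prob=0.20),
    }
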