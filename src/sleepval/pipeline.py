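"""End-to-end orchestration: cohort -> agreement -> metrics -> reliability.

``run_all`` takes a :class:`RunConfig`, obtains a cohort (from CSV or by
simulation), runs every analysis stage, and writes all result tables as
CSV files into one output directory together with a ``manifest.json``
mapping each artifact to its SHA-256 hash.  Identical (config, seed)
produce identical hashes.  Results go only to files; progress goes to the
logger, so the pipeline composes cleanly.

The default comparison pairs mirror a two-technician study with four
automatic classifiers: S1 vs S2, each technician vs the automatic PSG
scorer, and each technician vs each of the three ear-EEG scorers — nine
pairwise comparisons in total.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import agreement, metrics, reliability
from .core import (
    TRUTH_SCORER,
    CohortDataset,
    read_cohort_csv,
    write_cohort_csv,
)
from .errors import ConfigurationError, PipelineError
from .metrics import METRIC_NAMES
from .synth import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

#: The nine standard pairwise comparisons (first id is the reference side).
DEFAULT_COMPARISON_PAIRS: tuple[tuple[str, str], ...] = (
    ("S1", "S2"),
    ("S1", "aut_psg_cons"),
    ("S2", "aut_psg_cons"),
    ("S1", "aut_ear_1"),
    ("S2", "aut_ear_1"),
    ("S1", "aut_ear_2"),
    ("S2", "aut_ear_2"),
    ("S1", "aut_ear_cons"),
    ("S2", "aut_ear_cons"),
)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``cohort_source`` is either a path to a cohort CSV or a
    :class:`~sleepval.synth.CohortConfig`; ``None`` means the default
    synthetic cohort.  ``seed`` overrides the generator seed when a cohort
    is simulated.
    """

    cohort_source: str | Path | CohortConfig | None = None
    reference_scorer: str = "S1"
    comparison_pairs: tuple[tuple[str, str], ...] = DEFAULT_COMPARISON_PAIRS
    output_dir: str | Path = "sleepval_results"
    seed: int = 0
    max_nights: int = 4
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        pairs = data.pop("comparison_pairs", None)
        cfg = cls(**data)
        if pairs is not None:
            cfg.comparison_pairs = tuple((a, b) for a, b in pairs)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _obtain_cohort(config: RunConfig) -> tuple[CohortDataset, bool]:
    src = config.cohort_source
    if isinstance(src, (str, Path)):
        return read_cohort_csv(src), False
    if src is None:
        src = CohortConfig(seed=config.seed)
    elif isinstance(src, CohortConfig):
        src = dataclasses.replace(src, seed=config.seed)
    else:
        raise ConfigurationError(
            f"cohort_source must be a path or CohortConfig, got {type(src)}"
        )
    return simulate_cohort(src), True


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_all(config: RunConfig) -> dict[str, str]:
    """Run every stage and return {artifact filename: sha256}.

    On any stage failure a :class:`PipelineError` naming the stage is
    raised and partial outputs written by this run are removed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "configuration"
    try:
        dataset, generated = _obtain_cohort(config)
        known = set(dataset.scorer_ids)
        for a, b in config.comparison_pairs:
            if a not in known or b not in known:
                raise ConfigurationError(
                    f"comparison pair ({a!r}, {b!r}) names a scorer absent "
                    f"from the cohort; available: {sorted(known)}"
                )
        if config.reference_scorer not in known:
            raise ConfigurationError(
                f"reference scorer {config.reference_scorer!r} absent from "
                f"the cohort"
            )

        if generated:
            stage = "cohort"
            path = out_dir / "cohort.csv"
            write_cohort_csv(dataset, path)
            written.append(path)

        stage = "agreement"
        pooled_rows, night_frames = [], []
        for a, b in config.comparison_pairs:
            counts = agreement.pooled_confusion(dataset, a, b)
            n = int(counts.sum())
            pooled_rows.append(
                {
                    "scorer_a": a,
                    "scorer_b": b,
                    "n_epochs": n,
                    "percent_agreement": counts.trace() / n,
                    "kappa": agreement.kappa_from_counts(counts),
                }
            )
            cm_path = out_dir / f"confusion_{a}_vs_{b}.csv"
            pd.DataFrame(
                counts, index=list(agreement.STAGES), columns=list(agreement.STAGES)
            ).to_csv(cm_path, lineterminator="\n")
            written.append(cm_path)
            summary = agreement.per_night_kappa_summary(dataset, a, b)
            frame = summary.per_night.copy()
            frame.insert(0, "scorer_b", b)
            frame.insert(0, "scorer_a", a)
            night_frames.append(frame)
        path = out_dir / "kappa_pooled.csv"
        _write(pd.DataFrame(pooled_rows), path)
        written.append(path)
        path = out_dir / "kappa_per_night.csv"
        _write(pd.concat(night_frames, ignore_index=True), path)
        written.append(path)

        stage = "metrics"
        table = metrics.cohort_metrics_table(dataset)
        path = out_dir / "metrics.csv"
        _write(table, path)
        written.append(path)

        stage = "reliability"
        ref = config.reference_scorer
        paired_rows = []
        for a, b in config.comparison_pairs:
            if a != ref:
                continue
            for metric in METRIC_NAMES:
                comp = reliability.paired_comparison(table, metric, ref, b)
                paired_rows.append(
                    {
                        "reference": ref,
                        "alternative": b,
                        "metric": metric,
                        "n_pairs": comp.n_pairs,
                        "bias": comp.bias,
                        "sd_diff": comp.sd_diff,
                        "normalized_bias": comp.normalized_bias,
                        "normalized_sd": comp.normalized_sd,
                    }
                )
        path = out_dir / "paired_comparisons.csv"
        _write(pd.DataFrame(paired_rows), path)
        written.append(path)

        curve_rows, crossover_rows = [], []
        scorers = [s for s in dataset.scorer_ids if s != TRUTH_SCORER]
        for metric in METRIC_NAMES:
            curves = {}
            for scorer in scorers:
                curve = reliability.uncertainty_curve(
                    table, metric, scorer, max_M=config.max_nights
                )
                curves[scorer] = curve
                for m, value in sorted(curve.uncertainty_by_M.items()):
                    curve_rows.append(
                        {
                            "metric": metric,
                            "scorer": scorer,
                            "M": m,
                            "uncertainty": value,
                            "population_spread": curve.population_spread,
                        }
                    )
            for scorer in scorers:
                if scorer == ref:
                    continue
                crossover_rows.append(
                    {
                        "metric": metric,
                        "scorer": scorer,
                        "reference": ref,
                        "crossover_night": reliability.crossover_night(
                            curves[scorer], curves[ref]
                        ),
                    }
                )
        path = out_dir / "uncertainty_curves.csv"
        _write(pd.DataFrame(curve_rows), path)
        written.append(path)
        path = out_dir / "crossover.csv"
        _write(pd.DataFrame(crossover_rows), path)
        written.append(path)

        rem = reliability.rem_agreement_summary(
            dataset, list(config.comparison_pairs)
        )
        path = out_dir / "rem_agreement.csv"
        _write(rem, path)
        written.append(path)

        manifest = {p.name: _sha256(p) for p in written}
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except ConfigurationError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
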