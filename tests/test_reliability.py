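import math

import numpy as np
import pandas as pd
import pytest

from sleepval import (
    CohortDataset,
    Hypnogram,
    UncertaintyCurve,
    crossover_night,
    paired_comparison,
    rem_agreement_summary,
    rem_period_agreement,
    uncertainty_curve,
)
from sleepval.errors import (
    InsufficientDataError,
    SleepvalError,
    UndefinedOnsetError,
)


def long_table(values_by_scorer, metric="tst_min"):
    """Build a long metric table from {scorer: {(subject, night): value}}."""
    rows = []
    for scorer, values in values_by_scorer.items():
        for (subject, night), value in values.items():
            rows.append((subject, night, scorer, metric, value))
    return pd.DataFrame(
        rows, columns=["subject", "night", "scorer", "metric", "value"]
    )


def night_hypnogram(rem_latency_epochs, onset_epochs=4, n=400):
    """A night with sleep onset after `onset_epochs` wake epochs and a
    single REM run starting `rem_latency_epochs` after onset."""
    labels = ["W"] * onset_epochs + ["N2"] * n
    start = onset_epochs + rem_latency_epochs
    for i in range(start, min(start + 20, len(labels))):
        labels[i] = "R"
    return Hypnogram.from_stages(labels)


class TestPairedComparison:
    def test_hand_worked_bias_and_sd(self):
        table = long_table(
            {
                "S1": {("a", 1): 10, ("b", 1): 20, ("c", 1): 30},
                "alt": {("a", 1): 12, ("b", 1): 22, ("c", 1): 29},
            }
        )
        comp = paired_comparison(table, "tst_min", "S1", "alt")
        assert comp.bias == pytest.approx(1.0)
        assert comp.sd_diff == pytest.approx(math.sqrt(3), abs=1e-9)

    def test_identical_scorings_have_zero_bias_and_sd(self):
        values = {("a", 1): 10.0, ("a", 2): 20.0, ("b", 1): 15.0}
        table = long_table({"S1": values, "alt": dict(values)})
        comp = paired_comparison(table, "tst_min", "S1", "alt")
        assert comp.bias == 0.0
        assert comp.sd_diff == 0.0

    def test_normalisation_by_reference_spread(self):
        # |bias| = 2 against a reference s.d. of 4 -> normalized bias 0.5
        ref = {("a", 1): 0.0, ("b", 1): 4.0, ("c", 1): 8.0}  # sd = 4
        alt = {k: v - 2 for k, v in ref.items()}
        comp = paired_comparison(long_table({"S1": ref, "alt": alt}), "tst_min", "S1", "alt")
        assert comp.normalized_bias == pytest.approx(0.5)

    def test_pairwise_deletion_of_undefined_nights(self):
        table = long_table(
            {
                "S1": {("a", 1): 10, ("a", 2): float("nan"), ("b", 1): 20, ("c", 1): 30},
                "alt": {("a", 1): 12, ("a", 2): 99, ("b", 1): 22, ("c", 1): 29},
            }
        )
        comp = paired_comparison(table, "tst_min", "S1", "alt")
        assert comp.n_pairs == 3
        assert comp.bias == pytest.approx(1.0)

    def test_too_few_pairs_raises(self):
        table = long_table({"S1": {("a", 1): 1.0}, "alt": {("a", 1): 2.0}})
        with pytest.raises(InsufficientDataError, match="tst_min"):
            paired_comparison(table, "tst_min", "S1", "alt")


class TestUncertaintyCurve:
    def test_closed_form_values(self):
        # every subject has nightly variance 4 -> u(1) = 2, u(4) = 1
        values = {}
        for i, base in enumerate([10.0, 12.0, 14.0]):
            for night, delta in enumerate([-2, 0, 2], start=1):
                values[(f"s{i}", night)] = base + delta
        curve = uncertainty_curve(long_table({"A": values}), "tst_min", "A")
        assert np.allclose(curve.per_subject_variances, 4.0)
        assert curve.uncertainty_by_M[1] == pytest.approx(2.0)
        assert curve.uncertainty_by_M[4] == pytest.approx(1.0)
        # per-subject means are 10, 12, 14 -> population spread 2.0
        assert curve.population_spread == pytest.approx(2.0)

    def test_inverse_sqrt_m_law_exact(self):
        rng = np.random.default_rng(108)
        values = {
            (f"s{i}", n): float(rng.normal(400, 30))
            for i in range(6)
            for n in range(1, 5)
        }
        curve = uncertainty_curve(long_table({"A": values}), "tst_min", "A", max_M=4)
        u1 = curve.uncertainty_by_M[1]
        for m, u in curve.uncertainty_by_M.items():
            assert u * math.sqrt(m) == pytest.approx(u1, abs=1e-12)
        assert curve.uncertainty_by_M[4] == pytest.approx(u1 / 2, abs=1e-12)
        us = [curve.uncertainty_by_M[m] for m in sorted(curve.uncertainty_by_M)]
        assert all(a > b for a, b in zip(us, us[1:]))

    def test_single_night_subjects_excluded_with_warning(self, caplog):
        values = {("a", 1): 10.0, ("a", 2): 12.0, ("b", 1): 99.0}
        with caplog.at_level("WARNING", logger="sleepval.reliability"):
            curve = uncertainty_curve(long_table({"A": values}), "tst_min", "A")
        assert len(curve.per_subject_variances) == 1
        assert "excluded" in caplog.text

    def test_no_eligible_subject_raises(self):
        table = long_table({"A": {("a", 1): 10.0}})
        with pytest.raises(InsufficientDataError):
            uncertainty_curve(table, "tst_min", "A")

    def test_matches_resampling_oracle(self):
        """The closed form equals Monte-Carlo night resampling: draw M
        nights per subject with replacement, average, and pool the squared
        deviations of those averages from the subject means (matching
        population-variance denominator)."""
        rng = np.random.default_rng(109)
        per_subject = {
            f"s{i}": rng.normal(400, 30, size=4) for i in range(20)
        }
        values = {
            (s, n + 1): float(v)
            for s, nights in per_subject.items()
            for n, v in enumerate(nights)
        }
        curve = uncertainty_curve(
            long_table({"A": values}), "tst_min", "A", ddof=0
        )
        n_rep = 100_000
        for m in (1, 2, 4):
            sq = []
            for nights in per_subject.values():
                draws = rng.choice(nights, size=(n_rep, m), replace=True)
                sq.append(((draws.mean(axis=1) - nights.mean()) ** 2).mean())
            mc = math.sqrt(np.mean(sq))
            assert curve.uncertainty_by_M[m] == pytest.approx(mc, rel=0.03)


class TestCrossover:
    def _curve(self, metric, values, spread=1.0):
        return UncertaintyCurve(
            metric_name=metric,
            scorer_id="x",
            per_subject_variances=np.array([1.0]),
            uncertainty_by_M=dict(enumerate(values, start=1)),
            population_spread=spread,
        )

    def test_forced_crossover_at_two(self):
        wearable = self._curve("tst_min", [1.2, 0.849, 0.693, 0.6])
        reference = self._curve("tst_min", [1.0, 0.7, 0.57, 0.5])
        assert crossover_night(wearable, reference) == 2

    def test_crossover_at_one_when_already_better(self):
        wearable = self._curve("tst_min", [0.9, 0.63, 0.52, 0.45])
        reference = self._curve("tst_min", [1.0, 0.7, 0.57, 0.5])
        assert crossover_night(wearable, reference) == 1

    def test_no_crossover_returns_none(self):
        wearable = self._curve("tst_min", [3.0, 2.1, 1.7, 1.5])
        reference = self._curve("tst_min", [1.0, 0.7, 0.57, 0.5])
        assert crossover_night(wearable, reference) is None

    def test_metric_mismatch_rejected(self):
        with pytest.raises(SleepvalError):
            crossover_night(
                self._curve("tst_min", [1.0]), self._curve("sol_min", [1.0])
            )


class TestRemPeriodAgreement:
    def test_both_find_rem_early(self):
        rec = rem_period_agreement(night_hypnogram(140), night_hypnogram(140))
        assert rec.category == "agree"
        assert rec.latency_delay_min == 0.0

    def test_second_scoring_misses_first_period(self):
        # first REM at 70 min vs 130 min: only the first is in the window
        rec = rem_period_agreement(night_hypnogram(140), night_hypnogram(260))
        assert rec.category == "b_missed_first"
        assert rec.latency_delay_min == pytest.approx(60.0)

    def test_neither_finds_rem_within_window(self):
        rec = rem_period_agreement(night_hypnogram(220), night_hypnogram(240))
        assert rec.category == "both_late"

    def test_exactly_at_window_boundary_is_late(self):
        # latency of exactly 100 min falls outside the half-open window
        rec = rem_period_agreement(night_hypnogram(120), night_hypnogram(200))
        assert rec.category == "b_missed_first"
        both_in = rem_period_agreement(night_hypnogram(120), night_hypnogram(198))
        assert both_in.category == "agree"

    def test_undefined_onset_raises(self):
        awake = Hypnogram.from_stages(["W"] * 10)
        with pytest.raises(UndefinedOnsetError):
            rem_period_agreement(night_hypnogram(10), awake)


class TestRemAgreementSummary:
    def test_all_nights_agree(self):
        ds = CohortDataset(
            {
                ("s1", n, scorer): night_hypnogram(100)
                for n in (1, 2, 3)
                for scorer in ("A", "B")
            }
        )
        out = rem_agreement_summary(ds, [("A", "B")])
        assert out.loc[0, "agree"] == 1.0

    def test_category_fractions_sum_to_one(self):
        ds = CohortDataset(
            {
                ("s1", 1, "A"): night_hypnogram(100),
                ("s1", 1, "B"): night_hypnogram(100),
                ("s1", 2, "A"): night_hypnogram(100),
                ("s1", 2, "B"): night_hypnogram(260),
                ("s1", 3, "A"): night_hypnogram(220),
                ("s1", 3, "B"): night_hypnogram(230),
            }
        )
        out = rem_agreement_summary(ds, [("A", "B")])
        cats = out[["agree", "a_missed_first", "b_missed_first", "both_late"]]
        assert cats.sum(axis=1).iloc[0] == pytest.approx(1.0)
        assert out.loc[0, "b_missed_first"] == pytest.approx(1 / 3)

    def test_miss_probability_recovered_with_long_first_runs(self, rng):
        """With rem_run_miss_prob = 0.2, long unambiguous first REM runs
        and the second REM period far beyond the window, the fraction of
        wearable-missed nights estimates 0.2 (binomial, 200 nights)."""
        from sleepval import ScorerModel, apply_scorer_noise

        scorer = ScorerModel(confusion=np.eye(6), rem_run_miss_prob=0.2)
        records = {}
        for i in range(200):
            truth = night_hypnogram(60, n=500)  # REM at 30 min, no 2nd run
            records[(f"s{i}", 1, "A")] = truth
            records[(f"s{i}", 1, "B")] = apply_scorer_noise(truth, scorer, rng)
        out = rem_agreement_summary(CohortDataset(records), [("A", "B")])
        assert out.loc[0, "b_missed_first"] == pytest.approx(0.2, abs=0.06)
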