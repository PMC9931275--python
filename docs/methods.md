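# Methods

This note documents the models and conventions behind `sleepval`: what
the synthetic cohort generator emulates (and deliberately does not), how
its default parameters were chosen, the exact definitions used by the
analysis operations, and the numerical edge-case rules.

## Data model

A hypnogram is a non-empty sequence of 30-second epoch labels from the
six-class vocabulary W, R, N1, N2, N3, U ("unclassified"), indexed from
lights out; epoch *i* covers the half-open interval
[30·i, 30·(i+1)) seconds, and lights-on is defined as the end of the last
epoch (recordings are assumed scored from lights out to final wake-up, so
no separate lights-on marker exists). All confusion-matrix axes use the
fixed order (W, R, N1, N2, N3, U). A cohort maps
(subject, night, scorer) to hypnograms; all scorings of one night must
have equal length because they label the same recording, and missing
nights are simply absent keys. The single on-disk format is a long CSV
(`subject,night,scorer,epoch,stage`) — diffable, language-neutral, and
deliberately free of raw-signal formats.

## Synthetic cohort generator

### Truth model

Each night's true stage sequence is a first-order Markov chain over
(W, R, N1, N2, N3) — deliberately *not* semi-Markov: the analyses under
test consume label sequences, and bout-length realism is achieved through
strong self-transitions. Night length is drawn as round(N(960, 60))
epochs, floored at 600 (≈ 8 h of 30-s epochs; the floor only guards
degenerate draws).

The default transition matrix was chosen to give, at the same time,

* realistic bout structure: sleep-onset wake ≈ 9 min, REM periods
  ≈ 10 min, consolidated N2/N3 blocks;
* stage occupancy W ≈ 17 %, N2 ≈ 39 %, N3 ≈ 30 %, R ≈ 8–10 % of epochs;
* REM-cycle structure usable by the REM-period analysis: REM is entered
  only from N2 and exits into N3, so consecutive REM periods are
  separated by a long deep-sleep block and a night's *second* REM period
  usually lies well beyond 100 minutes after onset.

The last point is where a 5-state first-order chain is genuinely
limited: first-passage times to REM are sums of geometric sojourns and
therefore have high variance, so REM latency is more dispersed and REM
fraction lower (≈ 10 % vs a physiological 18–25 %) than in real sleep.
This trade-off was accepted deliberately — see "REM-period agreement"
below. The generated truth never contains U; only scorers produce it.

Between-subject and between-night variation is injected by adding
Gaussian noise (s.d. 0.30 per subject, 0.20 per night) to the logs of the
non-zero transition probabilities and renormalising rows; structural
zeros stay zero. This produces genuine within-subject night-to-night
variance in every sleep metric, which the reliability analysis requires;
the defaults yield single-night TST uncertainty of ≈ 40–45 min, in the
range a clinician would recognise for healthy young sleepers.

### Scorer model

A scorer is (1) a 6×6 row-stochastic confusion matrix applied
independently per epoch to the true stage, and (2) a REM-run miss
probability: each maximal run of true R is, independently, wholly
relabelled to N2 *before* the confusion noise. Whole-run relabelling
makes "the scorer missed the first REM period" a coherent event rather
than a scattering of epoch flips. The truth row for U is unused.

The six default scorers mirror a two-technician study with four automatic
classifiers: `S1`, `S2` (technician-grade; independent draws of one
confusion model), `aut_psg_cons` (automatic, PSG-based), and `aut_ear_1`,
`aut_ear_2`, `aut_ear_cons` (automatic, ear-EEG-based; in the emulated
study design these differ by training labels, here they share one noise
model and differ only in their random draws).

No stage-wise confusion rates are published for the study being emulated
— only pairwise kappas, one raw-agreement figure, bias directions and a
REM-miss rate. The default matrices are therefore *synthetic choices*,
calibrated once (before the acceptance tests were written, using the
closed-form expected-kappa oracle `expected_kappa` plus pilot cohort
simulations) so that the default world reproduces the reported behaviour:

* pooled κ(S1, S2) ≈ 0.83, per-night mean ≈ 0.82;
* pooled κ(technician, automatic PSG) ≈ 0.80;
* pooled κ(technician, ear-EEG) ≈ 0.71 (reported range 0.70–0.74);
* the ear scorer overestimates N2 % (bias ≈ +5 points) and
  underestimates N3 % (≈ −3.5), via an N3→N2 confusion of ≈ 0.20;
* technicians have near-perfect wake recognition and essentially no
  spurious REM; the ear scorer mistakes some wake for light sleep
  (missed brief awakenings) and emits ≈ 0.8 % U epochs;
* REM-run miss probabilities: 0.08 for each technician, 0.10 for the
  automatic PSG scorer, 0.20 for the ear scorers.

Two calibration lessons are worth recording. First, even small spurious
REM rates (≥ 0.003 per epoch from N1/N2) destroy the REM-period
analysis: an isolated false R epoch "finds" REM long before the true
first REM period, so a scorer's false-R rates must be ≈ 0.001, which
matches how classifiers behave (REM is rarely emitted in isolation).
Second, per-epoch wake→sleep confusion shrinks SOL toward zero and
inflates the variance of SOL differences; technicians do not mark
consolidated pre-onset wake as sleep, so the technician W row is nearly
diagonal (0.99).

All randomness flows through one `numpy` generator seeded from the
config; identical (config, seed) give byte-identical cohort CSVs.

### What a green test does not establish

The generator emulates label sequences and scorer disagreement, not
physiology: no semi-Markov bout durations, no circadian/ultradian time
structure beyond the REM-refractory trick above, no correlated errors
between scorers (real automatic scorers trained on technician labels err
*with* those technicians), no artifact/missing-data mechanism, and night
lengths are independent of sleep quality. Passing tests establish the
*analysis* is correct and behaves as published under a plausible
generative world — not that the world is physiologically complete.

## Agreement

Cohen's kappa over all six classes with `p_e` from the observed
marginals; classes absent from both scorings contribute zero. U is a
first-class label — not dropped, not merged into W (the convention choice
is visible in confusion matrices, where U rows/columns appear
explicitly). Pooled kappa concatenates every co-scored epoch of a cohort
(repeated measures ignored — the convention behind headline interrater
numbers, algebraically equal to kappa of the summed per-night confusion
matrices); per-night kappa is summarised separately (median, mean, n−1
s.d.). Degenerate cases never arise in realistic data but are pinned
down: two constant identical scorings give κ = 1, two constant different
scorings κ = 0, both logged.

## Sleep metrics

With 30-s epochs and sleep = {R, N1, N2, N3}: sleep onset is the first
sleep epoch (R counts — sleep-onset REM is real and the ear scorer can
produce it); TST = 0.5 min × sleep epochs; SOL = epochs before onset
× 0.5; SE = TST / total recording minutes; WASO counts W strictly between
first and last sleep epoch; REM latency = first R epoch at/after onset,
relative to onset (the alternative "first sustained R run" convention
would shift latencies by at most a couple of epochs and is not used);
REM/N2/N3 % use sleep-epoch count as denominator. N1 % is intentionally
not computed. U epochs are neither sleep nor wake: excluded from every
numerator and from percentage denominators, included only in the SE
denominator (they extend the recording).

A night with no sleep epochs has TST = SE = WASO = 0 and *undefined* SOL
and REM latency; a night with sleep but no REM has undefined REM latency
only. Undefined values are NaN throughout and are removed pairwise in
downstream statistics — a missed REM period is a categorical event, not a
latency of zero.

## Reliability

* **Paired comparison** — bias = mean(alternative − reference) over
  complete pairs (positive bias ⇒ the alternative overestimates);
  s.d. of differences with n−1 denominator; normalized bias/s.d. divide
  |bias| and s.d. by the n−1 s.d. of the metric under the reference
  scoring over the same pairs. At least two complete pairs are required.
* **Uncertainty curve** — uncertainty(M) = sqrt(meanₙ σ²ₙ / M), the
  within-subject standard error; σ²ₙ uses the n−1 denominator by default
  (a `ddof` parameter exists because the equivalent night-resampling
  bootstrap matches the population-variance denominator; the package
  tests both). Subjects need ≥ 2 defined nights, others are excluded
  with a warning. The 1/√M law holds exactly by construction, and
  uncertainty(4) = uncertainty(1)/2.
* **Crossover night** — smallest M with wearable uncertainty(M)
  *strictly* below the reference's uncertainty(1); `None` if no M
  qualifies within the nights available.
* **Population spread** — n−1 s.d. of per-subject mean values, the
  between-subject reference scale.
* **REM-period agreement** — each scoring is tested for an R epoch
  within 100 minutes (half-open: latency < 100) after its *own* sleep
  onset; nights fall into agree / a-missed / b-missed / both-late, with
  the absolute latency difference reported when both latencies exist.

On the default world the measured wearable first-REM miss fraction is
≈ 0.19 against a generative run-miss probability of 0.20: a few misses
are masked by a second REM period inside the window, a few nights have
REM beyond 100 minutes under both scorings (both-late), and the two
effects nearly cancel. Exact equality is unattainable in a 5-state
first-order chain (geometric-tailed REM-cycle times); the residual gap
is documented rather than hidden by parameter tweaks.

## Pipeline

`run_all(RunConfig)` validates the configuration (unknown scorer ids
fail before any computation), then runs cohort → agreement → metrics →
reliability, writing every table as CSV plus a `manifest.json` of SHA-256
hashes; identical (config, seed) give identical hashes, and any stage
failure removes that run's partial outputs. The default comparison pairs
are the nine of the emulated study design: (S1,S2), each technician vs
`aut_psg_cons`, and each technician vs each of the three ear scorers.
Results go only to files; progress goes to the logger.

## Known limitations

* The first-order truth chain under-disperses REM fraction and
  over-disperses REM latency relative to real sleep (see above).
* Scorer errors are conditionally independent across scorers given the
  truth; correlated errors would lower effective agreement between
  automatic scorers and their training technicians.
* The reliability formula assumes nights are exchangeable within subject
  (no first-night effect, no trend); σ²ₙ from ≤ 4 nights is itself a
  noisy estimate, which is why uncertainty curves should be read at
  cohort level, not per subject.
* `paired_comparison` drops nights with undefined values, so REM-latency
  bias/s.d. condition on both scorings having found REM at all; the
  categorical REM table is the complementary view.
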