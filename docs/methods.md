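# Methods

This note documents the models, estimators and design choices behind
`gammarep`: what the synthetic recordings emulate, how each statistic is
defined, and where the design was genuinely open.

## Synthetic recordings

### Task sequences

*Natural-image design.* Each trial's stimulus is drawn pseudorandomly from a
rolling subset of `subset_size` (default 3) stimuli; a stimulus that has
reached its repetition quota is replaced by a fresh one from the full set.
The lag — the number of other-stimulus trials since a stimulus's previous
presentation — is capped at `max_lag` (default 4) by a forced-pick rule: a
subset member whose lag has reached the cap is drawn next. Among
already-presented stimuli the lags are pairwise distinct (each presentation
resets one counter; all others advance by one), so at most one stimulus is
ever at the deadline and the greedy rule can never violate the constraint.
Conversely, more than `max_lag + 1` concurrently active presented stimuli
would force a violation by pigeonhole, so `subset_size > max_lag + 1` is
rejected as infeasible. With 25 stimuli and 20 repetitions each, one block
is exactly 500 trials. An optional prefix interleaves two "dummy" stimuli
with reduced repetition counts with the first set stimulus, so that set
stimuli do not all begin their sequences simultaneously.

*Change times.* The interval from stimulus onset to the behavioral-change
event is a standard Weibull draw, f(t; a, b) with scale `a = 0.27` s and
shape `b = 2`, i.e. a hazard rising linearly in time. The printed source
formula is ambiguous about the scaling (and its claimed ~2 s mode is
inconsistent with a = 0.27 under any standard reading); we expose the
standard parameterization plus an additive offset. The natural-image
generator offsets draws by 1.8 s — the minimum stimulus duration — which
places the mode near 2.0 s and reconciles the two statements. Grating tasks
use a uniform 1.5–2.3 s interval.

*Block designs.* Stimulus-identity designs are strings over {A, B}
(e.g. ABA, BBA; 100 trials per block by default), location designs strings
over {In, Out} (50 trials per block). Block labels use bracket notation
(`A[B]A` = second block of ABA). `repetition_number` counts consecutive
same-stimulus (or same-location) trials and continues across adjacent
identical blocks; `trial_in_block` restarts at 1 in every block.

### Ground-truth trajectories

Per stimulus, the gamma response gain follows either

- a piecewise-linear function of repetition number with a hinge at
  repetition 4 (separate early/late slopes; natural-image design), or
- `1 + offset + b·log10(trial-in-block)` (block designs).

The block `offset` implements persistence: when a stimulus (or location)
returns after intervening blocks, a fraction `persistence` per intervening
block of its previously accrued gain carries over. MUA gains use the same
hinge form with (typically negative) decay slopes.
`specificity_transfer` ∈ [0, 1] mixes each stimulus's trajectory with the
across-stimulus mean: 0 = fully stimulus-specific, 1 = fully shared. Default
per-stimulus parameters (`GroundTruth.random`) are chosen to be realistic
for V1: gamma peaks 45–75 Hz, stimulus/baseline power ratios 2–4, early
gamma slopes N(−0.03, 0.06) per repetition (variable in sign, slightly
negative on average), late slopes N(+0.02, 0.025), MUA decays of a few
percent per early repetition (≈10 % over 15 repetitions), a ~2 Hz/decade
gamma-frequency drift, and for block designs a log-slope of ≈0.25/decade,
i.e. ≈50 % gamma growth over a 100-trial block.

### Signals

LFP = unit-variance 1/f^α background (α = 1) plus a stimulus-gated
narrowband gamma process: Gaussian-envelope (spectral SD 5 Hz) filtered
noise centered at the per-trial peak frequency, gated at stimulus onset with
a 20 ms cosine ramp. The gamma waveform is shared across sites up to a fixed
±10 % per-site gain, emulating the spatial coherence of V1 gamma. Its
variance is calibrated so that the stimulus/baseline power ratio at the peak
frequency — *as measured by the ±10 Hz multitaper estimator*, which averages
the bump over 2W of bandwidth — equals `gamma_base_power × gain`. The
baseline spectral density entering the calibration is estimated from the
generated background itself (Welch, 250 ms segments). Narrower-band
estimators (500 ms Hann) therefore read a higher peak ratio; the multitaper
configuration is the gamma-band workhorse and the calibration target.

MUA = per-site noise floor + spontaneous rate + stimulus drive (onset
transient at ~70 ms plus saturating sustained component), multiplied by
`1 + κ·g(t)` where g is the unit-variance gamma waveform and κ the locking
strength (default 0.4) — this produces MUA–LFP phase locking at the gamma
frequency (PPC). Gaussian noise with SD ∝ √rate is added and the envelope
clipped at zero. Trials with the stimulus outside the receptive fields
(`location = Out`) drive gamma and MUA at 10 % gain.

Session-to-session variability enters as a ±10 % multiplicative jitter per
stimulus trajectory per session, and in the trajectory-level generator
(`synthesize_gamma_trajectories`) as i.i.d. noise with SD 0.25 × each
stimulus's mean level. The noise is multiplicative (proportional to
response level) deliberately: response variance grows with response mean in
neural power measures — the very reason the specificity analysis z-scores —
and an absolute noise floor would make per-stimulus reliability differ,
breaking stimulus exchangeability even when trajectories are fully shared.
With the default noise level, ten-session runs give split-half correlations
of ≈0.3–0.5, the reliability scale typical of session-resolved gamma
measurements.

What the generator does *not* emulate: broadband (>250 Hz) structure and
spike waveforms, realistic retinotopy or receptive-field geometry,
inter-areal interactions, eye-position-dependent response modulation, slow
non-stationarities within a session, and line noise/artifacts. Passing
tests therefore demonstrate correctness and calibration of the estimators
under the assumed signal model, not robustness to every pathology of real
recordings.

## Preprocessing

Bins and epochs are half-open `[start, stop)`; sample i covers
`[i/fs, (i+1)/fs)`. dMUA averages the MUA envelope in 10 ms bins over
−1…1.5 s and subtracts the per-site minimum binned value over all trials
and bins (the minimum is taken over binned means, not raw samples, matching
the stated order of operations). Rate smoothing is a 20 ms-SD Gaussian with
reflection padding; latency-sensitive analyses use unsmoothed data.
Baseline normalization always divides by the *session-average* baseline per
site (never per trial): spectra by the trial-averaged −1…0 s spectrum, dMUA
by the −0.95…0 s rate. Epochs are left-aligned, non-overlapping;
`floor(window/epoch_len)` per trial.

## Spectral estimation

FFT length equals epoch length (no zero padding): 4 Hz grid for 250 ms
epochs, 2 Hz for 500 ms. Tapers are unit-energy; DPSS taper count follows
K = 2TW, which yields 5 tapers at T = 0.25 s, W = 10 Hz. The alternative
convention K = 2TW − 1 (4 tapers) is available via `TaperConfig(k_rule=)`.
Power is |tapered FFT|² averaged over tapers, then over within-trial epochs,
giving per-trial spectra; cross-trial statistics operate on those.

Cross-spectra (LFP × conj(MUA), summed over tapers) are normalized to unit
magnitude per epoch; PPC over N pooled epochs uses the closed form
`(|Σz|² − N)/(N(N−1))`, equal to the mean pairwise cosine and unbiased by N.
MUA–LFP pairs are restricted to direct array neighbors, same-electrode pairs
excluded; a MUA site's PPC is averaged over its neighboring LFP sites.
The default analysis windows are 0.5–1.5 s post-onset (stimulus) and
−1–0 s (baseline).

## Gamma peaks

Peaks are strict local maxima of the relative power spectrum between 20 and
190 Hz, ranked by height (ties toward the lower frequency), two kept per
site/stimulus. Validation is a one-sided permutation test (1000
permutations) of trial-wise mean power in peak ± 8 Hz against 190 ± 8 Hz —
a reference chosen above any spike-leakage plateau — where each permutation
re-assigns the two band labels independently per trial (the permutation
unit is the trial; the source is silent on trials vs epochs). Band means
use the bins fully inside ± 8 Hz (± 16 Hz for natural-image band scalars);
on the 4 Hz grid these bands are symmetric. Sites are grouped by connected
components of "largest peaks within ± 16 Hz"; alignment shifts spectra by
integer grid bins so each peak sits at relative frequency 0. Gamma analyses
require ≥ 5 sites with a validated peak per stimulus, ≥ 8 correct trials
(≥ 4 for early-segment fits).

## Repetition metrics

Trajectories are z-scored with the population (N) SD — the repetitions of a
stimulus are the full population of interest, and the affine invariance of
the z-score is what removes offset and gain differences between stimuli.
Slopes are ordinary least squares over the early (repetitions 1–4) or late
(5 onward; 5–15 for natural images) segment; block designs regress on
log10(trial-in-block) with trials 1–4 excluded. RRC =
r_last / (0.5·(r_last + r_first)) with both endpoints evaluated *from the
fit*; |r_first + r_last| < 10⁻⁶ is treated as degenerate, excluded and
counted (the plain ratio r_last/r_first is unstable near zero, which is why
the symmetrized denominator is used). RRC = 1 iff the fitted slope is zero.

Drive dependence: per session and stimulus–site combination, two OLS fits on
interleaved repetition subsets (one half takes every second repetition
starting with the first, the other starting with the second); medians across
sessions; Spearman correlation of one half's slope against the *other*
half's intercept, both directions averaged. The interleaving removes the
mechanical coupling between a fit's own slope and intercept (verified by a
bias test). The floor-effect control median-splits combinations by
intercept (odd counts: extra point to the lower half), tests each half's
correlation against 1000 intercept randomizations, and FDR-corrects across
the two halves.

## Stimulus specificity

Per session, site and stimulus, the trajectory of the analyzed feature is
z-scored across repetitions; site-averaged; concatenated in a canonical
(lexicographic) stimulus order into one session vector; sessions under 50 %
vector coverage are dropped. The statistic is the Pearson correlation
between the average vectors of two random equal-size session halves
(⌊n/2⌋/⌈n/2⌉ for odd n), averaged over s = 100 splits, then over animals.
Missing entries use pairwise-complete correlation.

The permutation null re-randomizes stimulus identity: each of 1000
iterations draws an independent random stimulus order *per session*,
relabels the stimulus blocks, and recomputes the full split-averaged
statistic on the same s splits. Under the null (trajectories carry no
stimulus information) the per-session blocks are exchangeable, so the
relabeling is a distribution-preserving group action and the Monte-Carlo
randomization test is exact. An alternative scheme — permuting only the
half-2 average vector with a fresh order per split — was implemented and
rejected: because the observed statistic averages the same splits (and thus
the same sessions), that null's conditional spread collapses and the test
rejected ~85 % of fully-shared-trajectory datasets at α = 0.05. The scheme
used here measures 4–8 % rejection at `specificity_transfer = 1` and ≥ 90 %
power at `transfer = 0` with 10 sessions, monotone in between. Two-sided p
values take the doubled one-sided exceedance (floor 2/n_perm); per-bin
results (frequency spectra, dMUA time courses) are BH-FDR corrected.

## Shared statistics

Sign-flip test: observed = mean of session-level values (stimuli/animals
averaged upstream); null = means after random per-session sign flips.
Exchange test: per-session random swap of two paired condition values
(equivalently a sign flip of the difference). Both use 1000 permutations and
the two-sided convention p = min(1, 2·max(min(c_≥, c_≤), 1)/n_perm), so the
minimal p is 0.002; both are calibrated to nominal level in 500-run null
simulations. Bootstrap SEM resamples sessions with replacement (1000
draws) within stimulus, averages across stimuli then animals, and reports
the SD of the resampling distribution; plots use ±2 SEM. FDR control is
Benjamini–Hochberg step-up at 0.05 (the cited correction gives no formula;
BH is the standard step-up procedure at the stated rate). Location-block
contrasts first bin responses in centered ±3-trial windows.

Block-design regression: OLS on log10 responses (so strong-response stimuli
do not dominate) with log10 repetition terms, block-indicator main effects
(intercept shifts = persistence/specificity) and their interactions with
the log-repetition term (slope changes), categorical session/stimulus
terms, and behavioral covariates (microsaccade rate, pupil response, ISI,
previous stimulus duration, reaction time, overall trial number). Partial
variance explained is type-II partial η²; rank-deficient fits report
aliased terms as NaN.

## Behavior

Microsaccade detection: gaze smoothed with a ±5 ms boxcar; velocity from
differences across samples 10 ms apart; threshold λ·c per axis with
c = √(median(v²) − median(v)²) and λ = 6; suprathreshold runs on either
axis merge into single events. The square root is deliberate — the printed
criterion omits it, but without it the threshold comparison is
dimensionally inconsistent (c must carry velocity units). c is
scale-equivariant, not offset-invariant (the median shifts). Pupil traces
are z-scored against the single-trial −1…0 s baseline; zero-variance
baselines are flagged.

## Pipeline, problem sizes, determinism

`run_dataset1_analysis` chains generator → preprocessing → spectra → peak
detection/validation (trials pooled across sessions) → gamma-band and dMUA
trajectories → slopes/RRC with sign-flip and exchange tests → drive
dependence → specificity (gamma scalar, 20–100 Hz correlation spectrum,
100 ms-binned dMUA time course). `run_block_analysis` builds ABA/BBA or
In/Out sessions, fits per-block log-trial regressions, and runs the
specificity/persistence contrasts (A[B]A vs B[B]A, AB[A] vs BB[A] between
sessions, AB[A] vs [A]BA within session; Out[In] vs In[In] and InOut[In] vs
OutOut[In] for locations) plus the single-trial regression model. LFP power
analyses default to unipolar signals: the generator's gamma is a
common-mode component across sites, which a common-average reference would
cancel; the derivation modes remain available in `preprocess.derive_sites`.

Default demonstration sizes (6–10 sessions, 4–6 stimuli, 3–4 sites,
12–18 repetitions, 50–100-trial blocks) are chosen so a full run takes
seconds while every test retains its planted effect at comfortable margins;
the generator's task-structure constants (25 × 20 natural-image blocks,
subset 3, lag 4, 100-trial grating blocks, 50-trial location blocks, fs =
500 Hz, peri-stimulus window −1.3…1.5 s) are the experiments' design
constants and are not tuned. The
simulated-correctness option (higher Bernoulli error rate on repetitions
1–3, repetition numbers recounted over correct trials) is off by default in
the pipeline demos and exercised directly in tests. All randomness flows
from explicit seeds through `numpy.random.Generator`; reports are
byte-reproducible under a fixed seed and include an exclusion ledger
(low-coverage sessions, unvalidated stimuli, degenerate RRCs).

## Known limitations

- The gamma calibration targets the ±10 Hz multitaper readout; absolute
  peak ratios under other estimators differ by the bandwidth ratio.
- Peak detection on ±10 Hz-smoothed relative spectra has a flat top; with
  few trials the argmax can land one 4 Hz bin off the injected frequency
  (the 2 Hz Hann grid resolves it).
- The NaN-tolerant specificity path (missing repetitions) falls back to an
  O(n_perm · s) loop and is markedly slower than the dense path.
- `fit_block_regression` is fixed-effects OLS; mixed-effects variants are
  out of scope.
- Exchange-test pairing for between-session contrasts pairs sessions by
  order within each condition list; with unequal counts the surplus is
  dropped.
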