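# Methods

This note records the modelling choices, parameter conventions and
known limitations of the `sfpa` package, in the spirit of a methods
appendix: what the procedures assume, where the design was genuinely
open and which option was taken, and what the synthetic benchmark does
and does not establish.

## Time and event conventions

* TR indices are 0-based.  A window "centered on" TR *t* spans
  [t − 7, t + 7] inclusive — 15 samples for the default window.
* Event timestamps map to TRs by `round(onset_s / tr_seconds)` with
  half-away-from-zero rounding (NumPy's default half-to-even would make
  the mapping depend on parity).
* The event table is the single source of temporal order.  Every
  event-indexed vector (states, event-level ISFC, peak windows) aligns
  to its row order; mismatched event sets raise rather than silently
  reindex.
* Events whose onset TR lacks seven TRs on either side of the valid
  sliding-window range are discarded at downsampling.  A 946-TR scan
  has 932 valid window centers (TRs 7…938).

## ISFC

The unit of analysis is the ROI time series (one z-scored row per
region); voxel-level extraction is upstream of this package.  Rows are
standardized at load (population sd) because Pearson correlation is
scale-free but the leave-one-out average is not.

The directional statistic — one subject's region-i window against the
other subjects' average region-j window — is computed in both
directions and the two Fisher-z values averaged, yielding an exactly
symmetric pair matrix; the diagonal is the ISC.  Averaging across
subjects happens in Fisher-z space, and `ISFCSeries.r` maps back to
the correlation scale for reporting.

Numerical guards: correlations are clipped to ±(1 − 1e−7) before
`atanh`, so z stays finite for degenerate windows; a window with zero
variance on either side contributes r = 0 (keeping the subject count
constant at every TR) and is counted in
`ISFCSeries.n_zero_variance_windows` rather than dropped.

The sliding computation uses cumulative-sum window moments and an
outer-product cross-term, giving exact per-window Pearson values (the
unit suite checks agreement with a per-window `np.corrcoef` loop to
1e−12) at roughly three orders of magnitude less time than the naive
loop.

## Behavioral processing

Ratings are z-scored per participant and measure with sample (ddof=1)
standard deviation, then averaged across the participants who rated
each event.  Because the questionnaire assigns each participant one of
three chronologically interleaved event subsets, each event's group
mean pools a different rater subset; rater counts are carried with
every state vector.  Participant-measure cells with zero variance are
excluded with a warning — a constant response carries no ordering
information and cannot be standardized; exclusion, not imputation, is
the rule.

Peak selection takes the k = 5 largest state values; ties break toward
the earlier event, making peak sets deterministic.

The collinearity control is a partial correlation: both vectors are
residualized against the covariate set plus an intercept by least
squares, and the residuals correlated.  With no covariates this equals
the plain Pearson correlation exactly, which the suite asserts.

## Permutation inference

* **Event shuffle** (correlation SFPA): the event-level ISFC vector is
  permuted and re-correlated with the intact state vector; two-tailed
  p compares |r|.  P values use add-one smoothing,
  p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_iter), so a sampled p is
  never zero — a deliberate, documented divergence from a raw
  percentile, standard for sampled permutation tests.
* **Peak max-difference**: two *disjoint* random five-event sets per
  iteration ("an additional five" is read as disjoint); the statistic
  is the max over the 29 bins of the absolute difference of set means;
  rejection compares the observed statistic to the 95th percentile of
  the null maxima (one-tailed).
* **Pair peak**: the mean event-level ISFC of five random events forms
  the null for the observed five-peak-event mean (one-tailed), with
  BH-FDR across pairs.
* **Phase randomization** (full-length ISFC): surrogates preserve the
  amplitude spectrum exactly — DC and (for even length) Nyquist bins
  untouched, positive-frequency phases replaced and mirrored
  conjugate-symmetrically.  The default draws phases i.i.d. uniform on
  [0, 2π); `mode="permute"` instead permutes the original phases, since
  "shuffling the phases" admits both readings.  Every subject is
  randomized each iteration and correlated against the leave-one-out
  mean of the surrogates; the max |r| over pairs and subjects forms the
  familywise null.

Reproducibility: each (pair, measure) test draws from its own child
stream (`SeedSequence(root_seed, spawn_key=...)`), so results are
bit-identical under a fixed seed and independent of evaluation order.

BH-FDR is delegated to `statsmodels.stats.multitest.multipletests`;
the test suite validates it against a from-scratch transcription of
the step-up definition on 1000 random p-vectors.  NaN entries
(undefined tests, e.g. constant inputs) pass through unrejected and do
not count toward the number of hypotheses.  FDR is applied across
region pairs separately within each behavioral measure, matching the
per-measure pair matrices the analysis reports.

Parametric p values and Fisher-z CIs are reported alongside, but
significance calls are permutation-based.  The CI is
tanh(atanh r ± z₀.₉₇₅/√(n−3)); this construction reproduces the four
published interval endpoints at 2-decimal rounding, which is the
package's CI acceptance check.

## Peak analysis conventions

ISFC series are z-scored per pair across the movie (ddof=1) before
event-triggered averaging, putting pairs on a common scale.  Event
windows have 29 bins (onset ± 14); bin b holds the 15-TR window score
centered at onset + b, so bin +1 spans event TR −6 … +8.  Bins whose
window center falls outside the valid range are missing and excluded
from averages (not zero-filled).  Network averages pool all
off-diagonal pairs whose two ROIs are both in the network; ISC
diagonal entries are excluded so coactivation is not mixed with
single-region reliability.  Onset-bin summaries (mean ± SEM across
subjects) use bin t = 0.

## Synthetic data generator

The generator encodes the assumptions the ISFC logic relies on:
subject signal = group-common stimulus-driven component + idiosyncratic
AR(1) noise.  Per ROI r,

    c_r(t) = g_r(t) + [r ∈ coupled] · (a0 + β·s(e)) · u(t)   (t in event e's ±7-TR window)

with g_r and u independent AR(1) group-common processes and s(e) i.i.d.
standard-normal latent surprise.  Where event windows overlap, the
contributions of all covering events sum.  The effect is multiplicative
on a *shared* signal, so it changes inter-regional correlation without
adding a surprise-locked univariate response — which is why Control I
comes out null on synthetic data with planted coupling.

Defaults are the target study configuration: 35 subjects, 946 TRs at
1.5 s, 49 events at ~30-s intervals (spacing compresses slightly to
~28.6 s so every event keeps the ±7-TR retention margin inside a
23.6-minute scan), 31 ROIs (10 DMN, 12 DAN, 4 Vis, 5 subcortical), 45
raters in three interleaved subsets.  Operating-point parameters were
fixed once by pilot simulation and not revisited:

| parameter | default | meaning |
|---|---|---|
| `coupling_beta` | 1.5 | surprise slope of the coupling gain (z-units of s per unit u) |
| `baseline_gain` (a0) | 1.5 | event-window coactivation at s = 0 |
| `shared_signal_sd` | 1.0 | sd of the per-ROI group-common signal (vs. noise sd 1) |
| `noise_sd` | 1.0 | sd of per-subject idiosyncratic AR(1) noise |
| `ar1_phi` | 0.3 | lag-1 autocorrelation, BOLD-like at TR = 1.5 s |
| `rating_noise_sd` | 1.0 | rater noise before rounding/clipping to the 1–7 scale |

Ratings are `clip(round(4 + 1.5·s + η), 1, 7)`; free-recall unit
counts use the same latent with a shifted, floored transform giving
non-negative integers around 0–8.  A `collinearity` knob correlates
the emotional-intensity latent with surprise for confound studies.
Per-frame luminance/saliency features track a smooth positive
amplitude envelope on a Vis-network shared component, so
feature-driven coactivation appears in Vis pairs and not DMN pairs —
the dissociation Control II is meant to detect.

**What passing synthetic tests shows — and does not.**  The generator
produces Gaussian AR(1) signals with a single planted latent; it has
no hemodynamic response function, head motion, physiological artifact,
scanner drift, inter-subject anatomical variability, or narrative
structure in the latents.  Recovery results therefore validate the
*estimator and inference chain* (that the pipeline finds exactly the
planted coupling at correct error rates), not the neuroscientific
claims one could only test on real data.

## Benchmark problem sizes

The package's acceptance checks run at reduced scales chosen as the
smallest configurations that exercise every code path with stable
statistics: type-I calibration on 25 null datasets of 10 subjects ×
300 TRs × 30 events (500 pair×seed draws, 500 iterations per test);
recovery on 20 datasets of 15 subjects × 400 TRs with the default 49
events (at this length event windows overlap — the summed-gain model
handles this — and the network-level surprise correlation still
recovers at r ≈ 0.7).  Full-scale runs (35 × 946) take a few minutes
and are exercised only for structural counts.

## Known limitations

* Optional NIfTI ingestion is out of scope; ROI × TR matrices are the
  input contract.
* The repeated-measures ANOVA reported alongside the original peak
  analysis is not implemented; network contrasts here are
  permutation-based only.
* Free-recall scoring into memory / theory-of-mind units is a manual
  annotation step; the package ingests the counts.
* `max_null_isfc` at full scale (1000 iterations × 35 subjects × all
  pairs) is the most expensive routine; for exploratory work reduce
  `spec_n_iter` and treat the threshold as approximate.
* Fisher-z CIs assume bivariate normality across events; event-level
  ISFC scores from overlapping windows are weakly dependent, so the
  permutation p values are the primary inference.
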