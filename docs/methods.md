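# Methods

This note documents the models, conventions and design choices behind the
package; every empirical number it mentions is computed by the test suite
or by `scripts/acceptance.py` at run time.

## The analysis problem

During NREM sleep, cortical slow oscillations (SOs, < 1 Hz) group
thalamocortical spindles (12–16 Hz) in their excitable up-states, and
hippocampal/MTL sharp-wave ripples (80–120 Hz in humans) nest toward the
troughs of spindles. TMR replays learning-associated sound cues during
sleep; the hypothesis the pipeline operationalizes is that memory content
becomes decodable around spindle-locked ripples. The chain is: detect
ripples and spindles → quantify spindle-phase/ripple-amplitude coupling →
train a classifier on awake retrieval data → test it on sleep data, either
across all cue-locked time points (temporal generalization) or re-epoched
around spindle-locked ripples, against a ripple-free surrogate.

## Synthetic data generator

The generator produces the statistical structure this chain assumes, not a
biophysical simulation (no neural-mass models, no artifacts, no REM):

* **Background**: Gaussian 1/f^slope noise per channel (FFT shaping),
  default slope 1 and SD 10 µV. The slope is verified against a
  periodogram fit (log-PSD slope over 1–40 Hz within ±0.3 of −1).
* **Events**: SO half-waves (0.8 Hz cycle, 60 µV) with a Gaussian-windowed
  spindle burst (13 Hz carrier, 0.75 s — the spindle envelope uses
  SD = duration/4 so that the detector's supra-threshold extent matches
  the nominal duration) centred on the SO up-state, on all cortical
  channels; ripple bursts (90 Hz carrier, 100 ms, envelope SD =
  duration/6, negative peak at centre) on MTL channels. Burst amplitudes
  are expressed relative to the broadband background SD (defaults:
  spindles and ripples 4×), which puts detection thresholds — computed
  over all data points including the events — comfortably between
  background and burst level, as in real recordings where ripples stand
  out of the filtered background.
* **Coupling**: each ripple is placed where the spindle carrier phase
  equals an angle drawn from von Mises(μ, κ); μ defaults to ±π (the
  spindle trough, matching the phase convention below) and κ to 2.
  κ = 0 yields circularly uniform placement; κ ≥ 500 is treated as the
  degenerate case (all angles exactly μ). Event counts are deterministic
  functions of the rates (ripples = round(rate × spindles)), so rate
  doubling doubles counts exactly.
* **Task structure**: retrieval and TMR trials at 5.5 ± 0.2 s intervals,
  epochs [−1, 3] s around onset, balanced left/right classes (plus a
  control cue in TMR). Class identity is carried by one fixed multichannel
  template per class, shared between retrieval and TMR (cross-task
  classification presupposes shared patterns), scaled by `pattern_snr`
  (default 1.0) × background SD, added as a boxcar: in retrieval inside
  [0.1, 0.6] s for remembered trials only (not-remembered trials carry no
  pattern — the generative analogue of their non-decodability), in TMR
  locked to the injected ripple (±150 ms) in learning-cue trials only.
  Retrieval trials additionally carry MTL ripples at ~0.45 s with a higher
  rate for remembered (1.0/trial) than for not-remembered (0.3/trial)
  trials, so the remembered-vs-not ripple-rate contrast has a known
  direction.
* **Determinism**: one `numpy` generator seeded from `SimParams.seed`
  drives every draw in a fixed order (background channel-by-channel,
  jitters, angles, templates, flags); identical parameters give
  bit-identical data.

Defaults are desk-scale (8 channels, 10–40 trials per class, minutes of
data) rather than study-scale; they exercise every code path while keeping
the full test suite and acceptance run in minutes on one CPU. What passing
tests show is that the implementation recovers known structure under the
generator's assumptions (Gaussian background, stereotyped bursts, fixed
templates); they cannot show robustness to artifacts, non-stationarity,
electrode heterogeneity or epileptiform activity, which real-data users
must handle upstream.

## Preprocessing

Scalp data are downsampled to 200 Hz (polyphase resampling with
anti-aliasing); iEEG stays at its native 1000 Hz. Epoching takes the
nearest sample to each onset; out-of-range onsets are dropped with a
warning. Z-scoring across trials uses the sample SD (n − 1); zero-variance
cells are set to 0 with a warning. The 150 ms running average rounds to an
odd sample count (31 samples at 200 Hz) and shrinks its window at the
edges so the output length equals the input. CAR, whole-trial baseline and
z-scoring are idempotent (tested to 1e−10).

## Event detection

Both detectors share one machinery: zero-phase Butterworth band-pass
(order 3 per pass), centred RMS over a window, same-length smoothing, a
threshold of mean + k·SD of the smoothed RMS over the caller's scope (all
data points by default — for epoched data trials are concatenated so the
statistics span the whole set, and boundary-straddling events are
discarded), merging of supra-threshold runs separated by < 20 ms, and
duration limits. Ripples: 80–120 Hz, 20 ms windows, k = 2, 25–300 ms,
and ≥ 3 cycles, where cycles = (sign changes of the band-filtered
segment) // 2; the event is timestamped at the maximal *negative*
band-filtered amplitude (config-switchable to the absolute extremum, since
the field uses both conventions). Spindles: 12–15 Hz, 200 ms windows,
k = 1.5, 0.5–3 s. The spindle detector is a documented conventional
stand-in — published spindle duration statistics obtained with other
algorithms are not comparable to its output.

The t statistic in the detectors' companion cluster test (below) and the
detector itself are insensitive to DC offsets and overall gain (threshold
scales with the signal), which the tests assert directly.

## Coupling

Phase is the Hilbert angle of the band-filtered signal: 0 at the filtered
peak, ±π at the trough, so "ripples nest toward the trough" reads as
angles clustering at ±π. MI bins phase into 18 bins of 20°, averages
amplitude per bin, normalizes to a distribution P and reports
KL(P‖U)/log 18 ∈ [0, 1]; empty bins contribute zero mass before
renormalization, an all-zero amplitude returns 0 with a warning, and the
implementation is tested to 1e−12 against a brute-force oracle plus the
analytic endpoints (constant amplitude → 0; single-bin mass → 1; two equal
bins → log 9/log 18). Comodulogram filters use full bandwidths of 0.3 f
(phase, 4–20 Hz) and 0.7 f (amplitude, 20–130 Hz), clamped at 1 Hz.
Surrogates permute the trial assignment of the amplitude segments
(100 repetitions, seeded), per the quoted procedure, rather than
time-shifting. One caveat the synthetic study exposes: when segments are
*ripple-centred* and coupling is strong, the amplitude peak sits at the
segment centre in every trial, so trial shuffling does not fully destroy
phase–amplitude alignment and the surrogate distribution is conservative
there; on continuous (non-event-locked) coupled signals the surrogate
calibration is exact, which is how the acceptance checks test it.

Circular summaries: mean direction and resultant length R from the mean
resultant vector; V test V = n·R·cos(θ̄ − μ), u = V·√(2/n), upper-tail
normal p. Peri-event histograms use 50 ms bins and report events/s per
trial; the count-conservation identity is exact. The ripple-onset ×
spindle-onset histogram assigns each ripple its nearest spindle onset.

## Decoding

The chain is CAR → whole-trial baseline → z-score across trials → PCA
(30 components, fitted on pooled data when train and test must share a
space) → 150 ms smoothing → per-time-point LDA. LDA uses the lsqr solver
with Ledoit-Wolf shrinkage ("auto"; configurable — note that automatic
shrinkage makes the discriminant weakly dependent on trial duplication,
which the tests pin down by fixing the shrinkage where exact invariance is
asserted). AUC is the Mann-Whitney probability with ties counted 0.5,
exactly equal to the concordant-pair count (asserted for up to 100
trials). Cross-validation is stratified five-fold, repeated five times
with seeded fold assignment; temporal generalization trains one
classifier per training time point and applies it to every test time
point with no cross-validation (independent sets). For tractability the
per-time-point classification runs on a 100 Hz time grid (decimation of
the already-smoothed component scores — at a 150 ms smoothing width the
discarded samples are redundant); the grid is a config value.

Ripple-locked classification re-epochs the component-space TMR scores
around qualifying ripple peaks (peak inside 0.7–1.4 s after cue onset and
inside a detected spindle's extent on the reference cortical contact) and
applies the retrieval-trained classifiers. The surrogate draws, per
repetition, as many uniform time points in the qualifying window (≥ 100 ms
from any ripple peak — the exclusion radius is a documented choice, the
source procedure states only that no ripple be present) as there are real
ripples, decodes identically, and averages the AUC maps over repetitions
(default 100; scaled-down repetition counts are used where a check
iterates over many seeds).

## Statistics

The cluster permutation test computes a dependent-samples t per sample
across units (participants, contacts or CV folds, depending on the
analysis), thresholds two-sidedly at α = 0.05, forms contiguous clusters
per sign (4-connectivity in 2-D maps), and compares each cluster's summed
t against the sign-flip permutation distribution of the maximum absolute
cluster mass (1000 randomizations by default), with the (b+1)/(n+1)
Monte Carlo correction. Degenerate cells with zero variance across units
take t = 0 when the mean is also zero and a saturated t = ±100 otherwise:
identical nonzero deviations (e.g. AUC pinned at 1.0 in every fold) are
maximal evidence and must not break a cluster. The implementation is
cross-checked against MNE's cluster test (same threshold and null) for
identical geometry and Monte Carlo-compatible p values, and its
family-wise error on null AR(1) data is verified to sit in [0.025, 0.075].
Rank correlation is Spearman's ρ (the correlation actually reported with
the statistic this pipeline mirrors), with Pearson available directly from
scipy when preferred.

## Pipeline

`run_retrieval_analysis` and `run_tmr_analysis` fix the stage order to the
dependency structure (TFR contrast → cluster mask → median split → ripple
histograms → coupling → decoding); there is no hidden state between
stages, each stochastic stage takes the config seed, and every run returns
a provenance record (SHA-256 of the config, seed, package version).
Scalp-rate inputs (fs < 250 Hz) skip the ripple stages with a logged
warning, mirroring the scalp/iEEG split. Where the TFR contrast yields no
significant cluster (small synthetic studies with few channel-units are
deliberately conservative under sign-flip permutation), a rectangular
fallback mask (12–16 Hz, 0.5–1.5 s) keeps downstream stages defined. The
spatial extent of the per-trial cluster power score averages over the
channels entering the contrast. Ambiguities resolved as package defaults:
z-scoring is applied within each set before pooling retrieval and TMR
data (a flag can switch to pooled z-scoring); the high/low split decoding
reuses the pooled-PCA space rather than refitting per split.

## Known limitations

* The generator's class patterns are stationary boxcar templates; real
  reactivation patterns drift, so decoding performance here is an upper
  bound.
* Trial-shuffled MI surrogates are conservative for strongly coupled
  ripple-centred segments (see above).
* The spindle detector is a stand-in for an unspecified algorithm; only
  its qualitative behaviour (detection, extent) is relied on.
* Fixed-effects statistics over a handful of synthetic channels have
  coarse permutation resolution (2^n sign flips); the pipeline falls back
  to defined masks rather than failing.
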