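# Methods

This note documents the models, estimators, parameter choices, and known
limitations of the analysis chain, and what the synthetic-data generator
does and does not emulate.

## Synthetic sessions

A session is the sum of four independently seeded components (one global
seed fanned out through `numpy.random.SeedSequence` spawning, so each
component is reproducible and statistically independent):

- **Aperiodic background.** White noise is spectrally shaped in the Fourier
  domain so the expected log10 power spectrum is exactly
  `offset − x·log10 f`. Inverse-FFT shaping was chosen over AR fitting
  because the target exponent is exact and the cost is one FFT. Default
  exponent 1.5 — mid-range for pyramidal-layer LFP.
- **Oscillatory bouts.** Per state, bout onsets follow a Poisson process at
  the configured rate (defaults: theta 8 ± 1 Hz at 6/min in rest vs 0.5/min
  in search; beta2 25 ± 3 Hz with the rates reversed — magnitudes chosen to
  reproduce the qualitative state dissociation, since only its direction is
  constrained by the phenomenon being modelled). Durations are lognormal
  (~1 s); each bout is a Hann-tapered cosine whose envelope reaches zero at
  the edges (no spectral splatter at bout boundaries); amplitude is a
  multiple of the background SD. Each bout class keeps one continuous
  global oscillator phase so in-bout LFP phase and spike locking agree
  exactly.
- **SWR complexes.** Each event is a biphasic slow deflection
  (difference-of-Gaussians, width ~80 ms, energy below 10 Hz) plus a ripple
  burst (140 Hz default) with a flat-top Tukey(0.4) taper. Ripple amplitude
  is calibrated in SD units of the 100–250 Hz filtered background — the
  flat-top taper keeps that amplitude sustained through the burst core,
  which is what the stated SD means for a detector thresholding a smoothed
  envelope. Events are placed Poisson per state and resampled on collision.
- **Spikes.** Inhomogeneous Poisson by thinning with rate
  `base · exp(κ cos θ_f(t))/I₀(κ) · g(t)`, where θ_f is the *noiseless*
  oscillator phase (exact ground truth for coherence recovery) and `g` is
  the SWR gain inside ±300 ms windows around ground-truth events. The von
  Mises normalisation keeps the time-averaged rate at `base` when the gain
  is 1. The expected PPC of a κ-locked unit is the analytic
  `(I₁(κ)/I₀(κ))²`, used throughout as the oracle. A unit can restrict its
  locking to SWR windows (`lock_in_swr_only`), the confound case the
  SWR-conditioned analysis exists to expose.

Two auxiliary constructions serve the cross-frequency analyses: correlated
amplitude-modulated carriers (three tones whose *powers* are slow linear
functions of Gaussian modulators; in-sample modulator correlations are
pinned by Gram–Schmidt because slow processes carry few effective degrees
of freedom per session, and the linear power map transfers them exactly,
optionally with band-limited noise sharing the modulators so comodulation
spans bands rather than single bins), and segment-wise coupled triads
(tones at f1, f2, f1+f2 with per-segment random phases, the third phase
either the sum — perfect quadratic coupling — or independent).

What the generator does **not** emulate: spike waveforms and sorting noise,
saccade- or stimulus-evoked transients, non-stationary background
(electrode drift), correlated multi-unit populations, and the laminar
structure of real recordings. Passing tests therefore certify estimator
correctness and calibration on signals with known structure — not
robustness to every pathology of real data.

## Spectral estimation and parametrization

Welch PSDs use 1024-sample Hann windows with 50% overlap; windows are
zero-padded to `fs/0.25` samples so the grid spacing is 0.25 Hz
(zero-padding only interpolates the same estimator). The parametric model
fits log10 power on a 0.5 Hz grid over 1–200 Hz (capped at the available
range): a robust log-log linear background fit that iteratively excludes
points more than 1 SD above the fit (peaks are one-sided outliers), greedy
extraction of Gaussian peaks from the residual (tallest first, ties toward
lower frequency) until the residual maximum falls below 2.0 residual SDs,
a joint bounded least-squares refit of all peaks (width limits 0.5–12 Hz),
and a final background refit on the peak-subtracted spectrum. "Unlimited"
peaks are capped at 20 with a warning to guarantee termination; on noisy
estimator output small residual wiggles routinely reach that cap, which is
harmless for the background parameters.

One systematic property worth knowing: a spectral peak present in only one
condition slightly biases that condition's background fit, so flattened
power *away* from the peak is consistently a little lower. With enough
paired sessions a signed-rank test can flag this small but systematic
difference; interpret narrow-band contrasts at the oscillation bands, not
broadband residual offsets.

The sorted spectral-density map median-normalises each per-window PSD,
sorts by mean 20–30 Hz power, and averages into 50 equal-count (±1)
quantile bins. State contrasts are per-frequency paired Wilcoxon
signed-rank tests with Benjamini–Hochberg FDR at 0.05.

## Bout detection

Morlet wavelets with 6-cycle width, L2-normalised, on a log-spaced
29-point grid (2–128 Hz default); samples within one wavelet support of
the edges are never hits. The background is a log-log linear regression of
mean power on frequency (configured oscillation bands excluded from the
regression to avoid threshold inflation); the amplitude threshold is the
95th percentile of a chi-square distribution with 2 degrees of freedom —
the distribution of wavelet power for Gaussian noise — scaled so its mean
equals the fitted background. A hit requires suprathreshold power
sustained for 3 cycles. Occupancy is the percentage of samples that are
hits.

Calibration on pure 1/f background: per-frequency exceedance of the
amplitude threshold is 5% ± 1% and occupancy after the duration rule stays
below 1% — both judged on a 10-realization ensemble (3000 s), since single
300 s realizations fluctuate to ~2% at the lowest frequencies where
3 cycles span 1.5 s. A caveat intrinsic to 6-cycle wavelets: temporal
smearing means a very strong 2-cycle transient can exceed threshold for
more than 3 cycles and be detected; the duration rule discriminates
marginal transients, not arbitrarily strong ones.

## Cross-frequency coupling

The comodulogram is the Pearson correlation of per-window Welch power
across all frequency pairs. Its surrogate null shuffles the window order
independently per frequency row (destroying cross-frequency alignment,
preserving marginals), 5000 permutations by default. Cells whose
two-sided p < 0.05 are clustered by 4-connectivity, positive and negative
cells separately; a cluster is significant when its size exceeds the null
of per-permutation maximum cluster sizes at the 5% level (permutation
p-value with the `(1+k)/(n+1)` convention). Cluster *size* is
integer-valued, so on small grids the achievable α is quantised and the
test errs conservative; calibration (family-wise error 0.03–0.05 at the
nominal 0.05) holds on grids of ~80 frequencies and up. For the
permutation machinery the 0.25 Hz grid is decimated to 2 Hz, bounding the
null stack's memory at a few MB.

Bicoherence uses Hann-tapered 50%-overlapping 1024-sample segments;
requested 1 Hz grids map to the nearest FFT bins, and cells with
f1 + f2 above Nyquist are flagged invalid. The red-noise null is an AR(1)
process matched to the signal's lag-1 autocorrelation and variance, run
through the identical estimator, with the same cluster correction
(high tail only). Note that for *any* signal with independent segment
phases the bicoherence bias is ~1/√n_segments — the same magnitude as the
AR(1) null — so per-cell thresholds sit exactly at the control's
distribution; only the cluster-corrected decision is a meaningful
negative control.

Envelope correlation bandpasses each frequency ±1 Hz with a zero-phase
3rd-order Butterworth filter and correlates the Hilbert amplitude
envelopes; on long stationary signals it agrees with the comodulogram
entry within ~0.15.

## SWR detection

Bandpass (ripple 100–250 Hz; high gamma 80–120; HFO 110–160, zero-phase
4th-order Butterworth) → z-score → rectify → secondary 1–20 Hz bandpass
(the envelope). Candidates must exceed mean + 3 SD of the envelope (1 SD
for the secondary bands), extend to the 1 SD crossings, last ≥ 50 ms, and
events closer than 125 ms merge. Candidates that overlap any candidate on
the distant noise channel are discarded; overlapping events across bands
consolidate with the SWR label dominating. Peak time is the envelope
argmax; amplitude is reported in envelope SD units. Envelope statistics
are computed over the whole recording: in recordings that contain events,
the events themselves widen the SD and thereby raise the absolute
threshold — on event-free Gaussian background the 3 SD + 50 ms rule fires
at ~2/min (the intrinsic upcrossing rate of a 1–20 Hz envelope), so
false-positive rates should be assessed against the non-event stretches
of realistic, event-containing recordings, where they fall well below
0.5/min.

## Spike-field coherence

Spike phases come from Hann-tapered complex dot products with 5 cycles
per frequency on a 1 Hz grid (2–200 Hz); a spike at a cosine peak maps to
phase 0. Spikes whose window would overrun the recording are excluded at
that frequency; analyses that compare spike subsets restrict to spikes
valid at every frequency (the window at the lowest frequency). PPC uses
the closed form ((Σcos)² + (Σsin)² − N)/(N(N−1)), the unbiased mean over
all unordered pairs of cos(θ_j − θ_k). Significance requires all three of:
PPC above the 95th percentile of 1000 uniform spike-time redraws (the
stronger null compared with local jitter), Rayleigh p < 0.05 (z = NR²,
with the standard small-sample series correction), and membership in the
suprathreshold region around a spectrum peak of height and prominence
≥ 0.005. Preferred-frequency distributions use Gaussian KDEs with a 4 Hz
absolute bandwidth.

The SWR-conditioned decomposition partitions spikes by merged 600 ms
windows centred on SWR events (units with < 20 window spikes, or without
≥ 2 residual spikes, are excluded with an explicit reason). Within each of
six bands (2–3, 4–10, 11–20, 21–40, 41–100, 101–200 Hz) only the frequency
with the largest |ΔPPC| is tested, two-tailed, against 1000 count-matched
random reassignments, FDR-corrected across bands. Because the tested value
is a maximum over the band, the null is the same selection statistic — the
per-reassignment band maximum of |ΔPPC|; comparing the selected peak to a
single-frequency null inflates false positives several-fold. Two further
calibration facts, both consequences of windowed phase estimation rather
than implementation choices: (i) spikes close in time share LFP segments,
so their phase estimates are correlated and PPC over temporally clumped
spikes is noisier than over scattered ones; (ii) windows centred on real
LFP events are *not* a null even for a uniformly locked unit, because the
stereotyped sharp-wave deflection gives in-window spikes genuinely
different measured phases — which is precisely the spurious-coupling
phenomenon this analysis quantifies. Null calibration therefore uses
pseudo-event windows at random times.

## Theta modulation index

Autocorrelograms use 10 ms bins over ±500 ms, self-pairs excluded,
normalised to the maximum count at lags 100–150 ms and clipped at 1;
units with fewer than 100 total counts are excluded. The model

    y(t) = [a(cos(2πωt) + 1) + b] e^(−|t|/τ₁) + c e^(−t²/τ₂²)

is fitted by Nelder–Mead simplex with constraints enforced by smooth
reparameterisation (a, b ≥ 0; ω ∈ (4, 10) Hz; c ∈ (0, 0.2);
τ₂ ∈ (0, 0.05) s; τ₁ ∈ (0.01, 5) s for numerical stability), multi-started
over ω ∈ {4.5, 6, 7.5, 9} Hz with ties broken toward lower ω; the zero-lag
bin is excluded and the model is clipped at 1 inside the objective,
matching the clipping of the data curve. The oscillation uses cosine
phase: the ACG of a rhythmically modulated train peaks at lags 0, 1/ω,
2/ω, and a quarter-period-shifted sine cannot track it. The index is
a/max(b, 10⁻³); fits that hit the b floor are flagged. Two quantitative
facts shape interpretation: sinusoidal rate modulation of depth d yields
ACG modulation d²/2, capping the index at 1 — indices well above 1
(rat-like theta cells) require sharper-than-sinusoidal modulation, e.g.
von Mises exp(κ cos) firing profiles; and a flat ACG drives a → 0 with
index ≈ 0, the non-modulated (primate-like) case.

## Orchestration and problem sizes

The pipeline runs stages in dependency order, draws every stage's
randomness from fixed substreams of one global seed, and records
parameters, outputs, input digests, and timing in a JSON manifest; re-runs
under the same seed are byte-identical, and any stage can be re-run in
isolation from the session on disk. Surrogate counts are configurable per
run; the packaged demo uses 300 permutations / 100 bicoherence surrogates
/ 200 spike shuffles (logged when below the 5000/1000 defaults), sized for
an interactive desk run. The test suite and the acceptance script use
sessions of 240–1260 s at 1 kHz with 500-surrogate statistics — sizes at
which every calibration quantity reported here is stable across seeds.
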