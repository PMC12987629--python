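# Methods

This note documents the models behind each analysis stage, the synthetic
generators used to validate them, the numerical choices that were genuinely
open, and what passing tests do and do not establish about real recordings.

## Photometry preprocessing

Motion and bleaching artifacts are removed by fitted-control subtraction: an
affine least-squares fit f(F₄₁₅) = a·F₄₁₅ + b of the isosbestic channel onto
the signal channel, with ΔF/F = (F₄₇₀ − f)/f. This is the most common
published correction; it is invariant to affine transforms of the control
channel, and a constant control falls back to intercept-only fitting (with a
warning) rather than failing. Interleaved channels are aligned by linear
interpolation of the 470 nm samples onto the 415 nm timestamps — the control
channel is the reference so that no extrapolation occurs at record edges.

Band-pass filtering uses a 2nd-order Butterworth run forward–backward
(zero phase), so time-to-peak and lag estimates downstream are unbiased;
the squared magnitude response of the low order keeps the passband within
±5% over the 0.01–10 Hz fast band at the rates used here. Reflect padding
spans up to three time constants of the low edge, capped at the record
length, and the first/last ~5 s should be treated as edge-contaminated.
Whether published analyses z-score ΔF/F or raw fluorescence before spectral
analysis is not always stated; this package z-scores ΔF/F and records the
choice in each trace's provenance list.

## Spectral energy density

A Welch averaged periodogram (Hann window, default 20 s windows with 50%
overlap) reported on a fixed 36-bin log-spaced grid. Two normalization
choices matter:

- Segments are *not* individually detrended; the global mean is removed
  instead, and the DC point's energy is folded into the lowest reporting
  bin. Per-segment detrending silently discards all power slower than one
  window — for the mutant's slow-wave-dominated signals that is most of the
  variance — and would break the invariant that ∑ e·Δf equals the signal
  variance (held to within 5%, Parseval check).
- Log bins are filled by energy-preserving aggregation (each Welch frequency
  contributes its exact energy to the bin containing it), and 36 bins are
  few enough that a Hann main lobe (three Welch points) fits inside one bin
  over the fast band, so a pure tone reports ≥90% of its energy in a single
  bin.

Group comparison is a per-bin two-sample t test with Holm–Šídák correction
at α = 0.05.

## Decile-variance heterogeneity statistic

The premise: for a homogeneous filtered point process (kernel transients at
a constant Poisson rate, plus white measurement noise), the variability of
the one-sample first difference d(i) = x(i+1) − x(i) given the current level
x(i) is constant — jumps arrive independently of state. Structured,
state-dependent release makes increment variability grow with the level.

The statistic bins interior samples by empirical deciles of x(i) (stable
ranks; tied values share the lower bin) and computes, per bin, the variance
of d about the within-bin least-squares line of d on x. The regression step
is deliberate: an exponential-kernel shot-noise process mean-reverts, with
E[d | x] = (ρ − 1)·x exactly (ρ = e^(−Δt/τ)), so the *plain* within-bin
variance is inflated by (1 − ρ)²·Var(x | bin) — negligible in narrow
interior deciles but a several-percent artifact in the wide tail deciles,
which is where the test looks. Removing the within-bin linear trend removes
this term exactly under the null while leaving genuine conditional-variance
heterogeneity untouched; simulation (500 null groups of 9 sessions) confirms
family type-I error at or below the nominal α, where the undetrended version
is anticonservative. Profiles are normalized to the lowest decile
(v_norm[0] ≡ 1).

The group test is a one-sample t on log v_norm[k] across sessions for each
decile k ≥ 2, Benjamini–Hochberg corrected across the nine comparisons. This
is a simplification of a repeated-measures ANOVA followed by simple-effect
comparisons: decisions come from the per-decile simple effects, which is
what the corresponding figures annotate. The first derivative is a
one-sample forward difference at the analysis rate (default 20 Hz); the
differencing interval scales v but cancels in v_norm under the flat null.

## Cross-correlation

r(τ) is the Pearson correlation of the z-scored DS signal with the VS signal
shifted by τ, computed over the overlapping samples for each lag on a
±max_lag grid, with three-point parabolic refinement of the peak. Positive
peak lag means DS leads. Session curves are averaged on the common lag grid
before peak extraction (matching group-level presentation); per-session
peaks remain available.

## FSCV kinetics

Traces are assumed pre-calibrated to μM (electrode chemistry is out of
scope). Peak [DA]₀ is the maximum over a 5 s post-stimulus window minus the
baseline mean; TTP is the argmax time; t½ is the first crossing of
baseline + peak/2 after the peak, linearly interpolated between samples and
therefore offset-invariant. Two smoothing scales condition the searches: a
30 ms moving average for the peak/TTP (the evoked peak is sharp — heavier
smoothing clips it) and a 110 ms moving average for the half-decay crossing
(the slope there is shallow, so unsmoothed sample noise dominates the
crossing-time jitter). Both are skipped for noise-free traces, so noiseless
synthetic traces are recovered to machine precision. With noise at 5% of the
WT peak, the median absolute relative error of each kinetic measure stays
below 5% over 100 seeded traces. Sites whose post-stimulus signal never
exceeds baseline + 4 SD are excluded with a logged reason rather than
imputed; traces that never reach half-peak within the record return a
censoring flag. Site values are averaged within slice before genotype
statistics.

## Michaelis–Menten uptake fitting

Nonlinear least squares of v = Vmax·C/(Km + C) over the six-point two-fold
dilution row (1–0.031 μM), multistarted from the Lineweaver–Burk
linearization plus three deterministic perturbations; the best residual sum
of squares wins. Standard errors are asymptotic (Jacobian at the optimum);
bootstrap errors were considered and omitted for speed. Negative rates are
flagged but kept (no outlier screen by default); a fitted Km outside the
concentration range ×10 triggers an extrapolation warning. Mutant capacity
is summarized as the paired Vmax fraction against the WT fit from the same
experimental pair, normalizing before group aggregation.

## Microdialysis

The baseline is the mean dialysate dopamine over the 40 minutes preceding
the drug; the response is the post-drug maximum as a fold of that baseline,
which makes it invariant to multiplicative recalibration. Concentration
units are presentation-dependent across studies, so summaries are reported
both raw and as percent of the WT group mean.

## Line-grid fiber density

Scan lines are laid every 25 μm (both orientations by default); along each
line, intensity peaks above mean + 1·SD separated by ≥ 1 μm count as fiber
crossings, reported per 100 μm of line. Peak counting was chosen over
threshold-run counting because two touching fibers crossed obliquely still
produce two maxima; the threshold's mean + k·SD form makes counts invariant
to intensity rescaling. Grid spacing, threshold multiplier and minimum
separation are all config-exposed, since published grid geometries vary.
Both image-level values and per-mouse means are reported.

## Synthetic generators

The generators' defaults *are* the validation conditions; genotype contrasts
are direct parameters so that each analysis stage can be scored against
ground truth.

- **Uptake**: v(C) on the dilution row with multiplicative Gaussian noise
  (CV 5% default). WT Vmax ≡ 1, Km 0.16 μM; mutant Vmax 0.25, Km 0.25 μM.
- **FSCV**: phenomenological trace — zero baseline, linear rise to the peak
  at TTP, monoexponential decay with half-time t½, additive Gaussian noise —
  rather than a mechanistic release–clearance model, so the fold-changes are
  exact generator parameters and recovery is well-posed. WT absolute values
  (peak 1.0/0.6 μM DS/VS, TTP 0.3 s, t½ 0.2 s) are plausible defaults;
  mutant folds are 6%/22% of WT peak (DS/VS), 2.5×/5× TTP and t½ in DS, and
  1.8×/3× in VS (the ventral deficit is smaller; the VS kinetic folds are
  design defaults, not measured values).
- **Photometry** (20 Hz default, ≥60 s): WT DS dopamine is shot noise — a
  log-Gaussian doubly stochastic rate (mean 4 Hz, log-SD 0.6, 3 s
  correlation time) driving unit-amplitude kernels (0.05 s rise, 0.4 s
  decay). WT VS is 0.5× a smoothed copy of DS delayed by 0.35 s plus an
  independent slower shot-noise component (1 s decay). The mutant keeps 10%
  of the event amplitude and adds a dominant Ornstein–Uhlenbeck slow wave
  (45 s correlation time, the simplest stationary process with one timescale
  knob) shared between regions. White sensor noise (SD 0.05) is added, and
  the dopamine signal is embedded into 470/415 channels around baselines of
  100/50 counts with a shared OU artifact (20 s timescale) and channel
  noise; the 415 channel is uncorrelated with the dopamine truth.
  ``mode="homogeneous"`` switches to a constant event rate and a pure
  exponential kernel — the null for heterogeneity-test calibration. An
  optional amphetamine event adds a slow saturating response (180 s rise)
  scaled per region in realized baseline-SD units (WT 10×/35× DS/VS; mutant
  8×/3×, design defaults reflecting a preserved dorsal and blunted ventral
  response).
- **Microdialysis** (10-minute fractions, 12 fractions): flat baseline (WT
  1.0, mutant 2.8×), drug at the end of the 40-minute baseline window, then
  a gamma-shaped response (shape 2) peaking exactly 2.5 fraction intervals
  later so a fraction midpoint lands on the peak and a noiseless series
  reproduces the programmed fold (17× WT, 1.6× mutant) exactly. Fraction
  noise is multiplicative (CV 10% default).
- **Fiber images** (768 px at 0.2 μm/px): fibers are smooth random paths
  (2 px steps, heading SD 0.03/step) of fixed intensity entering from a
  random edge, blurred by a Gaussian PSF (σ 1.5 px) and degraded by
  Poisson-like photon noise over a constant background. Ground truth stores
  every polyline, so grid crossings are computed exactly by segment–line
  intersection. Defaults were chosen so that single fibers are clearly
  resolvable (peak ≈ 10× background); at 80 fibers the method's merging
  limit becomes visible, which is intentional.

What these generators do *not* emulate: hemodynamic or pH artifacts and
sensor kinetics in photometry; bleed-through between fibers; amphetamine
pharmacokinetics; D2-autoreceptor feedback on release; probe recovery in
microdialysis; anisotropic PSFs or staining gradients in imaging. Passing
recovery tests therefore demonstrates estimator correctness under the stated
noise models, not robustness to every artifact of real recordings.

## Random streams and reproducibility

All stochastic stages draw from labelled streams: (seed, label) is hashed
(SHA-256, platform-independent) into a seed sequence, so identical labels
reproduce identical draws, different labels are independent, and a full
pipeline run at a fixed seed is bit-reproducible.

## Simulated problem sizes

The validation suite and the recovery script use: 4 WT:mutant uptake pairs
(6 concentrations × 3 replicates, CV 5%); 8 FSCV traces per genotype and
region with noise at 2% of the trace's evoked peak; 7 WT and 6 mutant
microdialysis series (CV 10%); 8 paired 30-minute WT photometry sessions at
20 Hz for the coupling lag; and 500 groups of 9 ten-minute homogeneous-mode
sessions (rate 2 Hz, kernel decay 0.3 s, noise SD 0.05) for the type-I
calibration of the heterogeneity test. The in-suite calibration check runs
150 groups; its acceptance bound (α + 2 Monte Carlo SEs) widens accordingly.

## Known limitations

- The peak-based estimators (FSCV peak, microdialysis peak fold) are
  max-statistics and carry a small upward noise bias (~0.5–1 noise SD); at
  the noise levels above this stays within a few percent, but it grows for
  signals near the detection floor.
- The heterogeneity test assumes an (approximately) linear conditional mean
  of the increment in the level; strongly nonlinear mean dynamics within a
  decile would leak into the variance profile.
- Cross-correlation lags are only meaningful to about half a sample
  (±25 ms at 20 Hz); the parabolic refinement assumes a locally smooth peak.
- The band-pass upper edge is capped at 0.45·fs when the configured band
  reaches the Nyquist frequency (as 0.01–10 Hz does at 20 Hz sampling), so
  "fast-component" amplitudes at low sampling rates cover only the
  resolvable part of the band.
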