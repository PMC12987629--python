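# datdyn

Quantitative analysis of striatal dopamine physiology in dopamine-transporter
(DAT) deficient mouse models.

Genetic loss of DAT function — as in atypical dopamine transporter deficiency
syndrome, modeled by compound-heterozygous DAT loss-of-function mice —
reshapes dopamine signaling at every scale: synaptosomal reuptake capacity,
electrically evoked release and clearance in striatal slices, tonic
extracellular dopamine and its amphetamine response, the fast temporal
structure of dopamine fluctuations recorded by fiber photometry, and the
density of dopaminergic axon terminals. `datdyn` implements the measurement
pipeline for each of these readouts, plus seeded synthetic-data generators
that carry exact ground truth, so every estimator in the package can be
validated end to end without any recorded data.

## What it computes

**Photometry preprocessing** (`photometry_pre`). Two-channel recordings
(470 nm dopamine-sensitive, 415 nm isosbestic control) are motion-corrected
by an affine least-squares fit of the control onto the signal channel,
expressed as ΔF/F = (F₄₇₀ − f(F₄₁₅)) / f(F₄₁₅), and z-scored to a baseline
window. Filtering is zero-phase so that timing measures are not phase
shifted.

**Dopamine dynamics** (`da_dynamics`).

- *Spectral energy density*: Welch averaged periodogram (Hann window) on a
  log-spaced frequency grid, normalized so that ∑ e·Δf equals the signal
  variance; groups are compared per frequency bin by t tests with Holm–Šídák
  correction.
- *Decile-variance heterogeneity*: the variance of the one-sample first
  difference d(i) = x(i+1) − x(i), conditioned on deciles of the signal
  level x(i) and normalized to the lowest decile. For a homogeneous
  shot-noise process — kernel-shaped transients arriving at a constant
  Poisson rate — the profile is flat; state-dependent release makes it rise
  with intensity. A one-sample t test on log v_norm per decile across
  sessions, Benjamini–Hochberg corrected, flags deciles whose increment
  variability differs from the bottom decile.
- *Regional coupling*: normalized cross-correlation r(τ) between dorsal (DS)
  and ventral (VS) striatal signals with three-point parabolic refinement of
  the peak lag (positive lag = DS leads).
- *Drug response*: AUC and peak in baseline-SD units after an injection, and
  the mean rectified amplitude of the fast (0.01–10 Hz) component before
  versus after.

**FSCV kinetics** (`fscv`). Evoked dopamine traces are summarized by peak
concentration [DA]₀, time to peak (TTP), and clearance half-time t½ (first
half-peak crossing after the peak, baseline-referenced and interpolated
between samples). Derived measures: D2-antagonist disinhibition (% of paired
baseline peak) and regional penetrance (mutant peaks as % of the WT mean).

**Neurochemistry** (`neurochem`). Saturation uptake v(C) = Vmax·C/(Km + C)
fitted by multistart nonlinear least squares (started from the
Lineweaver–Burk linearization), with paired mutant/WT Vmax fractions; and
microdialysis fraction series summarized by the 40-minute pre-drug baseline
mean and the post-drug peak as a fold of baseline.

**Fiber imaging** (`fiber_imaging`). Line-grid intercept quantification:
intensity peaks above mean + k·SD along evenly spaced scan lines, separated
by a minimum distance, counted per 100 μm of scanned line as a proxy for
axonal area density.

**Synthetic data** (`synthgen`). Generators for every input class,
parameterized by genotype effect sizes (WT vs mutant): uptake Vmax/Km,
regional FSCV kinetics, shot-noise photometry with a doubly stochastic event
rate and a DS→VS coupling delay, microdialysis baselines and amphetamine
responses, and fiber images with known polylines. A homogeneous-Poisson mode
provides the exact null for calibrating the heterogeneity test.

## Worked example

```bash
$ datdyn report --seed 1 --out-dir out/
               measure     value
    vmax_reduction_pct 75.098253
              wt_km_uM  0.164960
fscv_penetrance_DS_pct  6.187872
fscv_penetrance_VS_pct 22.283328
      ds_vs_peak_lag_s  0.354320
```

This simulates paired WT/mutant uptake experiments, evoked FSCV traces and
paired DS/VS photometry sessions, then runs the corresponding analyses: the
mutant's fitted uptake capacity is reduced by ~75% at a WT Michaelis constant
of ~0.16 μM; evoked release in the mutant is ~6% of WT in dorsal striatum
versus ~22% in ventral striatum (a strongly region-dependent deficit); and
the dorsal signal leads the ventral one by ~0.35 s in the session-averaged
cross-correlation. Each number is an estimate recovered from noisy synthetic
data whose true effect sizes are the generator parameters.

The same stages are available individually, e.g.

```bash
datdyn simulate --what photometry --genotype MUT --seed 7 --out-dir sim/
datdyn photometry --in sim/photometry_MUT_DS.csv --out-dir sim/
datdyn dynamics --in sim/photometry_MUT_DS.csv --out-dir sim/dyn/
```

or from Python:

```python
import datdyn as dd

rng = dd.make_rng(1, "demo")
ds, vs = dd.gen_photometry_session("WT", duration_s=1800, rng=rng)
z_ds, z_vs = dd.preprocess_session(ds), dd.preprocess_session(vs)
xc = dd.cross_correlate(z_ds, z_vs, max_lag_s=5.0)
print(xc.peak_lag)   # ~0.35 s
```

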