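"""Seeded generators for every input class, with exact ground truth.

The generators emulate the two genotypes studied throughout the package: WT
(normal dopamine transporter function) and MUT (a compound-heterozygous DAT
loss-of-function genotype with ~25% residual uptake). Genotype contrasts that
the analysis stages are expected to recover — the Vmax reduction, Km values,
evoked-release penetrance and kinetic slowing, dorsal-to-ventral signal lag,
microdialysis baseline elevation and blunted amphetamine response — are direct
generator parameters, so every estimator can be tested against a known truth.

Absolute WT scales (peak 1.0 uM, TTP 0.3 s, t1/2 0.2 s, photometry rates and
kernels) are plausible defaults, not measured values; only the mutant/WT folds
and the regional lag are anchored to reported effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.ndimage
import scipy.signal
import skimage.draw

from .core_io import PhotometrySession, RngStream, TimeSeries
from .errors import ResolutionError, ValidationError
from .fiber_imaging import FiberImage
from .fscv import FscvKinetics, FscvTrace
from .neurochem import MicrodialysisSeries, UptakeDataset

# ---------------------------------------------------------------------------
# Genotype parameter sets
# ---------------------------------------------------------------------------


@dataclass
class UptakeParams:
    vmax: float  # normalized uptake capacity (WT = 1)
    km_uM: float


@dataclass
class FscvParams:
    peak_uM: dict  # by region
    ttp_s: dict
    thalf_s: dict


@dataclass
class PhotometryParams:
    event_rate_hz: float = 4.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.4
    event_amp: float = 1.0
    vs_event_rate_hz: float = 1.0
    vs_kernel_decay_s: float = 1.0
    vs_coupling_gain: float = 0.5
    vs_smooth_s: float = 0.1
    ds_vs_delay_s: float = 0.35
    rate_log_sd: float = 0.6  # doubly-stochastic log-rate modulation depth
    rate_timescale_s: float = 3.0
    slow_wave_timescale_s: float = 45.0
    slow_wave_sd: float = 1.0
    mut_event_amp_factor: float = 0.1
    noise_sd: float = 0.05
    artifact_sd: float = 1.0  # shared motion/bleaching artifact, raw counts
    channel_noise_sd: float = 0.05  # per-channel acquisition noise, raw counts
    amph_sd_units: dict = field(default_factory=dict)  # response peak in baseline-SD units
    amph_rise_s: float = 180.0


@dataclass
class DialysisParams:
    baseline: float
    amph_peak_fold: float


@dataclass
class GenotypeParams:
    genotype: str
    uptake: UptakeParams
    fscv: FscvParams
    photometry: PhotometryParams
    dialysis: DialysisParams


_WT_FSCV = FscvParams(
    peak_uM={"DS": 1.0, "VS": 0.6},
    ttp_s={"DS": 0.3, "VS": 0.3},
    thalf_s={"DS": 0.2, "VS": 0.2},
)

# mutant folds relative to WT; DS folds are reported effect sizes, VS kinetic
# folds are design defaults (regional deficit smaller in VS than DS)
_MUT_PEAK_FRACTION = {"DS": 0.06, "VS": 0.22}
_MUT_TTP_FOLD = {"DS": 2.5, "VS": 1.8}
_MUT_THALF_FOLD = {"DS": 5.0, "VS": 3.0}


def genotype_params(genotype: str) -> GenotypeParams:
    """Parameter set for 'WT' or 'MUT' with reported effect sizes baked in."""
    if genotype == "WT":
        return GenotypeParams(
            genotype="WT",
            uptake=UptakeParams(vmax=1.0, km_uM=0.16),
            fscv=_WT_FSCV,
            photometry=PhotometryParams(amph_sd_units={"DS": 10.0, "VS": 35.0}),
            dialysis=DialysisParams(baseline=1.0, amph_peak_fold=17.0),
        )
    if genotype == "MUT":
        fscv = FscvParams(
            peak_uM={r: _WT_FSCV.peak_uM[r] * _MUT_PEAK_FRACTION[r] for r in ("DS", "VS")},
            ttp_s={r: _WT_FSCV.ttp_s[r] * _MUT_TTP_FOLD[r] for r in ("DS", "VS")},
            thalf_s={r: _WT_FSCV.thalf_s[r] * _MUT_THALF_FOLD[r] for r in ("DS", "VS")},
        )
        return GenotypeParams(
            genotype="MUT",
            uptake=UptakeParams(vmax=0.25, km_uM=0.25),
            fscv=fscv,
            # DS amphetamine photometry response largely preserved, VS blunted
            photometry=PhotometryParams(amph_sd_units={"DS": 8.0, "VS": 3.0}),
            dialysis=DialysisParams(baseline=2.8, amph_peak_fold=1.6),
        )
    raise ValidationError("genotype must be 'WT' or 'MUT'")


def fscv_kinetics(genotype: str, region: str, params: Optional[GenotypeParams] = None) -> FscvKinetics:
    """True (generator) single-pulse kinetics for a genotype/region."""
    p = params or genotype_params(genotype)
    return FscvKinetics(
        peak_uM=p.fscv.peak_uM[region],
        ttp_s=p.fscv.ttp_s[region],
        thalf_s=p.fscv.thalf_s[region],
    )


# ---------------------------------------------------------------------------
# Saturation uptake
# ---------------------------------------------------------------------------

#: six-point 2-fold dilution row, uM
UPTAKE_CONCENTRATIONS = np.array([1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125])


def gen_uptake_dataset(
    params: GenotypeParams,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    rng: Optional[RngStream] = None,
    pair_id: str = "",
) -> UptakeDataset:
    """Replicate uptake rates v(C) = Vmax*C/(Km+C) with multiplicative noise."""
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if noise_cv > 0 and rng is None:
        raise ValidationError("rng required when noise_cv > 0")
    u = params.uptake
    conc = np.tile(UPTAKE_CONCENTRATIONS, n_replicates)
    rep = np.repeat(np.arange(n_replicates), UPTAKE_CONCENTRATIONS.size)
    v = u.vmax * conc / (u.km_uM + conc)
    if noise_cv > 0:
        v = v * (1.0 + noise_cv * rng.generator.standard_normal(v.size))
    return UptakeDataset(
        conc_uM=conc,
        rate=v,
        replicate=rep,
        pair_id=pair_id,
        genotype=params.genotype,
        truth={"vmax": u.vmax, "km_uM": u.km_uM, "noise_cv": noise_cv},
    )


# ---------------------------------------------------------------------------
# FSCV traces
# ---------------------------------------------------------------------------


def gen_fscv_trace(
    kin: FscvKinetics,
    noise_sd: float = 0.0,
    rng: Optional[RngStream] = None,
    fs: float = 100.0,
    duration_s: float = 8.0,
    t_stim: float = 2.0,
    region: str = "DS",
    genotype: str = "WT",
    **labels,
) -> FscvTrace:
    """Phenomenological evoked trace: linear rise, exponential clearance.

    Zero before the stimulus, linear rise to ``kin.peak_uM`` at
    ``t_stim + kin.ttp_s``, then monoexponential decay with half-time
    ``kin.thalf_s``; additive Gaussian noise of SD ``noise_sd`` (uM).
    """
    if fs < 100:
        raise ValidationError("FSCV generator requires fs >= 100 Hz")
    if kin.ttp_s <= 2 / fs or kin.thalf_s <= 2 / fs:
        raise ResolutionError("TTP and t1/2 must exceed two sample intervals")
    if noise_sd > 0 and rng is None:
        raise ValidationError("rng required when noise_sd > 0")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    rise = (t > t_stim) & (t <= t_stim + kin.ttp_s)
    x[rise] = kin.peak_uM * (t[rise] - t_stim) / kin.ttp_s
    fall = t > t_stim + kin.ttp_s
    x[fall] = kin.peak_uM * 0.5 ** ((t[fall] - t_stim - kin.ttp_s) / kin.thalf_s)
    if noise_sd > 0:
        x = x + noise_sd * rng.generator.standard_normal(n)
    return FscvTrace(
        ts=TimeSeries(x=x, fs=fs, unit="uM"),
        t_stim=t_stim,
        region=region,
        genotype=genotype,
        truth={"peak_uM": kin.peak_uM, "ttp_s": kin.ttp_s, "thalf_s": kin.thalf_s, "noise_sd": noise_sd},
        **labels,
    )


# ---------------------------------------------------------------------------
# Photometry sessions
# ---------------------------------------------------------------------------


def _ou(n: int, dt: float, tau: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact discretization)."""
    rho = np.exp(-dt / tau)
    innov = sd * np.sqrt(1 - rho**2) * rng.standard_normal(n)
    innov[0] = sd * rng.standard_normal()
    return scipy.signal.lfilter([1.0], [1.0, -rho], innov)


def _kernel(fs: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak transient kernel: exponential decay with optional rise."""
    t = np.arange(int(round(6 * decay_s * fs)) + 1) / fs
    if rise_s > 0:
        k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    else:
        k = np.exp(-t / decay_s)
    return k / np.max(k)


def _shot_noise(
    n: int,
    fs: float,
    rate_hz: float,
    kernel: np.ndarray,
    amp: float,
    rng: np.random.Generator,
    homogeneous: bool,
    rate_log_sd: float,
    rate_timescale_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filtered point process; returns (signal, event counts, rate path)."""
    if homogeneous:
        rate = np.full(n, rate_hz)
    else:
        g = _ou(n, 1 / fs, rate_timescale_s, rate_log_sd, rng)
        rate = rate_hz * np.exp(g - 0.5 * rate_log_sd**2)
    counts = rng.poisson(rate / fs)
    signal = scipy.signal.fftconvolve(counts.astype(float), kernel)[:n] * amp
    return signal, counts, rate


def _delay(x: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return x.copy()
    out = np.empty_like(x)
    out[:k] = x[0]
    out[k:] = x[:-k]
    return out


def gen_photometry_session(
    genotype: str,
    duration_s: float = 600.0,
    fs: float = 20.0,
    rng: Optional[RngStream] = None,
    mode: str = "exploratory",
    event_rate_hz: Optional[float] = None,
    kernel_rise_s: Optional[float] = None,
    kernel_decay_s: Optional[float] = None,
    noise_sd: Optional[float] = None,
    ds_vs_delay_s: Optional[float] = None,
    artifact_sd: Optional[float] = None,
    channel_noise_sd: Optional[float] = None,
    amph_time_s: Optional[float] = None,
    params: Optional[GenotypeParams] = None,
) -> tuple[PhotometrySession, PhotometrySession]:
    """Paired dorsal/ventral two-channel sessions with full ground truth.

    WT dorsal dopamine is a shot-noise process driven by a log-Gaussian
    doubly-stochastic event rate (transient kernel: 0.05 s rise, 0.4 s decay);
    the ventral signal couples to a smoothed, delayed copy of it (delay
    ``ds_vs_delay_s``) plus an independent slower shot-noise component. The
    mutant keeps 10% of the event amplitude and adds a dominant
    Ornstein-Uhlenbeck slow wave (45 s correlation time) in both regions.
    ``mode="homogeneous"`` uses a constant event rate (no rise by default),
    the null process for heterogeneity-test calibration.

    The isosbestic 415 channel carries a shared low-frequency artifact plus
    independent noise and is uncorrelated with the dopamine truth. When
    ``amph_time_s`` is set, a slow saturating response is added, scaled per
    region in units of the realized pre-injection baseline SD.
    """
    if rng is None:
        raise ValidationError("rng is required")
    if fs < 20:
        raise ValidationError("photometry generator requires fs >= 20 Hz")
    if duration_s < 60:
        raise ValidationError("photometry generator requires duration >= 60 s")
    if mode not in ("exploratory", "homogeneous"):
        raise ValidationError("mode must be 'exploratory' or 'homogeneous'")
    p = (params or genotype_params(genotype)).photometry
    if event_rate_hz is not None:
        p = replace(p, event_rate_hz=event_rate_hz)
    if kernel_rise_s is not None:
        p = replace(p, kernel_rise_s=kernel_rise_s)
    if kernel_decay_s is not None:
        p = replace(p, kernel_decay_s=kernel_decay_s)
    if noise_sd is not None:
        p = replace(p, noise_sd=noise_sd)
    if ds_vs_delay_s is not None:
        p = replace(p, ds_vs_delay_s=ds_vs_delay_s)
    if artifact_sd is not None:
        p = replace(p, artifact_sd=artifact_sd)
    if channel_noise_sd is not None:
        p = replace(p, channel_noise_sd=channel_noise_sd)

    g = rng.generator
    n = int(round(duration_s * fs))
    homogeneous = mode == "homogeneous"
    amp_factor = p.mut_event_amp_factor if genotype == "MUT" else 1.0

    rise = 0.0 if homogeneous else p.kernel_rise_s
    ds_kernel = _kernel(fs, rise, p.kernel_decay_s)
    ds_da, ds_counts, ds_rate = _shot_noise(
        n, fs, p.event_rate_hz, ds_kernel, p.event_amp * amp_factor, g,
        homogeneous, p.rate_log_sd, p.rate_timescale_s,
    )

    delay_k = int(round(p.ds_vs_delay_s * fs))
    smooth_sigma = p.vs_smooth_s * fs
    ds_smoothed = scipy.ndimage.gaussian_filter1d(ds_da, smooth_sigma, mode="nearest")
    vs_kernel = _kernel(fs, rise, p.vs_kernel_decay_s)
    vs_own, vs_counts, _ = _shot_noise(
        n, fs, p.vs_event_rate_hz, vs_kernel, p.event_amp * amp_factor, g,
        homogeneous, p.rate_log_sd, p.rate_timescale_s,
    )
    vs_da = p.vs_coupling_gain * _delay(ds_smoothed, delay_k) + vs_own

    if genotype == "MUT":
        slow = _ou(n, 1 / fs, p.slow_wave_timescale_s, p.slow_wave_sd, g)
        ds_da = ds_da + slow
        vs_da = vs_da + _delay(slow, delay_k)

    ds_noise = p.noise_sd * g.standard_normal(n)
    vs_noise = p.noise_sd * g.standard_normal(n)
    ds_sig = ds_da + ds_noise
    vs_sig = vs_da + vs_noise

    events = []
    amph_truth = {}
    if amph_time_s is not None:
        if not (0 < amph_time_s < duration_s):
            raise ValidationError("amph_time_s outside record")
        i0 = int(round(amph_time_s * fs))
        tail = np.arange(n - i0) / fs
        shape = 1 - np.exp(-tail / p.amph_rise_s)
        for name, sig in (("DS", ds_sig), ("VS", vs_sig)):
            sd_base = float(np.std(sig[:i0]))
            resp = np.zeros(n)
            resp[i0:] = p.amph_sd_units[name] * sd_base * shape
            if name == "DS":
                ds_sig = ds_sig + resp
            else:
                vs_sig = vs_sig + resp
            amph_truth[name] = {"baseline_sd": sd_base, "peak_sd_units": p.amph_sd_units[name]}
        events.append(("AMPH", float(amph_time_s)))

    def embed(signal: np.ndarray, rgen: np.random.Generator) -> tuple[TimeSeries, TimeSeries]:
        """Wrap a dopamine signal into 470/415 channels with shared artifact."""
        f470, f415, gain = 100.0, 50.0, 0.1
        art = _ou(n, 1 / fs, 20.0, p.artifact_sd, rgen) if p.artifact_sd > 0 else np.zeros(n)
        raw470 = f470 * (1 + gain * signal) + art
        raw415 = f415 + 0.5 * art
        if p.channel_noise_sd > 0:
            raw470 = raw470 + p.channel_noise_sd * rgen.standard_normal(n)
            raw415 = raw415 + p.channel_noise_sd * rgen.standard_normal(n)
        return (
            TimeSeries(x=raw470, fs=fs, unit="au"),
            TimeSeries(x=raw415, fs=fs, unit="au"),
        )

    ds470, ds415 = embed(ds_sig, g)
    vs470, vs415 = embed(vs_sig, g)

    common_truth = dict(
        mode=mode,
        delay_s=delay_k / fs,
        noise_sd=p.noise_sd,
        event_amp=p.event_amp * amp_factor,
        amph=amph_truth,
    )
    ds = PhotometrySession(
        region="DS", genotype=genotype, raw470=ds470, raw415=ds415, events=list(events),
        truth={**common_truth, "da": ds_da, "signal": ds_sig, "event_counts": ds_counts,
               "event_count_total": int(ds_counts.sum()), "rate_path": ds_rate},
    )
    vs = PhotometrySession(
        region="VS", genotype=genotype, raw470=vs470, raw415=vs415, events=list(events),
        truth={**common_truth, "da": vs_da, "signal": vs_sig, "event_counts": vs_counts,
               "event_count_total": int(vs_counts.sum())},
    )
    return ds, vs


# ---------------------------------------------------------------------------
# Microdialysis
# ---------------------------------------------------------------------------

#: pre-drug baseline window, minutes
DIALYSIS_BASELINE_MIN = 40.0


def gen_microdialysis_series(
    genotype: str,
    n_fractions: int = 12,
    fraction_min: float = 10.0,
    noise_cv: float = 0.10,
    rng: Optional[RngStream] = None,
    params: Optional[GenotypeParams] = None,
) -> MicrodialysisSeries:
    """Fraction series: flat baseline, then a gamma-shaped drug response.

    The drug is given at the end of the 40-minute baseline window; the
    response peaks at ``amph_peak_fold`` times baseline, 2.5 fraction
    intervals after the drug (so a fraction midpoint lands exactly on the
    peak and a noiseless series reproduces the fold exactly).
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    if noise_cv > 0 and rng is None:
        raise ValidationError("rng required when noise_cv > 0")
    if n_fractions * fraction_min <= DIALYSIS_BASELINE_MIN:
        raise ValidationError("record must extend past the baseline window")
    d = (params or genotype_params(genotype)).dialysis
    t_drug = DIALYSIS_BASELINE_MIN
    t = (np.arange(n_fractions) + 0.5) * fraction_min
    da = np.full(n_fractions, d.baseline)
    post = t > t_drug
    tau = t[post] - t_drug
    t_peak = 2.5 * fraction_min
    shape = 2.0
    g = (tau / t_peak) ** shape * np.exp(shape * (1 - tau / t_peak))
    da[post] = d.baseline * (1 + (d.amph_peak_fold - 1) * g)
    if noise_cv > 0:
        da = da * (1 + noise_cv * rng.generator.standard_normal(n_fractions))
    return MicrodialysisSeries(
        t_min=t,
        da=da,
        t_drug_min=t_drug,
        baseline_window_min=DIALYSIS_BASELINE_MIN,
        genotype=genotype,
        truth={"baseline": d.baseline, "amph_peak_fold": d.amph_peak_fold, "t_peak_min": t_drug + t_peak},
    )


# ---------------------------------------------------------------------------
# Fiber images
# ---------------------------------------------------------------------------


def _random_polyline(
    shape: tuple[int, int], rng: np.random.Generator, step_px: float, heading_sd: float
) -> np.ndarray:
    """Smooth random fiber path entering from a random edge."""
    h, w = shape
    edge = rng.integers(4)
    if edge == 0:  # top
        pos = np.array([0.0, rng.uniform(0, w - 1)])
        heading = np.pi / 2
    elif edge == 1:  # bottom
        pos = np.array([h - 1.0, rng.uniform(0, w - 1)])
        heading = -np.pi / 2
    elif edge == 2:  # left
        pos = np.array([rng.uniform(0, h - 1), 0.0])
        heading = 0.0
    else:  # right
        pos = np.array([rng.uniform(0, h - 1), w - 1.0])
        heading = np.pi
    heading += rng.uniform(-0.6, 0.6)
    pts = [pos.copy()]
    max_steps = int(4 * (h + w) / step_px)
    for _ in range(max_steps):
        heading += heading_sd * rng.standard_normal()
        pos = pos + step_px * np.array([np.sin(heading), np.cos(heading)])
        pts.append(pos.copy())
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            break
    return np.array(pts)


def gen_fiber_image(
    n_fibers: int,
    size_px: int = 768,
    um_per_px: float = 0.2,
    psf_sigma_px: float = 1.5,
    noise_level: float = 0.05,
    rng: Optional[RngStream] = None,
    intensity: float = 5.0,
    background: float = 0.1,
    step_px: float = 2.0,
    heading_sd: float = 0.03,
    channel: str = "DAT",
) -> FiberImage:
    """Synthetic fiber image: smooth curves, Gaussian PSF, Poisson-like noise.

    Ground truth records every fiber's polyline so grid crossings can be
    computed exactly. ``noise_level`` is the relative photon-noise SD at unit
    intensity (smaller = cleaner).
    """
    if n_fibers < 0:
        raise ValidationError("n_fibers must be >= 0")
    if rng is None:
        raise ValidationError("rng is required")
    g = rng.generator
    img = np.zeros((size_px, size_px))
    polylines = []
    for _ in range(n_fibers):
        poly = _random_polyline((size_px, size_px), g, step_px, heading_sd)
        polylines.append(poly)
        for i in range(len(poly) - 1):
            r0, c0 = np.clip(np.round(poly[i]), 0, size_px - 1).astype(int)
            r1, c1 = np.clip(np.round(poly[i + 1]), 0, size_px - 1).astype(int)
            rr, cc = skimage.draw.line(r0, c0, r1, c1)
            img[rr, cc] = intensity
    img = scipy.ndimage.gaussian_filter(img, psf_sigma_px)
    photons = 1.0 / noise_level**2
    noisy = g.poisson(photons * (img + background)) / photons
    return FiberImage(
        pixels=noisy,
        um_per_px=um_per_px,
        channel=channel,
        truth={"polylines": polylines, "n_fibers": n_fibers, "psf_sigma_px": psf_sigma_px,
               "noise_level": noise_level, "background": background},
    )
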