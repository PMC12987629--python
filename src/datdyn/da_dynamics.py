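"""Dopamine-dynamics analytics: spectra, heterogeneity, coupling, drug response.

These operators quantify the temporal structure of striatal dopamine signals:

* spectral energy density (Welch averaged periodogram, reported on a log grid),
* the decile-variance heterogeneity statistic — the variance of the one-sample
  first difference of the signal, conditioned on deciles of signal intensity
  and normalized to the lowest decile. Under a homogeneous shot-noise null
  (kernel jumps arriving independently of state) the profile is flat; state-
  dependent release makes it rise with intensity,
* dorsal-to-ventral cross-correlation with sub-sample peak-lag refinement
  (positive lag = dorsal leads),
* amphetamine-response summaries: AUC and peak in baseline-SD units and the
  mean rectified amplitude of the fast (band-passed) signal component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, TimeSeries
from .errors import ValidationError
from .photometry_pre import ProcessedTrace, bandpass, zscore_to_baseline

logger = logging.getLogger("datdyn")

#: number of log-spaced reporting bins for spectral densities; wide enough
#: that a Hann main lobe (3 Welch points at the default 20 s window) fits in
#: one bin over the fast band
N_SPECTRAL_BINS = 36


def _as_timeseries(obj) -> TimeSeries:
    return obj.ts if isinstance(obj, ProcessedTrace) else obj


# ---------------------------------------------------------------------------
# Spectral energy density
# ---------------------------------------------------------------------------


@dataclass
class SpectralDensity:
    """Energy density per Hz on a log-spaced frequency grid.

    ``df`` holds the effective bin widths, so ``sum(e * df)`` recovers the
    signal variance (Parseval normalization check).
    """

    f: np.ndarray
    e: np.ndarray
    df: np.ndarray
    n_segments: int

    def total_energy(self) -> float:
        return float(np.sum(self.e * self.df))

    def band_fraction(self, f_lo: float, f_hi: float = np.inf) -> float:
        """Fraction of total energy in [f_lo, f_hi)."""
        mask = (self.f >= f_lo) & (self.f < f_hi)
        return float(np.sum(self.e[mask] * self.df[mask]) / self.total_energy())


def spectral_energy_density(
    z, cfg: Optional[AnalysisConfig] = None
) -> SpectralDensity:
    """Welch averaged-periodogram estimate on a fixed log-spaced grid.

    Hann window of ``cfg.welch_window_s`` with ``cfg.welch_overlap_frac``
    overlap; the linear Welch grid is aggregated into log-spaced bins by
    energy-preserving averaging (each Welch frequency contributes its exact
    energy to the bin containing it).
    """
    cfg = cfg or AnalysisConfig()
    ts = _as_timeseries(z)
    nperseg = int(round(cfg.welch_window_s * ts.fs))
    if nperseg > ts.n:
        raise ValidationError("record shorter than one Welch window")
    noverlap = int(nperseg * cfg.welch_overlap_frac)
    step = nperseg - noverlap
    n_segments = 1 + (ts.n - nperseg) // step
    if n_segments < 10:
        raise ValidationError(
            f"record supports only {n_segments} Welch windows; >= 10 required"
        )
    # detrend=False so that components slower than one window still appear as
    # near-DC energy and the Parseval normalization holds for slow signals;
    # the global mean is removed instead so total energy equals the variance
    f, pxx = scipy.signal.welch(
        ts.x - np.mean(ts.x),
        fs=ts.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )
    delta = f[1] - f[0]
    p0 = pxx[0]  # sub-resolution (segment-mean) energy, folded into bin 1
    f, pxx = f[1:], pxx[1:]

    edges = np.geomspace(f[0] * 0.999, f[-1] * 1.001, N_SPECTRAL_BINS + 1)
    idx = np.digitize(f, edges) - 1
    fb, eb, db = [], [], []
    for k in range(N_SPECTRAL_BINS):
        sel = idx == k
        m = int(sel.sum())
        if m == 0:
            continue
        energy = float(np.sum(pxx[sel]) * delta)
        if not fb:  # first populated bin also receives the DC-point energy
            energy += float(p0 * delta)
            m += 1
        fb.append(float(np.exp(np.mean(np.log(f[sel])))))
        eb.append(energy / (m * delta))
        db.append(m * delta)
    return SpectralDensity(
        f=np.array(fb), e=np.array(eb), df=np.array(db), n_segments=int(n_segments)
    )


def compare_spectra(
    group_a: Sequence[SpectralDensity],
    group_b: Sequence[SpectralDensity],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-frequency-bin two-sample t tests with Holm-Sidak correction."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need >= 2 sessions per group")
    f0 = group_a[0].f
    for s in list(group_a) + list(group_b):
        if s.f.shape != f0.shape or not np.allclose(s.f, f0):
            raise ValidationError("spectral frequency grids do not match")
    a = np.vstack([s.e for s in group_a])
    b = np.vstack([s.e for s in group_b])
    t, p = scipy.stats.ttest_ind(a, b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return pd.DataFrame({"f": f0, "t": t, "p": p, "p_adj": p_adj, "reject": reject})


# ---------------------------------------------------------------------------
# Decile-variance heterogeneity
# ---------------------------------------------------------------------------


@dataclass
class DecileVarianceProfile:
    """First-difference variance per signal-intensity decile.

    ``v_norm`` is ``v / v[0]`` (normalized to the lowest decile), so
    ``v_norm[0] == 1`` exactly.
    """

    edges: np.ndarray
    v: np.ndarray
    v_norm: np.ndarray


def _stable_decile_assignment(level: np.ndarray, k: int) -> np.ndarray:
    """Equal-count bins by stable rank; ties share the lower bin."""
    m = level.size
    order = np.argsort(level, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(m)
    bins = (ranks * k) // m
    # force equal values into the bin of their lowest-ranked occurrence
    sorted_vals = level[order]
    sorted_bins = bins[order]
    new_group = np.r_[True, sorted_vals[1:] != sorted_vals[:-1]]
    group_start = np.maximum.accumulate(np.where(new_group, np.arange(m), 0))
    sorted_bins = sorted_bins[group_start]
    bins[order] = sorted_bins
    return bins


def decile_variance_profile(z, n_deciles: int = 10) -> DecileVarianceProfile:
    """Variance of the first difference conditioned on signal-intensity deciles.

    Each interior sample i contributes its forward difference
    d(i) = x(i+1) - x(i), assigned to the decile of x(i). Within a decile the
    variance is taken about the least-squares line of d on x, which removes
    the mean-reversion component E[d|x] (exactly linear for an exponential-
    kernel shot-noise process) — without this, the finite width of the tail
    deciles would inflate their variance even under a homogeneous null. The
    profile is normalized to the lowest decile.
    """
    ts = _as_timeseries(z)
    x = ts.x
    m = x.size - 1
    if m < 100 * n_deciles:
        raise ValidationError(
            f"need >= {100 * n_deciles} interior samples for {n_deciles} bins, got {m}"
        )
    level = x[:-1]
    if np.unique(level).size < n_deciles:
        raise ValidationError("fewer distinct signal values than bins")
    d = np.diff(x)
    bins = _stable_decile_assignment(level, n_deciles)
    v = np.empty(n_deciles)
    for k in range(n_deciles):
        sel = bins == k
        nk = int(sel.sum())
        if nk < 3:
            raise ValidationError(f"decile {k} has fewer than 3 samples")
        lk, dk = level[sel], d[sel]
        # residual variance about the within-bin least-squares line in x
        slope, intercept = np.polyfit(lk, dk, 1) if np.std(lk) > 0 else (0.0, np.mean(dk))
        resid = dk - (slope * lk + intercept)
        v[k] = np.sum(resid**2) / max(nk - 2, 1)
    edges = np.quantile(level, np.linspace(0, 1, n_deciles + 1))
    return DecileVarianceProfile(edges=edges, v=v, v_norm=v / v[0])


def heterogeneity_test(
    profiles: Sequence[DecileVarianceProfile], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-decile comparison of v_norm against the lowest decile, BH-corrected.

    For each decile k >= 2 a one-sample t test on log v_norm[k] across
    sessions asks whether first-difference variability differs from the
    bottom decile; Benjamini-Hochberg controls the FDR across the n-1
    comparisons.
    """
    if len(profiles) < 3:
        raise ValidationError("need >= 3 sessions for the heterogeneity test")
    k = profiles[0].v_norm.size
    mat = np.vstack([p.v_norm for p in profiles])
    if mat.shape[1] != k or np.any(mat <= 0):
        raise ValidationError("profiles malformed or non-positive")
    logs = np.log(mat[:, 1:])
    t, p = scipy.stats.ttest_1samp(logs, 0.0, axis=0)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "decile": np.arange(2, k + 1),
            "mean_log_vnorm": logs.mean(axis=0),
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "reject": reject,
        }
    )


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------


@dataclass
class CrossCorrResult:
    lags: np.ndarray
    r: np.ndarray
    peak_lag: float
    peak_r: float


def _refine_peak(lags: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Three-point parabolic refinement of the argmax."""
    i = int(np.argmax(r))
    if 0 < i < r.size - 1:
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            dlag = lags[1] - lags[0]
            return float(lags[i] + delta * dlag), float(y1 - 0.25 * (y0 - y2) * delta)
    return float(lags[i]), float(r[i])


def cross_correlate(ds, vs, max_lag_s: float = 5.0) -> CrossCorrResult:
    """Normalized cross-correlation r(tau) of ds(t) with vs(t + tau).

    Positive peak lag means the dorsal signal precedes the ventral one.
    Each lag's coefficient is the Pearson correlation over the overlapping
    samples.
    """
    a = _as_timeseries(ds)
    b = _as_timeseries(vs)
    if a.n != b.n or abs(a.fs - b.fs) > 1e-9 * a.fs:
        raise ValidationError("traces must share length and sampling rate")
    if max_lag_s >= a.duration / 2:
        raise ValidationError("max_lag must be below half the record duration")
    L = int(round(max_lag_s * a.fs))
    lags = np.arange(-L, L + 1) / a.fs
    r = np.empty(lags.size)
    xa, xb = a.x, b.x
    for j, k in enumerate(range(-L, L + 1)):
        if k >= 0:
            u, w = xa[: a.n - k], xb[k:]
        else:
            u, w = xa[-k:], xb[: a.n + k]
        su, sw = np.std(u), np.std(w)
        r[j] = 0.0 if su == 0 or sw == 0 else float(
            np.mean((u - u.mean()) * (w - w.mean())) / (su * sw)
        )
    peak_lag, peak_r = _refine_peak(lags, r)
    return CrossCorrResult(lags=lags, r=r, peak_lag=peak_lag, peak_r=peak_r)


def average_crosscorr(results: Sequence[CrossCorrResult]) -> CrossCorrResult:
    """Session-averaged correlation curve with the peak re-extracted."""
    if not results:
        raise ValidationError("no cross-correlation curves to average")
    lags = results[0].lags
    for res in results:
        if res.lags.shape != lags.shape or not np.allclose(res.lags, lags):
            raise ValidationError("lag grids do not match")
    r = np.mean([res.r for res in results], axis=0)
    peak_lag, peak_r = _refine_peak(lags, r)
    return CrossCorrResult(lags=lags, r=r, peak_lag=peak_lag, peak_r=peak_r)


# ---------------------------------------------------------------------------
# Fast amplitude and drug response
# ---------------------------------------------------------------------------


@dataclass
class DrugResponse:
    auc: float
    peak_z: float
    fast_amp_pre: float
    fast_amp_post: float


def fast_amplitude(z, window: tuple[float, float], cfg: Optional[AnalysisConfig] = None) -> float:
    """Mean rectified amplitude of the band-passed signal over a window.

    The upper band edge is capped at 0.45*fs so the fast band remains valid
    at low sampling rates.
    """
    cfg = cfg or AnalysisConfig()
    ts = _as_timeseries(z)
    t0, t1 = window
    hi = min(cfg.band_hi_hz, 0.45 * ts.fs)
    filtered = bandpass(ts, cfg.band_lo_hz, hi)
    seg = filtered.slice_window(t0, t1)
    if seg.size == 0:
        raise ValidationError("empty window")
    return float(np.mean(np.abs(seg)))


def drug_response_summary(
    z: ProcessedTrace, t_inject: float, cfg: Optional[AnalysisConfig] = None
) -> DrugResponse:
    """AUC, peak and fast-amplitude change of a drug response.

    The trace is re-referenced to the pre-injection baseline (so AUC and peak
    are in baseline-SD units), the AUC is the trapezoidal integral over
    (t_inject, end], and the fast amplitudes are measured over equal-length
    windows before and after the injection.
    """
    cfg = cfg or AnalysisConfig()
    ts = _as_timeseries(z)
    t_lo, t_hi = ts.t0, ts.t0 + ts.duration
    if not (t_lo < t_inject < t_hi):
        raise ValidationError("injection time outside record")
    base_t0 = max(t_lo, t_inject - cfg.baseline_window_s)
    zb = zscore_to_baseline(ts, (base_t0, t_inject))
    post_mask = zb.ts.t > t_inject
    zpost = zb.ts.x[post_mask]
    tpost = zb.ts.t[post_mask]
    if zpost.size < 2:
        raise ValidationError("no post-injection samples")
    auc = float(np.trapezoid(zpost, tpost))
    peak_z = float(np.max(zpost))
    w = min(t_inject - t_lo, t_hi - t_inject)
    pre = fast_amplitude(zb, (t_inject - w, t_inject), cfg)
    post = fast_amplitude(zb, (t_inject, t_inject + w), cfg)
    return DrugResponse(auc=auc, peak_z=peak_z, fast_amp_pre=pre, fast_amp_post=post)
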