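"""Saturation-uptake Michaelis-Menten fitting and microdialysis quantification.

Synaptosomal uptake rates v(C) measured over a 2-fold dilution row are fitted
with v = Vmax*C/(Km+C) by nonlinear least squares, multistarted from the
Lineweaver-Burk linearization. Mutant transport capacity is summarized as the
paired Vmax fraction (and percent reduction) against the wild-type fit.
Microdialysis fraction series are summarized by the mean dialysate dopamine
over the pre-drug baseline window and the peak post-drug concentration as a
fold of that baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import FitError, ValidationError

logger = logging.getLogger("datdyn")


@dataclass
class UptakeDataset:
    """Replicate-resolved uptake rates over a concentration row."""

    conc_uM: np.ndarray
    rate: np.ndarray
    replicate: np.ndarray
    pair_id: str = ""
    genotype: str = "WT"
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (self.conc_uM.size == self.rate.size == self.replicate.size):
            raise ValidationError("conc, rate and replicate must have equal length")
        if np.any(self.conc_uM <= 0):
            raise ValidationError("concentrations must be positive")
        if np.unique(self.conc_uM).size < 4:
            raise ValidationError("need >= 4 distinct concentrations for fitting")


@dataclass
class MMFit:
    """Michaelis-Menten fit result with asymptotic standard errors."""

    vmax: float
    km_uM: float
    se_vmax: float
    se_km: float
    rss: float


def michaelis_menten(c: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * c / (km + c)


def _lineweaver_burk_start(c: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Start values from the double-reciprocal linearization (positive rates only)."""
    mask = v > 0
    if mask.sum() < 2:
        return float(np.max(v)) or 1.0, float(np.median(c))
    slope, intercept = np.polyfit(1.0 / c[mask], 1.0 / v[mask], 1)
    if intercept <= 0:
        return float(np.max(v[mask])), float(np.median(c))
    vmax0 = 1.0 / intercept
    km0 = slope * vmax0
    if km0 <= 0:
        km0 = float(np.median(c))
    return vmax0, km0


def fit_michaelis_menten(d: UptakeDataset) -> MMFit:
    """Fit v = Vmax*C/(Km+C) by multistart nonlinear least squares.

    Starts are the Lineweaver-Burk estimate plus three deterministic
    perturbations of it; the best residual sum of squares wins. Standard
    errors are asymptotic (from the Jacobian at the optimum). A fitted Km
    outside [conc_min/10, conc_max*10] triggers an extrapolation warning.
    """
    c, v = d.conc_uM, d.rate
    if not np.all(np.isfinite(v)):
        raise ValidationError("rates must be finite")
    if np.any(v < 0):
        warnings.warn("negative uptake rates present; kept (flag-only rule)", stacklevel=2)
    if np.all(v == 0):
        raise FitError("all rates are zero; Michaelis-Menten fit is degenerate")

    vmax0, km0 = _lineweaver_burk_start(c, v)
    starts = [
        (vmax0, km0),
        (vmax0 * 0.5, km0 * 2.0),
        (vmax0 * 2.0, km0 * 0.5),
        (vmax0 * 1.5, km0 * 1.5),
    ]
    best = None
    for p0 in starts:
        try:
            popt, pcov = scipy.optimize.curve_fit(
                michaelis_menten,
                c,
                v,
                p0=p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((v - michaelis_menten(c, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError("Michaelis-Menten fit failed from every start")
    (vmax, km), pcov, rss = best
    if not (np.min(c) / 10 <= km <= np.max(c) * 10):
        warnings.warn(
            f"fitted Km {km:.3g} uM outside the concentration range x10 (extrapolation)",
            stacklevel=2,
        )
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    return MMFit(
        vmax=float(vmax), km_uM=float(km), se_vmax=float(se[0]), se_km=float(se[1]), rss=rss
    )


def relative_vmax(fit_mut: MMFit, fit_wt: MMFit) -> tuple[float, float]:
    """Paired mutant/WT Vmax fraction and percent reduction."""
    if fit_wt.vmax <= 0:
        raise ValidationError("WT Vmax must be positive")
    fraction = fit_mut.vmax / fit_wt.vmax
    return fraction, 100.0 * (1.0 - fraction)


# ---------------------------------------------------------------------------
# Microdialysis
# ---------------------------------------------------------------------------


@dataclass
class MicrodialysisSeries:
    """Dialysate dopamine per fraction, with the drug-injection time.

    ``t_min`` are fraction midpoint times in minutes; the baseline window is
    the ``baseline_window_min`` minutes immediately preceding ``t_drug_min``.
    """

    t_min: np.ndarray
    da: np.ndarray
    t_drug_min: float
    baseline_window_min: float = 40.0
    genotype: str = "WT"
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.da = np.asarray(self.da, dtype=float)
        if self.t_min.size != self.da.size:
            raise ValidationError("t and da must have equal length")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValidationError("fraction times must be strictly increasing")
        # fraction times are interval midpoints; the record starts half a
        # fraction before the first midpoint
        half = 0.5 * float(np.median(np.diff(self.t_min))) if self.t_min.size > 1 else 0.0
        if self.t_drug_min - self.baseline_window_min < self.t_min[0] - half - 1e-9:
            raise ValidationError("baseline window extends before the record")


@dataclass
class MicrodialysisSummary:
    baseline_mean: float
    peak_fold: float
    t_peak_min: float


def microdialysis_summary(s: MicrodialysisSeries) -> MicrodialysisSummary:
    """Baseline mean over the pre-drug window and peak post-drug fold change."""
    base_mask = (s.t_min >= s.t_drug_min - s.baseline_window_min - 1e-9) & (
        s.t_min < s.t_drug_min
    )
    if base_mask.sum() < 3:
        raise ValidationError("need >= 3 baseline fractions")
    baseline = float(np.mean(s.da[base_mask]))
    if baseline <= 0:
        raise ValidationError("baseline mean must be positive")
    post_mask = s.t_min > s.t_drug_min
    if not np.any(post_mask):
        raise ValidationError("no post-drug fractions")
    i = int(np.argmax(s.da[post_mask]))
    peak = float(s.da[post_mask][i])
    t_peak = float(s.t_min[post_mask][i])
    return MicrodialysisSummary(
        baseline_mean=baseline, peak_fold=peak / baseline, t_peak_min=t_peak
    )


def baselines_percent_of_wt(
    baselines: np.ndarray, wt_baselines: np.ndarray
) -> np.ndarray:
    """Convert per-mouse baselines to percent of the WT group mean."""
    wt_baselines = np.asarray(wt_baselines, dtype=float)
    if wt_baselines.size == 0 or np.mean(wt_baselines) <= 0:
        raise ValidationError("WT baseline group empty or non-positive")
    return 100.0 * np.asarray(baselines, dtype=float) / np.mean(wt_baselines)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_uptake_csv(d: UptakeDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "conc_uM": d.conc_uM,
            "rate": d.rate,
            "replicate": d.replicate,
            "pair_id": d.pair_id,
            "genotype": d.genotype,
        }
    ).to_csv(path, index=False)


def read_uptake_csv(path: str | Path) -> UptakeDataset:
    df = pd.read_csv(path)
    return UptakeDataset(
        conc_uM=df["conc_uM"].to_numpy(),
        rate=df["rate"].to_numpy(),
        replicate=df["replicate"].to_numpy(),
        pair_id=str(df["pair_id"].iloc[0]) if "pair_id" in df else "",
        genotype=str(df["genotype"].iloc[0]) if "genotype" in df else "WT",
    )


def write_dialysis_csv(s: MicrodialysisSeries, path: str | Path) -> None:
    df = pd.DataFrame({"t_min": s.t_min, "da": s.da})
    df["t_drug_min"] = s.t_drug_min
    df["baseline_window_min"] = s.baseline_window_min
    df["genotype"] = s.genotype
    df.to_csv(path, index=False)


def read_dialysis_csv(path: str | Path) -> MicrodialysisSeries:
    df = pd.read_csv(path)
    return MicrodialysisSeries(
        t_min=df["t_min"].to_numpy(),
        da=df["da"].to_numpy(),
        t_drug_min=float(df["t_drug_min"].iloc[0]),
        baseline_window_min=float(df["baseline_window_min"].iloc[0]),
        genotype=str(df["genotype"].iloc[0]) if "genotype" in df else "WT",
    )
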