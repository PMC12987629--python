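"""Raw two-channel photometry -> motion-corrected, normalized dopamine signal.

The 415 nm isosbestic channel reports motion and bleaching artifacts but is
insensitive to dopamine. Correction fits the control channel onto the signal
channel with an affine least-squares regression and expresses the residual as
dF/F; the result is invariant to affine transforms of the control channel.
Filtering is zero-phase (forward-backward) so that time-to-peak and lag
estimates downstream are not phase shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import scipy.signal

from .core_io import TimeSeries, check_same_grid
from .errors import DegenerateFitError, ValidationError

#: seconds at each record edge that downstream statistics should treat as
#: filter-transient contaminated
EDGE_GUARD_S = 5.0


@dataclass
class ProcessedTrace:
    """A preprocessed photometry trace with provenance.

    ``ts.unit`` is ``"dff"`` after isosbestic correction or ``"z"`` after
    baseline z-scoring; ``baseline_mean``/``baseline_sd`` are in the source
    units of the step that computed them.
    """

    ts: TimeSeries
    baseline_mean: float = float("nan")
    baseline_sd: float = float("nan")
    provenance: list = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})


def _as_timeseries(obj) -> TimeSeries:
    return obj.ts if isinstance(obj, ProcessedTrace) else obj


def isosbestic_correct(raw470: TimeSeries, raw415: TimeSeries) -> ProcessedTrace:
    """Motion-correct by fitted-control subtraction and convert to dF/F.

    Fits ``f(415) = a*415 + b`` minimizing ``sum (470 - f(415))^2`` and returns
    ``(470 - f(415)) / f(415)``. A constant control channel triggers an
    intercept-only fallback (with a warning); a fitted control that is not
    strictly positive anywhere is a degenerate fit.
    """
    check_same_grid(raw470, raw415)
    x415 = raw415.x
    x470 = raw470.x
    if np.std(x415) < 1e-12:
        if np.std(x470) > 1e-12:
            warnings.warn(
                "constant 415 channel with non-constant 470: intercept-only fit",
                stacklevel=2,
            )
        a, b = 0.0, float(np.mean(x470))
    else:
        a, b = np.polyfit(x415, x470, 1)
    fitted = a * x415 + b
    if np.any(fitted <= 0):
        raise DegenerateFitError("fitted control channel is not strictly positive")
    dff = (x470 - fitted) / fitted
    out = ProcessedTrace(ts=raw470.with_x(dff, unit="dff"))
    out.record("isosbestic_correct", a=float(a), b=float(b))
    return out


def zscore_to_baseline(ts, baseline_window: tuple[float, float]) -> ProcessedTrace:
    """Scale a trace to SD units of a baseline window.

    ``z(t) = (x(t) - mean_baseline) / sd_baseline``; the baseline statistics
    are stored so that downstream drug-response measures can be expressed in
    baseline-SD units.
    """
    src = _as_timeseries(ts)
    t0, t1 = baseline_window
    t_lo, t_hi = src.t0, src.t0 + src.duration
    if not (t_lo - 1e-9 <= t0 < t1 <= t_hi + 1e-9):
        raise ValidationError("baseline window must lie within the record")
    base = src.slice_window(t0, t1)
    mu = float(np.mean(base))
    sd = float(np.std(base))
    if sd <= 0:
        raise ValidationError("baseline SD is zero; cannot z-score")
    z = (src.x - mu) / sd
    out = ProcessedTrace(ts=src.with_x(z, unit="z"), baseline_mean=mu, baseline_sd=sd)
    if isinstance(ts, ProcessedTrace):
        out.provenance = list(ts.provenance)
    out.record("zscore_to_baseline", t0=t0, t1=t1, mean=mu, sd=sd)
    return out


def bandpass(ts: TimeSeries, lo: float, hi: float, order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth band-pass.

    DC is rejected and the passband gain is within about 5% at mid-band (the
    forward-backward pass squares the magnitude response, which the low filter
    order compensates). Reflect padding spans up to three time constants of
    the low edge, capped at the record length.
    """
    if not (0 < lo < hi):
        raise ValidationError("require 0 < lo < hi")
    if hi >= ts.fs / 2:
        raise ValidationError(f"high edge {hi} Hz must be below Nyquist ({ts.fs / 2} Hz)")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    padlen = int(min(ts.n - 1, 3 * ts.fs / lo))
    y = scipy.signal.sosfiltfilt(sos, ts.x, padtype="even", padlen=padlen)
    return ts.with_x(y)


def resample(ts: TimeSeries, fs_out: float) -> TimeSeries:
    """Anti-alias filter and resample to a lower uniform rate (no upsampling)."""
    if fs_out > ts.fs * (1 + 1e-9):
        raise ValidationError("resample only downsamples; fs_out must be <= fs")
    if abs(fs_out - ts.fs) <= 1e-9 * ts.fs:
        return ts.with_x(ts.x.copy())
    frac = Fraction(fs_out / ts.fs).limit_denominator(1000)
    # linear-extension padding avoids the zero-padding droop at record edges
    y = scipy.signal.resample_poly(ts.x, frac.numerator, frac.denominator, padtype="line")
    return TimeSeries(x=y, fs=ts.fs * frac.numerator / frac.denominator, t0=ts.t0, unit=ts.unit)


def preprocess_session(
    session,
    baseline_window: Optional[tuple[float, float]] = None,
) -> ProcessedTrace:
    """Standard pipeline: isosbestic correction, then baseline z-scoring.

    The default baseline window is the stretch before the first event (e.g.
    a drug injection), or the whole record if the session has no events,
    excluding the filter edge guard.
    """
    dff = isosbestic_correct(session.raw470, session.raw415)
    src = dff.ts
    if baseline_window is None:
        t_end = src.t0 + src.duration
        first_event = min((t for _, t in session.events), default=t_end)
        baseline_window = (src.t0, first_event)
    z = zscore_to_baseline(dff, baseline_window)
    return z
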