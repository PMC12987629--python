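"""Domain containers, configuration, file I/O and deterministic random streams.

Times are seconds from session start throughout. Uniform sampling is enforced by
construction: a :class:`TimeSeries` stores ``(t0, fs, x)`` and derives its time
grid, so ``|dt - 1/fs|`` can never drift. Unit tags ("au", "dff", "z", "uM") are
carried as metadata and checked at stage boundaries rather than silently
converted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CorruptInterleaveError,
    FormatError,
    UnitError,
    ValidationError,
)

logger = logging.getLogger("datdyn")

VALID_UNITS = ("au", "dff", "z", "uM")


# ---------------------------------------------------------------------------
# Random-stream management
# ---------------------------------------------------------------------------


def _label_words(label: str) -> list[int]:
    """Map a stream label to stable 32-bit words (independent of PYTHONHASHSEED)."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


@dataclass
class RngStream:
    """A labelled, reproducible random substream.

    Identical ``(seed, label)`` pairs reproduce identical draw sequences;
    different labels (or seeds) give statistically independent streams.
    """

    seed: int
    label: str

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValidationError("seed must be >= 0")
        ss = np.random.SeedSequence([int(self.seed), *_label_words(self.label)])
        self.generator = np.random.default_rng(ss)

    def child(self, sub_label: str) -> "RngStream":
        """Derive an independent substream without advancing this one."""
        return RngStream(self.seed, f"{self.label}/{sub_label}")


def make_rng(seed: int, label: str) -> RngStream:
    """Create an independent, reproducible random stream for ``(seed, label)``."""
    return RngStream(seed, label)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    x : array of signal values.
    fs : sampling rate in Hz.
    t0 : time of the first sample, seconds from session start.
    unit : one of ``"au"`` (raw fluorescence), ``"dff"``, ``"z"``, ``"uM"``.
    """

    x: np.ndarray
    fs: float
    t0: float = 0.0
    unit: str = "au"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ValidationError("TimeSeries.x must be 1-D")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError("fs must be a positive finite number")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs if self.n else 0.0

    def index_of(self, time_s: float) -> int:
        """Nearest-sample index of an absolute time."""
        idx = int(round((time_s - self.t0) * self.fs))
        return min(max(idx, 0), self.n - 1)

    def slice_window(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Samples with t in [t_lo, t_hi] (inclusive)."""
        t = self.t
        mask = (t >= t_lo - 1e-12) & (t <= t_hi + 1e-12)
        return self.x[mask]

    def with_x(self, x: np.ndarray, unit: Optional[str] = None) -> "TimeSeries":
        return TimeSeries(x=x, fs=self.fs, t0=self.t0, unit=unit or self.unit)

    @staticmethod
    def from_t_x(t: np.ndarray, x: np.ndarray, unit: str = "au", rtol: float = 1e-6) -> "TimeSeries":
        """Build from explicit timestamps, enforcing uniform sampling."""
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        if t.size != x.size:
            raise ValidationError("t and x must have equal length")
        if t.size < 2:
            raise ValidationError("need at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        dt0 = np.median(dt)
        if np.max(np.abs(dt - dt0)) > rtol * dt0:
            raise ValidationError("timestamps are not uniformly spaced")
        return TimeSeries(x=x, fs=1.0 / dt0, t0=float(t[0]), unit=unit)


def check_same_grid(a: TimeSeries, b: TimeSeries) -> None:
    if a.n != b.n or abs(a.fs - b.fs) > 1e-9 * a.fs or abs(a.t0 - b.t0) > 1e-9:
        raise ValidationError("time series are not on a common grid")


def check_units(ts: TimeSeries, expected: str) -> None:
    if ts.unit != expected:
        raise UnitError(f"expected unit {expected!r}, got {ts.unit!r}")


@dataclass
class PhotometrySession:
    """Paired-channel photometry recording with metadata.

    ``raw470`` is the dopamine-sensitive channel, ``raw415`` the isosbestic
    (dopamine-independent) control used for motion/bleaching correction.
    ``events`` holds (label, time-in-seconds) markers such as drug injections.
    ``truth`` optionally carries the generator ground-truth record.
    """

    region: str
    genotype: str
    raw470: TimeSeries
    raw415: TimeSeries
    events: list = field(default_factory=list)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.region not in ("DS", "VS"):
            raise ValidationError("region must be 'DS' or 'VS'")
        if self.genotype not in ("WT", "MUT"):
            raise ValidationError("genotype must be 'WT' or 'MUT'")
        check_same_grid(self.raw470, self.raw415)
        t_lo, t_hi = self.raw470.t0, self.raw470.t0 + self.raw470.duration
        for label, t_ev in self.events:
            if not (t_lo - 1e-9 <= t_ev <= t_hi + 1e-9):
                raise ValidationError(f"event {label!r} at {t_ev} s outside record")


_CONFIG_DEFAULTS = dict(
    band_lo_hz=0.01,
    band_hi_hz=10.0,
    welch_window_s=20.0,
    welch_overlap_frac=0.5,
    n_deciles=10,
    max_lag_s=5.0,
    baseline_window_s=1800.0,
    alpha=0.05,
    seed=0,
)


@dataclass
class AnalysisConfig:
    """Analysis parameters with paper-anchored defaults.

    The fast band defaults to 0.01-10 Hz and the significance level to 0.05;
    ``n_deciles`` is the number of signal-intensity bins for the heterogeneity
    statistic. Band edges are validated against fs/2 at use time, not here,
    because the sampling rate is a property of the data.
    """

    band_lo_hz: float = _CONFIG_DEFAULTS["band_lo_hz"]
    band_hi_hz: float = _CONFIG_DEFAULTS["band_hi_hz"]
    welch_window_s: float = _CONFIG_DEFAULTS["welch_window_s"]
    welch_overlap_frac: float = _CONFIG_DEFAULTS["welch_overlap_frac"]
    n_deciles: int = _CONFIG_DEFAULTS["n_deciles"]
    max_lag_s: float = _CONFIG_DEFAULTS["max_lag_s"]
    baseline_window_s: float = _CONFIG_DEFAULTS["baseline_window_s"]
    alpha: float = _CONFIG_DEFAULTS["alpha"]
    seed: int = _CONFIG_DEFAULTS["seed"]

    def __post_init__(self) -> None:
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValidationError("require 0 < band_lo_hz < band_hi_hz")
        if not (0 <= self.welch_overlap_frac < 1):
            raise ValidationError("welch_overlap_frac must be in [0, 1)")
        if self.n_deciles < 2:
            raise ValidationError("n_deciles must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.welch_window_s <= 0 or self.max_lag_s <= 0 or self.baseline_window_s <= 0:
            raise ValidationError("window and lag parameters must be positive")


def load_config(path: Optional[str | Path] = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig`, applying defaults for absent keys.

    ``path`` may be a YAML or JSON file (JSON is a YAML subset); ``None``
    yields pure defaults. Unknown keys are an error. The fully resolved
    configuration is echoed to the package logger.
    """
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError("config file must contain a mapping")
        unknown = set(loaded) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        overrides = loaded
    cfg = AnalysisConfig(**{**_CONFIG_DEFAULTS, **overrides})
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


# ---------------------------------------------------------------------------
# Photometry CSV (long format: time, channel, value)
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ("time", "channel", "value")


def read_photometry_csv(
    path: str | Path,
    fs_expected: Optional[float] = None,
    region: str = "DS",
    genotype: str = "WT",
    events: Optional[list] = None,
) -> PhotometrySession:
    """Read long-format two-channel photometry rows into a session.

    Rows carry a timestamp, a channel flag (415 or 470) and a fluorescence
    value, as written by frame-interleaved acquisition. The two channels are
    demultiplexed and aligned onto the 415-channel timestamps (the reference
    channel) by linear interpolation of the 470 values, which avoids
    extrapolation at the record edges; the shared grid is then checked for
    uniformity.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"photometry CSV missing column(s): {missing}")
    ch = df["channel"].astype(int)
    d415 = df[ch == 415]
    d470 = df[ch == 470]
    if len(d415) == 0 or len(d470) == 0:
        raise FormatError("photometry CSV must contain both 415 and 470 rows")
    ratio = len(d470) / len(d415)
    if not (0.9 <= ratio <= 1.1):
        raise CorruptInterleaveError(
            f"470/415 row-count ratio {ratio:.3f} outside [0.9, 1.1]"
        )
    t415 = d415["time"].to_numpy(dtype=float)
    x415 = d415["value"].to_numpy(dtype=float)
    t470 = d470["time"].to_numpy(dtype=float)
    x470 = d470["value"].to_numpy(dtype=float)
    x470_on_415 = np.interp(t415, t470, x470)

    ts415 = TimeSeries.from_t_x(t415, x415, unit="au")
    ts470 = TimeSeries(x=x470_on_415, fs=ts415.fs, t0=ts415.t0, unit="au")
    if fs_expected is not None and abs(ts415.fs - fs_expected) > 1e-3 * fs_expected:
        raise FormatError(
            f"sampling rate {ts415.fs:.4f} Hz differs from expected {fs_expected} Hz"
        )
    return PhotometrySession(
        region=region,
        genotype=genotype,
        raw470=ts470,
        raw415=ts415,
        events=list(events or []),
    )


def write_photometry_csv(session: PhotometrySession, path: str | Path) -> None:
    """Write a session back to interleaved long-format rows."""
    t = session.raw415.t
    rows = []
    for ti, v415, v470 in zip(t, session.raw415.x, session.raw470.x):
        rows.append((ti, 415, v415))
        rows.append((ti, 470, v470))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tidy results tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy long-format results table (one row per (session, measure))."""
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
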