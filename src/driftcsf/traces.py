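"""Fixational eye-movement traces: simulation, segmentation and plain-text I/O.

Between saccades the eye is never still: it drifts along a seemingly erratic
path that displaces the retinal image by several arcminutes per second.  This
module generates such traces as 2D Brownian motion — the standard statistical
model of fixational drift — segments traces into drift and saccade periods by
a speed threshold, extracts saccade-free drift epochs, and reads/writes a
simple CSV trace format.

Conventions
-----------
Positions are in arcmin, time in seconds, sampled uniformly (default 1 kHz).
The diffusion coefficient ``D`` (arcmin^2/s) follows the per-axis physics
convention: each axis is an independent Gaussian random walk with increment
variance ``2*D*dt``, so the 2D mean squared displacement grows as ``4*D*t``.
This convention is declared once here and used consistently everywhere a
quantity depends on D (Lorentzian widths, scaling laws).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

ARCMIN_PER_DEG = 60.0

#: tolerance on sampling uniformity, seconds
_DT_TOL = 1e-9

TRACE_CSV_COLUMNS = ("trial_id", "t_s", "x_arcmin", "y_arcmin")


class TraceFormatError(ValueError):
    """Raised when a trace CSV file violates the trace schema."""


@dataclasses.dataclass(frozen=True)
class EyeTrace:
    """A uniformly sampled 2D gaze-position time series.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, uniformly spaced.
    x, y : ndarray
        Horizontal and vertical gaze offsets in arcmin.
    trial_id : str
        Opaque label identifying the trial.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    trial_id: str = "trace-0"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise ValueError("t, x, y must be 1D arrays")
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > _DT_TOL) or dt[0] <= 0:
            raise ValueError("trace is not uniformly sampled")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Time spanned by the trace, ``n * dt`` (one bin per sample)."""
        return self.n * self.dt

    def slice(self, start: int, stop: int, trial_id: str | None = None) -> "EyeTrace":
        """Return the subtrace over sample indices ``[start, stop)``."""
        return EyeTrace(
            self.t[start:stop],
            self.x[start:stop],
            self.y[start:stop],
            trial_id if trial_id is not None else self.trial_id,
        )


@dataclasses.dataclass(frozen=True)
class DiffusionSpec:
    """Brownian-drift parameters: diffusion coefficient and RNG seed.

    ``D`` is in arcmin^2/s with per-axis increment variance ``2*D*dt``.
    The value 250 represents normal fixational drift; 2 emulates the residual
    motion left by retinal stabilization.
    """

    D: float = 250.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient D must be >= 0")


@dataclasses.dataclass(frozen=True)
class SegmentLabels:
    """Per-sample drift/saccade labels plus the corresponding event runs.

    ``saccade`` is a boolean mask (True = saccade); ``events`` lists maximal
    runs as ``(label, start, stop)`` with ``stop`` exclusive, partitioning
    the trace.
    """

    saccade: np.ndarray
    events: tuple[tuple[str, int, int], ...]
    smoothed_speed: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.saccade, "saccade", "drift")

    def events_of(self, label: str) -> list[tuple[int, int]]:
        return [(a, b) for lab, a, b in self.events if lab == label]


def simulate_brownian_drift(
    duration: float, fs: float, spec: DiffusionSpec, trial_id: str = "brownian-0"
) -> EyeTrace:
    """Simulate one 2D Brownian drift trace starting at the origin.

    Each axis is the cumulative sum of i.i.d. zero-mean Gaussian increments
    with variance ``2*spec.D/fs``; reproducible given ``spec.seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration too short for the given sampling rate")
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(2.0 * spec.D / fs)
    steps = rng.standard_normal((n - 1, 2)) * sigma
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    t = np.arange(n) / fs
    return EyeTrace(t, pos[:, 0], pos[:, 1], trial_id)


def simulate_drift_ensemble(
    n_traces: int, duration: float, fs: float, spec: DiffusionSpec
) -> list[EyeTrace]:
    """Simulate ``n_traces`` independent Brownian traces from one root seed."""
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_traces)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        n = int(round(duration * fs))
        if duration <= 0 or fs <= 0 or n < 2:
            raise ValueError("invalid duration/fs")
        sigma = np.sqrt(2.0 * spec.D / fs)
        steps = rng.standard_normal((n - 1, 2)) * sigma
        pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        out.append(EyeTrace(np.arange(n) / fs, pos[:, 0], pos[:, 1], f"brownian-{i:03d}"))
    return out


def constant_trace(duration: float, fs: float, x: float = 0.0, y: float = 0.0,
                   trial_id: str = "constant-0") -> EyeTrace:
    """A motionless gaze trace (used for the no-eye-movement condition)."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return EyeTrace(t, np.full(n, float(x)), np.full(n, float(y)), trial_id)


def segment_by_speed(
    trace: EyeTrace, threshold: float = 2.0, smooth_window: float = 0.015
) -> SegmentLabels:
    """Label samples as drift or saccade by a smoothed-speed threshold.

    Speed is computed with central finite differences (one-sided at the
    ends), converted to deg/s, and smoothed with a moving average of width
    ``smooth_window`` seconds (default 15 ms).  Samples whose smoothed speed
    exceeds ``threshold`` (deg/s) are saccade; all others drift.
    """
    window = max(1, int(round(smooth_window * trace.fs)))
    if window > trace.n:
        raise ValueError("trace shorter than the smoothing window")
    vx = np.gradient(trace.x, trace.dt)
    vy = np.gradient(trace.y, trace.dt)
    speed = np.hypot(vx, vy) / ARCMIN_PER_DEG
    smoothed = uniform_filter1d(speed, size=window, mode="nearest")
    saccade = smoothed > threshold
    events = _runs(saccade)
    return SegmentLabels(saccade=saccade, events=events, smoothed_speed=smoothed)


def _runs(mask: np.ndarray) -> tuple[tuple[str, int, int], ...]:
    """Maximal runs of a boolean mask as (label, start, stop) tuples."""
    events: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            events.append(("saccade" if mask[start] else "drift", start, i))
            start = i
    return tuple(events)


def select_drift_epochs(
    trace: EyeTrace, labels: SegmentLabels, min_duration: float
) -> list[EyeTrace]:
    """Extract maximal saccade-free subtraces at least ``min_duration`` s long.

    Epochs keep the parent's time axis and get ``/driftN`` appended to the
    trial id.  May return an empty list.
    """
    if len(labels.saccade) != trace.n:
        raise ValueError("labels do not match the trace")
    min_samples = max(2, int(round(min_duration * trace.fs)))
    epochs = []
    for j, (start, stop) in enumerate(labels.events_of("drift")):
        if stop - start >= min_samples:
            epochs.append(trace.slice(start, stop, f"{trace.trial_id}/drift{j}"))
    return epochs


def write_trace_csv(traces: Sequence[EyeTrace], path) -> None:
    """Write traces to CSV with header ``trial_id,t_s,x_arcmin,y_arcmin``."""
    frames = [
        pd.DataFrame(
            {"trial_id": tr.trial_id, "t_s": tr.t, "x_arcmin": tr.x, "y_arcmin": tr.y}
        )
        for tr in traces
    ]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(TRACE_CSV_COLUMNS))
    df.to_csv(path, index=False)


def read_trace_csv(path) -> list[EyeTrace]:
    """Read traces from the CSV schema written by :func:`write_trace_csv`.

    Samples of a trial must be contiguous and time-ordered with uniform
    timestamps.  Malformed headers, timestamp gaps or NaN positions raise
    :class:`TraceFormatError` naming the offending row (1-based, counting the
    header as row 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file without header") from exc
    if tuple(df.columns) != TRACE_CSV_COLUMNS:
        raise TraceFormatError(
            f"{path}: bad header {tuple(df.columns)!r}, expected {TRACE_CSV_COLUMNS!r}"
        )
    if df.empty:
        return []
    numeric = df[["t_s", "x_arcmin", "y_arcmin"]].to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(numeric).all(axis=1))[0]
    if bad.size:
        raise TraceFormatError(f"{path}: non-finite value at row {bad[0] + 2}")
    traces = []
    seen: set[str] = set()
    # contiguous groups, order preserved
    trial_ids = df["trial_id"].astype(str).to_numpy()
    boundaries = np.nonzero(trial_ids[1:] != trial_ids[:-1])[0] + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(df)]])
    for start, stop in zip(starts, stops):
        tid = trial_ids[start]
        if tid in seen:
            raise TraceFormatError(
                f"{path}: samples of trial {tid!r} are not contiguous (row {start + 2})"
            )
        seen.add(tid)
        t = numeric[start:stop, 0]
        if len(t) < 2:
            raise TraceFormatError(f"{path}: trial {tid!r} has fewer than 2 samples")
        dt = np.diff(t)
        irregular = np.nonzero(np.abs(dt - dt[0]) > _DT_TOL)[0]
        if dt[0] <= 0 or irregular.size:
            row = start + 2 + (int(irregular[0]) + 1 if irregular.size else 1)
            raise TraceFormatError(
                f"{path}: non-uniform timestamps in trial {tid!r} at row {row}"
            )
        traces.append(EyeTrace(t, numeric[start:stop, 1], numeric[start:stop, 2], tid))
    return traces
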