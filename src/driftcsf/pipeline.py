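"""Predicted contrast sensitivity functions for each viewing condition.

The pipeline combines the retinal input power spectrum with the cell
transfer functions:

    O(f, w)   = P_I(f, w) * |RF(f, w)|^2          (response power)
    CSF_z(f)  = sqrt( sum_w  weight(w) * O_z(f, w) * d_nu )
    CSF(f)    = A * [ lambda * CSF_M(f) + (1 - lambda) * CSF_P(f) ]

with ``lambda = 0.57`` and the low-frequency policy zeroing temporal bins
below 0.63 Hz by default (the model assumes no sensitivity to unchanging
stimuli).  The integration runs up to the Nyquist frequency of the sampled
trial; the temporal filters decay fast enough that the tail is negligible.

Shape descriptors operationalize the qualitative band-pass / low-pass
vocabulary: a curve is *low-pass* when the sensitivity at the lowest sampled
spatial frequency reaches at least half of the peak sensitivity (the
threshold is configurable; a ratio exactly at threshold counts as low-pass).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import retinal_input as ri
from .filters import CellModel, LowFreqPolicy, default_cells, low_freq_weight, squared_gain_grid
from .traces import DiffusionSpec, EyeTrace, constant_trace, read_trace_csv, simulate_drift_ensemble

DEFAULT_SF_GRID = np.geomspace(0.1, 60.0, 24)


@dataclasses.dataclass(frozen=True)
class Condition:
    """One experimental condition: drift source plus stimulus defaults.

    ``drift_source`` is ``"brownian"`` (simulated drift with diffusion
    coefficient ``D``, ``n_trials`` traces from ``seed``), ``"traces"``
    (read from ``trace_file``), or ``"none"`` (retinally frozen stimulus,
    xi(t) = 0).
    """

    drift_source: str = "brownian"
    D: float = 250.0
    n_trials: int = 100
    seed: int | None = 0
    trace_file: str | None = None
    temporal_mod: float = 0.0
    duration: float = 3.2
    fs: float = 1000.0
    envelope: ri.EnvelopeSpec = ri.EnvelopeSpec()

    def __post_init__(self) -> None:
        if self.drift_source not in ("brownian", "traces", "none"):
            raise ValueError(f"unknown drift source {self.drift_source!r}")
        if self.drift_source == "traces" and not self.trace_file:
            raise ValueError("drift_source='traces' requires trace_file")

    @classmethod
    def brownian(cls, D: float = 250.0, n_trials: int = 100, seed: int | None = 0, **kw):
        return cls(drift_source="brownian", D=D, n_trials=n_trials, seed=seed, **kw)

    @classmethod
    def no_drift(cls, **kw):
        return cls(drift_source="none", **kw)

    @classmethod
    def from_traces(cls, trace_file: str, **kw):
        return cls(drift_source="traces", trace_file=str(trace_file), **kw)

    def stimulus(self, sf: float = 1.0) -> ri.GratingStimulus:
        return ri.GratingStimulus(
            sf=sf, temporal_mod=self.temporal_mod, duration=self.duration,
            envelope=self.envelope,
        )

    def make_traces(self) -> list[EyeTrace]:
        if self.drift_source == "brownian":
            return simulate_drift_ensemble(
                self.n_trials, self.duration, self.fs, DiffusionSpec(self.D, self.seed)
            )
        if self.drift_source == "none":
            # a single motionless trace: every trial is identical
            return [constant_trace(self.duration, self.fs)]
        return read_trace_csv(self.trace_file)


@dataclasses.dataclass(frozen=True)
class CombinationParams:
    """Global gain A and the M/P mixing weight lambda of the combined CSF."""

    A_gain: float = 1.0
    lam: float = 0.57

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class CSFCurve:
    """Predicted sensitivity vs spatial frequency, with per-class components."""

    sf_grid: np.ndarray
    sensitivity: np.ndarray
    csf_M: np.ndarray
    csf_P: np.ndarray
    condition: Condition | None = None
    params: CombinationParams | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sf_cpd": self.sf_grid,
                "csf_total": self.sensitivity,
                "csf_M": self.csf_M,
                "csf_P": self.csf_P,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class ShapeDescriptors:
    """Peak location, low-frequency ratio and band-pass/low-pass class."""

    peak_sf: float
    peak_sensitivity: float
    lowfreq_ratio: float
    shape_class: str


def response_power(P_I: ri.SpectrumGrid, cell: CellModel) -> ri.SpectrumGrid:
    """Response power O(f, w) = P_I(f, w) * |RF(f, w)|^2."""
    gain = squared_gain_grid(P_I.sf_grid, P_I.tf_grid, cell)
    return ri.SpectrumGrid(P_I.sf_grid, P_I.tf_grid, P_I.power * gain)


def cell_csf(O: ri.SpectrumGrid, policy: LowFreqPolicy | None = None) -> np.ndarray:
    """Per-class CSF: root of the weighted temporal integral of O(f, w)."""
    policy = policy or LowFreqPolicy()
    w = low_freq_weight(O.tf_grid, policy)
    return np.sqrt((O.power * w[None, :]).sum(axis=1) * O.d_nu)


def combine_csf(
    sf_grid: np.ndarray,
    csf_M: np.ndarray,
    csf_P: np.ndarray,
    cp: CombinationParams | None = None,
    **kw,
) -> CSFCurve:
    """Combined CSF: A * [lambda*CSF_M + (1-lambda)*CSF_P], elementwise."""
    cp = cp or CombinationParams()
    sf_grid = np.asarray(sf_grid, dtype=float)
    csf_M = np.asarray(csf_M, dtype=float)
    csf_P = np.asarray(csf_P, dtype=float)
    if not (sf_grid.shape == csf_M.shape == csf_P.shape):
        raise ValueError("sf grids of the M and P components do not match")
    total = cp.A_gain * (cp.lam * csf_M + (1.0 - cp.lam) * csf_P)
    return CSFCurve(sf_grid, total, csf_M, csf_P, params=cp, **kw)


def predict_csf_family(
    condition: Condition,
    temporal_mods: Sequence[float],
    cells: Mapping[str, CellModel] | None = None,
    combination: CombinationParams | None = None,
    policy: LowFreqPolicy | None = None,
    sf_grid: Sequence[float] | None = None,
    n_orientations: int = 8,
    n_phases: int = 4,
) -> dict[float, CSFCurve]:
    """Predict CSFs for several temporal modulation frequencies at once.

    All curves share the same simulated (or loaded) eye traces and the same
    demodulated phase paths, so scanning a temporal-frequency grid costs
    little more than a single condition.  Deterministic given the
    condition's seed.
    """
    cells = cells or default_cells()
    combination = combination or CombinationParams()
    policy = policy or LowFreqPolicy()
    sf_grid = np.asarray(sf_grid if sf_grid is not None else DEFAULT_SF_GRID, dtype=float)
    traces = condition.make_traces()
    spectra = ri.input_power_spectra(
        traces, condition.stimulus(), sf_grid, temporal_mods, n_orientations, n_phases
    )
    out: dict[float, CSFCurve] = {}
    for w, P_I in spectra.items():
        components = {
            name: cell_csf(response_power(P_I, cell), policy) for name, cell in cells.items()
        }
        cond_w = dataclasses.replace(condition, temporal_mod=w)
        curve = combine_csf(
            sf_grid,
            components["M"],
            components["P"],
            combination,
            condition=cond_w,
            meta={
                "seed": condition.seed,
                "n_trials": P_I.n_trials,
                "n_orientations": n_orientations,
                "n_phases": n_phases,
                "policy": dataclasses.asdict(policy),
            },
        )
        object.__setattr__(curve, "input_spectrum", P_I)
        out[w] = curve
    return out


def predict_csf(condition: Condition, **kw) -> CSFCurve:
    """End-to-end CSF prediction for one condition (Brownian drift, recorded
    traces, or no eye movements).

    Returns the combined curve with its M and P components; the input power
    spectrum used is attached as ``curve.input_spectrum``.
    """
    family = predict_csf_family(condition, [condition.temporal_mod], **kw)
    return family[float(condition.temporal_mod)]


def shape_descriptors(curve: CSFCurve, low_pass_threshold: float = 0.5) -> ShapeDescriptors:
    """Peak location (log-parabolic refinement) and shape classification.

    The peak is the grid argmax refined by fitting a parabola to log
    sensitivity vs log spatial frequency through the argmax and its two
    neighbours (no refinement at the grid edges).  ``lowfreq_ratio`` is the
    sensitivity at the lowest sampled sf divided by the maximum; the curve
    is classified low-pass when the ratio is >= the threshold (ties count
    as low-pass).  An all-zero curve yields NaN descriptors flagged as
    ``"undefined"``.
    """
    sens = np.asarray(curve.sensitivity, dtype=float)
    sf = np.asarray(curve.sf_grid, dtype=float)
    if len(sf) < 5:
        raise ValueError("need at least 5 grid points")
    if not np.any(sens > 0):
        return ShapeDescriptors(math.nan, math.nan, math.nan, "undefined")
    i = int(np.argmax(sens))
    peak_sf = float(sf[i])
    peak_sens = float(sens[i])
    if 0 < i < len(sf) - 1 and sens[i - 1] > 0 and sens[i + 1] > 0:
        u = np.log2(sf[i - 1 : i + 2])
        v = np.log(sens[i - 1 : i + 2])
        denom = v[0] - 2.0 * v[1] + v[2]
        if denom < 0:
            delta = 0.5 * (v[0] - v[2]) / denom
            delta = float(np.clip(delta, -1.0, 1.0))
            du = 0.5 * (u[2] - u[0])
            peak_sf = float(2.0 ** (u[1] + delta * du))
            peak_sens = float(np.exp(v[1] - 0.25 * (v[0] - v[2]) * delta))
    ratio = float(sens[0] / sens.max())
    shape = "low_pass" if ratio >= low_pass_threshold else "band_pass"
    return ShapeDescriptors(peak_sf, peak_sens, ratio, shape)


def transition_frequency(
    curves: Mapping[float, CSFCurve], low_pass_threshold: float = 0.5
) -> float:
    """Smallest temporal modulation frequency whose CSF is low-pass.

    ``curves`` maps omega_t (Hz) to predicted curves.  If no curve in the
    family is low-pass the sentinel ``math.inf`` ("above grid") is returned;
    if all are low-pass, the grid minimum.  A non-monotone classification
    along the grid triggers a warning and the first crossing is returned.
    """
    omegas = sorted(curves)
    classes = [
        shape_descriptors(curves[w], low_pass_threshold).shape_class == "low_pass"
        for w in omegas
    ]
    if not any(classes):
        return math.inf
    first = classes.index(True)
    if not all(classes[first:]):
        warnings.warn(
            "band-pass/low-pass classification is not monotone in temporal "
            "frequency; returning the first crossing",
            stacklevel=2,
        )
    return float(omegas[first])


def fit_gain(
    curve: CSFCurve,
    ref_sf: Sequence[float],
    ref_sensitivity: Sequence[float],
    fit_lambda: bool = False,
) -> CombinationParams:
    """Align the predicted curve with reference (sf, sensitivity) samples.

    With ``fit_lambda=False`` only the global gain A is fitted (least
    squares on log sensitivity; the curve's shape is untouched) and the
    returned A multiplies ``curve.sensitivity``.  With ``fit_lambda=True``
    both A and lambda are fitted to ``A*(lam*CSF_M + (1-lam)*CSF_P)`` built
    from the curve's components.  These parameters only align predictions
    with tabulated data; they cannot create or remove the band-pass shape.
    """
    ref_sf = np.asarray(ref_sf, dtype=float)
    ref_s = np.asarray(ref_sensitivity, dtype=float)
    if ref_sf.size == 0 or np.any(ref_s <= 0):
        raise ValueError("reference samples must be non-empty and positive")
    sf = curve.sf_grid
    if np.any(ref_sf < sf.min() - 1e-12) or np.any(ref_sf > sf.max() + 1e-12):
        raise ValueError("reference samples outside the curve's sf range")

    def loginterp(values):
        return np.interp(np.log(ref_sf), np.log(sf), np.log(np.maximum(values, 1e-300)))

    if not fit_lambda:
        log_a = float(np.mean(np.log(ref_s) - loginterp(curve.sensitivity)))
        lam = curve.params.lam if curve.params else 0.57
        return CombinationParams(A_gain=math.exp(log_a), lam=lam)

    if ref_sf.size < 3:
        raise ValueError("fitting lambda requires at least 3 reference samples")
    log_m = loginterp(curve.csf_M)
    log_p = loginterp(curve.csf_P)

    def resid(theta):
        log_a, lam = theta
        mix = lam * np.exp(log_m) + (1.0 - lam) * np.exp(log_p)
        return log_a + np.log(np.maximum(mix, 1e-300)) - np.log(ref_s)

    res = least_squares(resid, [0.0, 0.5], bounds=([-50.0, 0.0], [50.0, 1.0]))
    return CombinationParams(A_gain=math.exp(res.x[0]), lam=float(res.x[1]))
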