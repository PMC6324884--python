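"""Spatial and temporal transfer functions of modeled M and P ganglion cells.

Retinal ganglion cell responses are modeled as space-time separable linear
filters ``RF(f, w) = K(f) * H(w)``:

* ``K(f)`` is a difference of Gaussians (DoG) in the spatial-frequency
  domain, ``K(f) = C*(Kc*pi*rc^2*e^{-pi*(rc*g*f)^2} -
  Ks*pi*rs^2*e^{-pi*(rs*g*f)^2})``, with the foveal scaling ``g = 0.5``
  shrinking the receptive-field radii.  The printed source form of the
  exponent is dimensionally ambiguous; the standard frequency-domain DoG
  used here applies the scaling inside the square, ``(r*g*f)^2``.
* ``H(w)`` is a cascade of ``N`` first-order low-pass stages and one
  subtractive high-pass stage with a pure delay,
  ``H(w) = A*e^{-i*rho*2*pi*w*D}*(1 - Hs/(1+i*rho*2*pi*w*tauS))
  * (1+i*rho*2*pi*w*tauL)^{-N}``; ``rho = 1/1.6`` models the faster
  responses evoked by large stimuli.  Time constants are in ms (converted
  to seconds internally), ``w`` in Hz.  The delay factor has unit modulus
  and never affects any power-based quantity downstream.

Magno cells have ``Hs = 1``, i.e. exactly zero DC gain: they are blind to
unchanging stimuli.  Parvo cells retain a finite DC response, which is why
the low-frequency sensitivity policy (hard cutoff at 0.63 Hz by default, or
a power-law roll-off) matters for the predicted CSF.

The module also provides the DoG-to-CSF fitting analysis: asking what DoG
parameters would be needed for the *spatial kernel alone* to reproduce a
band-pass contrast sensitivity curve.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares


@dataclasses.dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians spatial kernel parameters (radii in deg)."""

    Kc: float
    rc: float
    Ks: float
    rs: float
    gamma: float = 0.5
    C: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rc < self.rs):
            raise ValueError("center radius rc must be smaller than surround radius rs")
        if self.Kc < 0 or self.Ks < 0:
            raise ValueError("Kc and Ks must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def surround_center_balance(self) -> float:
        """Integrated surround/center strength ratio ``Ks*rs^2 / (Kc*rc^2)``.

        A value of 1 means excitation and inhibition cancel exactly at DC.
        """
        return self.Ks * self.rs**2 / (self.Kc * self.rc**2)


@dataclasses.dataclass(frozen=True)
class TemporalParams:
    """Low-pass cascade + high-pass stage parameters (times in ms)."""

    N: int
    A: float
    delay_ms: float
    Hs: float
    tau_lowpass_ms: float
    tau_highpass_ms: float
    rho: float = 1.0 / 1.6

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 <= self.Hs <= 1.0):
            raise ValueError("Hs must be in [0, 1]")
        if self.tau_lowpass_ms <= 0 or self.tau_highpass_ms <= 0:
            raise ValueError("time constants must be positive")


@dataclasses.dataclass(frozen=True)
class CellModel:
    """Paired spatial and temporal parameter sets for one cell class."""

    cell_class: str
    dog: DoGParams
    temporal: TemporalParams


@dataclasses.dataclass(frozen=True)
class LowFreqPolicy:
    """How responses at very low temporal frequencies are discounted.

    ``hard_cutoff`` zeroes bins below ``cutoff`` Hz (nearest-bin rule: on a
    3.2 s trial the default 0.63 Hz discards exactly the first two bins);
    ``power_law`` attenuates power below the cutoff as ``(tf/cutoff)^exponent``
    clipped at 1, emulating the roughly log-log-linear decline of measured
    low-frequency sensitivity.
    """

    mode: str = "hard_cutoff"
    cutoff: float = 0.63
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("hard_cutoff", "power_law"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")


def default_cells() -> dict[str, CellModel]:
    """The M and P cell models shipped with the package (macaque fits)."""
    text = resources.files("driftcsf").joinpath("data/cell_params.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: CellModel(
            cell_class=name,
            dog=DoGParams(**entry["dog"]),
            temporal=TemporalParams(**entry["temporal"]),
        )
        for name, entry in raw.items()
    }


def dog_amplitude(sf, p: DoGParams):
    """Spatial DoG amplitude K(f) at spatial frequency ``sf`` (cycles/deg)."""
    f = np.asarray(sf, dtype=float)
    center = p.Kc * np.pi * p.rc**2 * np.exp(-np.pi * (p.rc * p.gamma * f) ** 2)
    surround = p.Ks * np.pi * p.rs**2 * np.exp(-np.pi * (p.rs * p.gamma * f) ** 2)
    out = p.C * (center - surround)
    return out if out.ndim else float(out)


def temporal_transfer(tf, p: TemporalParams):
    """Complex temporal transfer H(w) at temporal frequency ``tf`` (Hz)."""
    w = np.asarray(tf, dtype=float)
    x = p.rho * 2.0 * np.pi * w
    delay = np.exp(-1j * x * (p.delay_ms / 1000.0))
    highpass = 1.0 - p.Hs / (1.0 + 1j * x * (p.tau_highpass_ms / 1000.0))
    lowpass = (1.0 + 1j * x * (p.tau_lowpass_ms / 1000.0)) ** (-p.N)
    out = p.A * delay * highpass * lowpass
    return out if out.ndim else complex(out)


def rf_transfer(sf, tf, cell: CellModel):
    """Separable receptive-field transfer RF(f, w) = K(f) * H(w) (broadcast)."""
    return dog_amplitude(sf, cell.dog) * temporal_transfer(tf, cell.temporal)


def squared_gain_grid(sf_grid, tf_grid, cell: CellModel) -> np.ndarray:
    """|RF|^2 on the outer (sf x tf) grid — the gain applied to input power."""
    k2 = np.atleast_1d(dog_amplitude(sf_grid, cell.dog)) ** 2
    h2 = np.abs(np.atleast_1d(temporal_transfer(tf_grid, cell.temporal))) ** 2
    return k2[:, None] * h2[None, :]


def low_freq_weight(tf_grid, policy: LowFreqPolicy) -> np.ndarray:
    """Per-bin weights applied to response power before temporal integration."""
    tf = np.asarray(tf_grid, dtype=float)
    if tf.ndim != 1 or len(tf) < 2:
        raise ValueError("tf_grid must be a 1D grid")
    d_nu = tf[1] - tf[0]
    if np.any(np.abs(np.diff(tf) - d_nu) > 1e-9):
        raise ValueError("tf_grid must be uniform")
    if policy.cutoff == 0.0:
        return np.ones_like(tf)
    if policy.mode == "hard_cutoff":
        return (tf >= policy.cutoff - d_nu / 2.0).astype(float)
    w = np.zeros_like(tf)
    pos = tf > 0
    w[pos] = np.minimum(1.0, (tf[pos] / policy.cutoff) ** policy.exponent)
    return w


def read_csf_samples(path) -> tuple[np.ndarray, np.ndarray]:
    """Read user-supplied CSF samples from a CSV with columns
    ``sf_cpd,sensitivity`` (for gain alignment or DoG fitting)."""
    df = pd.read_csv(path)
    missing = {"sf_cpd", "sensitivity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df["sf_cpd"].to_numpy(dtype=float), df["sensitivity"].to_numpy(dtype=float)


@dataclasses.dataclass(frozen=True)
class DoGFit:
    """Result of fitting a DoG spatial kernel to CSF samples."""

    params: DoGParams
    gain: float
    residual_rss: float
    success: bool
    message: str


_DOG_FIELDS = ("Kc", "rc", "Ks", "rs", "gamma")


def fit_dog_to_csf(
    sf,
    sensitivity,
    init: DoGParams,
    free: tuple[str, ...] = ("Kc", "rc", "Ks", "rs"),
    fit_gain: bool = True,
) -> DoGFit:
    """Least-squares fit of a DoG amplitude (times a free gain) to a CSF.

    The fit is performed on log sensitivity, with the free parameters and
    the gain optimized in log space (all are positive).  Requires at least 4
    samples spanning at least one decade of spatial frequency.  A free gain
    together with a free ``Kc`` would make the overall scale degenerate
    (only ``gain*Kc`` is identified), so when ``fit_gain`` is true ``Kc`` is
    held at its initial value and the gain absorbs the scale; ``rc``, ``rs``,
    the ``Ks/Kc`` ratio and the surround/center balance are then all well
    defined.  Non-convergence is reported through ``success`` and
    ``message`` rather than an exception.
    """
    f = np.asarray(sf, dtype=float)
    s = np.asarray(sensitivity, dtype=float)
    if len(f) < 4:
        raise ValueError("need at least 4 CSF samples")
    if np.any(s <= 0) or np.any(f <= 0):
        raise ValueError("spatial frequencies and sensitivities must be positive")
    if f.max() / f.min() < 10.0:
        raise ValueError("samples must span at least one decade of spatial frequency")
    for name in free:
        if name not in _DOG_FIELDS:
            raise ValueError(f"unknown DoG parameter {name!r}")
    if fit_gain:
        free = tuple(name for name in free if name != "Kc")

    log_s = np.log(s)
    floor = 1e-12 * s.max()

    def unpack(theta):
        values = dict(
            Kc=init.Kc, rc=init.rc, Ks=init.Ks, rs=init.rs, gamma=init.gamma, C=init.C
        )
        for name, v in zip(free, theta):
            values[name] = np.exp(v)
        gain = np.exp(theta[-1]) if fit_gain else 1.0
        return values, gain

    def model_log(theta):
        values, gain = unpack(theta)
        f_ = f
        center = values["Kc"] * np.pi * values["rc"] ** 2 * np.exp(
            -np.pi * (values["rc"] * values["gamma"] * f_) ** 2
        )
        surround = values["Ks"] * np.pi * values["rs"] ** 2 * np.exp(
            -np.pi * (values["rs"] * values["gamma"] * f_) ** 2
        )
        k = values["C"] * (center - surround)
        return np.log(np.maximum(np.abs(k) * gain, floor))

    theta0 = np.asarray([np.log(getattr(init, name)) for name in free], dtype=float)
    if fit_gain:
        base = model_log(np.concatenate([theta0, [0.0]]))
        theta0 = np.concatenate([theta0, [np.median(log_s - base)]])

    bounds = (theta0 - 30.0, theta0 + 30.0)
    try:
        res = least_squares(
            lambda th: model_log(th) - log_s, theta0, bounds=bounds, max_nfev=20000
        )
        success = bool(res.success)
        message = res.message
        theta = res.x
        rss = float(np.sum(res.fun**2))
    except Exception as exc:  # pragma: no cover - defensive
        return DoGFit(init, 1.0, float("inf"), False, f"optimizer failure: {exc}")

    values, gain = unpack(theta)
    try:
        params = DoGParams(
            Kc=values["Kc"], rc=values["rc"], Ks=values["Ks"], rs=values["rs"],
            gamma=values["gamma"], C=values["C"],
        )
    except ValueError as exc:
        return DoGFit(init, gain, rss, False, f"fitted parameters invalid: {exc}")
    return DoGFit(params, gain, rss, success, message)
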