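"""Retinal input reconstruction and its space-time power spectrum.

A sinusoidal grating viewed through a moving eye becomes, at the retina,

    I(x, t) = sin(2*pi*f_s . (x - xi(t)) + phi_s) * s(t) * M(t)

where ``xi(t)`` is the eye trajectory, ``s(t)`` an optional sinusoidal
contrast modulation at ``omega_t`` Hz (``s = 1`` for static gratings) and
``M(t)`` the on/off contrast envelope of the trial.  For a pure sinusoid all
spatial structure reduces to a phase path: the complex *demodulated signal*

    z(t) = exp(-i*2*pi*f_s * u(alpha_s) . xi(t) / 60) * s(t) * M(t)

carries every temporal modulation the drifting grating imposes at spatial
frequency ``f_s`` (cycles/deg; ``xi`` in arcmin, hence the /60).  The
temporal power spectrum of ``z``, averaged over trials, orientations and
phases, is the radial slice ``P_I(f, omega)`` of the space-time input power.

Eye drift redistributes the grating's static (0 Hz) power into non-zero
temporal frequencies.  For Brownian drift the redistribution is a Lorentzian
with decay rate ``k = 4*pi^2*f^2*(D/3600)``, provided here as an independent
analytic oracle, alongside a brute-force space-time FFT oracle.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traces import ARCMIN_PER_DEG, EyeTrace


@dataclasses.dataclass(frozen=True)
class EnvelopeSpec:
    """On/off contrast envelope of a trial.

    ``ramp_shape`` is one of ``raised_cosine`` (default), ``linear`` or
    ``none``; symmetric ramps of ``ramp_duration`` seconds sit at both ends
    of the trial, with the plateau contrast in between.
    """

    ramp_shape: str = "raised_cosine"
    ramp_duration: float = 0.5
    plateau: float = 1.0

    def __post_init__(self) -> None:
        if self.ramp_shape not in ("raised_cosine", "linear", "none"):
            raise ValueError(f"unknown ramp shape {self.ramp_shape!r}")
        if self.ramp_duration < 0:
            raise ValueError("ramp_duration must be >= 0")


@dataclasses.dataclass(frozen=True)
class GratingStimulus:
    """Parameters of one trial's sinusoidal grating.

    sf in cycles/deg, orientation and phase in rad, temporal_mod in Hz
    (0 means an unmodulated, static grating), duration in seconds.
    """

    sf: float
    orientation: float = 0.0
    phase: float = 0.0
    temporal_mod: float = 0.0
    duration: float = 3.2
    envelope: EnvelopeSpec = EnvelopeSpec()

    def __post_init__(self) -> None:
        if self.sf <= 0:
            raise ValueError("spatial frequency must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.temporal_mod < 0:
            raise ValueError("temporal modulation frequency must be >= 0")

    def with_(self, **kw) -> "GratingStimulus":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class SpectrumGrid:
    """Power on a (spatial frequency x temporal frequency) grid.

    ``power`` has shape ``(len(sf_grid), len(tf_grid))`` in one-sided PSD
    convention: summed power times the bin width ``d_nu`` equals the mean
    squared signal.
    """

    sf_grid: np.ndarray
    tf_grid: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        sf = np.asarray(self.sf_grid, dtype=float)
        tf = np.asarray(self.tf_grid, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if p.shape != (len(sf), len(tf)):
            raise ValueError("power shape does not match the grids")
        object.__setattr__(self, "sf_grid", sf)
        object.__setattr__(self, "tf_grid", tf)
        object.__setattr__(self, "power", p)

    @property
    def d_nu(self) -> float:
        return float(self.tf_grid[1] - self.tf_grid[0])


@dataclasses.dataclass(frozen=True)
class InputSpectrum(SpectrumGrid):
    """Radially averaged space-time power spectrum of the retinal input."""

    n_trials: int = 1
    n_orientations: int = 1
    n_phases: int = 1

    def to_csv(self, path) -> None:
        """Long-format CSV ``sf_cpd,tf_hz,power``."""
        sf, tf = np.meshgrid(self.sf_grid, self.tf_grid, indexing="ij")
        pd.DataFrame(
            {"sf_cpd": sf.ravel(), "tf_hz": tf.ravel(), "power": self.power.ravel()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "InputSpectrum":
        df = pd.read_csv(path)
        sf_grid = np.unique(df["sf_cpd"].to_numpy())
        tf_grid = np.unique(df["tf_hz"].to_numpy())
        power = (
            df.pivot(index="sf_cpd", columns="tf_hz", values="power")
            .reindex(index=sf_grid, columns=tf_grid)
            .to_numpy()
        )
        return cls(sf_grid, tf_grid, power, **meta)


@dataclasses.dataclass(frozen=True)
class PowerDecomposition:
    """Per spatial frequency: DC (0 Hz bin) vs dynamic power above a cutoff."""

    sf_grid: np.ndarray
    dc_power: np.ndarray
    dynamic_power: np.ndarray
    cutoff: float

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "sf_cpd": self.sf_grid,
                "dc_power": self.dc_power,
                "dynamic_power": self.dynamic_power,
            }
        ).to_csv(path, index=False)


def contrast_envelope(t_grid: np.ndarray, env: EnvelopeSpec) -> np.ndarray:
    """Evaluate the contrast envelope M(t) on a uniform time grid.

    The trial duration is taken as ``n * dt`` so the grid covers
    ``[0, duration)``; ramps rise from 0 at trial onset to the plateau and
    mirror symmetrically at offset.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t_grid must be a 1D grid with >= 2 samples")
    dt = t[1] - t[0]
    if np.any(np.abs(np.diff(t) - dt) > 1e-9):
        raise ValueError("t_grid must be uniform")
    duration = len(t) * dt
    tau = t - t[0]
    ramp = env.ramp_duration
    if env.ramp_shape == "none" or ramp < 1e-12:
        return np.full_like(tau, env.plateau)
    if 2 * ramp > duration + 1e-12:
        raise ValueError("ramps longer than the trial")
    if env.ramp_shape == "raised_cosine":
        up = np.where(tau < ramp, 0.5 * (1.0 - np.cos(np.pi * np.minimum(tau, ramp) / ramp)), 1.0)
        rem = duration - tau
        down = np.where(rem < ramp, 0.5 * (1.0 - np.cos(np.pi * np.maximum(rem, 0.0) / ramp)), 1.0)
    else:  # linear
        up = np.minimum(tau / ramp, 1.0)
        down = np.minimum((duration - tau) / ramp, 1.0)
    m = np.minimum(up, down)
    return env.plateau * np.clip(m, 0.0, 1.0)


def _temporal_modulation(t: np.ndarray, omega_t: float) -> np.ndarray:
    """s(t): sinusoidal contrast modulation, identity for static gratings.

    The literal ``sin(2*pi*0*t)`` would null a static grating, so
    ``omega_t = 0`` means unmodulated (``s = 1``).
    """
    if omega_t > 0:
        return np.sin(2.0 * np.pi * omega_t * t)
    return np.ones_like(t)


def demodulated_signal(trace: EyeTrace, stim: GratingStimulus) -> np.ndarray:
    """Complex demodulated signal z(t) of a grating moved by an eye trace.

    ``z(t) = exp(-i*2*pi*sf * u(alpha) . xi(t)/60) * s(t) * M(t)``.  The
    spatial phase phi_s only rotates z by a unit constant and cancels in any
    power spectrum, so it is omitted here.
    """
    n = int(round(stim.duration * trace.fs))
    if trace.n < n:
        raise ValueError("trace shorter than the stimulus")
    t = trace.t[:n] - trace.t[0]
    proj_deg = (
        trace.x[:n] * np.cos(stim.orientation) + trace.y[:n] * np.sin(stim.orientation)
    ) / ARCMIN_PER_DEG
    z = np.exp(-2j * np.pi * stim.sf * proj_deg)
    return z * _temporal_modulation(t, stim.temporal_mod) * contrast_envelope(t, stim.envelope)


def _fold_one_sided(abs2: np.ndarray) -> np.ndarray:
    """Fold |Z|^2 over +-nu: P(nu) = |Z(nu)|^2 + |Z(-nu)|^2, P(0) = |Z(0)|^2."""
    n = abs2.shape[-1]
    half = n // 2
    out = np.empty(abs2.shape[:-1] + (half + 1,), dtype=float)
    out[..., 0] = abs2[..., 0]
    if n % 2 == 0:
        out[..., 1:half] = abs2[..., 1:half] + abs2[..., : half : -1]
        out[..., half] = abs2[..., half]  # Nyquist bin appears once
    else:
        out[..., 1:] = abs2[..., 1 : half + 1] + abs2[..., : half : -1]
    return out


def temporal_power_spectrum(z: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of a (possibly batched) complex series.

    Returns ``(tf_grid, psd)`` with resolution ``fs/n``; normalized so that
    ``sum(psd) * d_nu == mean(|z|^2)`` (Parseval).  The two signs of the
    temporal frequency carry the +-f_s spatial components of the real-valued
    grating, hence the folding.
    """
    z = np.asarray(z)
    n = z.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    Z = np.fft.fft(z, axis=-1) / n
    psd = _fold_one_sided(np.abs(Z) ** 2)
    d_nu = fs / n
    tf = np.arange(psd.shape[-1]) * d_nu
    return tf, psd / d_nu


def input_power_spectra(
    traces: Sequence[EyeTrace],
    stim: GratingStimulus,
    sf_grid: Sequence[float],
    temporal_mods: Sequence[float],
    n_orientations: int = 8,
    n_phases: int = 4,
) -> dict[float, InputSpectrum]:
    """Input power spectra for several temporal modulation frequencies at once.

    The demodulated phase paths depend only on (trace, orientation, sf), so
    they are computed once and reused across the ``temporal_mods``; this is
    what makes scanning omega_t over a grid affordable.  Orientation
    averaging over a uniform grid in [0, 2*pi) implements the radial average
    of the 2D spatial spectrum (both the input power and the spatial kernels
    are circularly symmetric after averaging).  The spatial phase cancels
    exactly in the power and is therefore not looped over; ``n_phases`` is
    recorded as metadata.
    """
    if not traces:
        raise ValueError("need at least one eye trace")
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    fs = traces[0].fs
    n = int(round(stim.duration * fs))
    for tr in traces:
        if abs(tr.fs - fs) > 1e-6:
            raise ValueError("traces must share one sampling rate")
        if tr.n < n:
            raise ValueError(f"trace {tr.trial_id!r} shorter than the stimulus")
    sf_grid = np.asarray(sf_grid, dtype=float)
    t = np.arange(n) / fs
    m = contrast_envelope(t, stim.envelope)

    alphas = np.arange(n_orientations) * 2.0 * np.pi / n_orientations
    X = np.stack([tr.x[:n] for tr in traces])  # (n_tr, n)
    Y = np.stack([tr.y[:n] for tr in traces])
    # (n_or * n_tr, n) projections in deg
    proj = (
        np.cos(alphas)[:, None, None] * X[None, :, :]
        + np.sin(alphas)[:, None, None] * Y[None, :, :]
    ).reshape(-1, n) / ARCMIN_PER_DEG

    mods = {float(w): m * _temporal_modulation(t, float(w)) for w in temporal_mods}
    n_bins = n // 2 + 1
    acc = {w: np.empty((len(sf_grid), n_bins)) for w in mods}
    tf = np.arange(n_bins) * fs / n
    for i, sf in enumerate(sf_grid):
        base = np.exp((-2j * np.pi * sf) * proj)
        for w, mod in mods.items():
            _, psd = temporal_power_spectrum(base * mod, fs)
            acc[w][i] = psd.mean(axis=0)
    return {
        w: InputSpectrum(
            sf_grid,
            tf,
            acc[w],
            n_trials=len(traces),
            n_orientations=n_orientations,
            n_phases=n_phases,
        )
        for w in mods
    }


def input_power_spectrum(
    traces: Sequence[EyeTrace],
    stim: GratingStimulus,
    sf_grid: Sequence[float],
    n_orientations: int = 8,
    n_phases: int = 4,
) -> InputSpectrum:
    """Radially averaged input power spectrum P_I(f, omega) for one stimulus."""
    return input_power_spectra(
        traces, stim, sf_grid, [stim.temporal_mod], n_orientations, n_phases
    )[float(stim.temporal_mod)]


def lorentzian_decay_rate(sf: float, D: float) -> float:
    """Decay rate k (1/s) of the demodulated Brownian phase signal.

    The autocovariance of ``exp(-i*2*pi*sf*xi_u(t)/60)`` for a projected
    Brownian path with per-axis increment variance ``2*D*dt`` is
    ``exp(-k*|tau|)`` with ``k = 4*pi^2*sf^2*(D/3600)`` (D converted from
    arcmin^2/s to deg^2/s).
    """
    return 4.0 * np.pi**2 * sf**2 * D / ARCMIN_PER_DEG**2


def lorentzian_prediction(sf: float, D: float) -> Callable[[np.ndarray], np.ndarray]:
    """One-sided Lorentzian PSD of Brownian-drift modulations, unit power.

    Returns a callable ``nu -> PSD`` with ``S(nu) = 4k/(k^2 + (2*pi*nu)^2)``
    for ``nu > 0`` and half that at ``nu = 0``; the half-width at half
    maximum is ``k / (2*pi)`` Hz and the total one-sided power integrates
    to 1.
    """
    if sf <= 0 or D <= 0:
        raise ValueError("sf and D must be positive")
    k = lorentzian_decay_rate(sf, D)

    def psd(nu):
        nu = np.asarray(nu, dtype=float)
        dens = 4.0 * k / (k**2 + (2.0 * np.pi * nu) ** 2)
        return np.where(nu == 0.0, 0.5 * dens, dens)

    return psd


def lorentzian_hwhm(sf: float, D: float) -> float:
    """Half-width at half maximum (Hz) of the Brownian Lorentzian."""
    return lorentzian_decay_rate(sf, D) / (2.0 * np.pi)


def lorentzian_bin_power(
    sf: float, D: float, tf_grid: np.ndarray, aliased: bool = False, n_images: int = 8
) -> np.ndarray:
    """Expected power per one-sided frequency bin under the Lorentzian law.

    Integrates the two-sided density over each bin (the bin at 0 covers
    ``[0, d_nu/2)``, interior bins are symmetric around their center, and the
    Nyquist bin of an even-length FFT covers a full bin width folded from
    both signs).  With ``aliased=True`` the spectral images displaced by
    multiples of the sampling rate are folded in, which is what a sampled
    measurement of the continuous process must contain; the bins then sum to
    the total unit power up to the neglected images beyond ``n_images``.
    """
    tf = np.asarray(tf_grid, dtype=float)
    d_nu = tf[1] - tf[0]
    fs = 2.0 * tf[-1]  # grid assumed to come from an even-length FFT
    k = lorentzian_decay_rate(sf, D)

    def cdf(nu):  # signed integral of the two-sided density from 0 to nu
        return np.arctan(2.0 * np.pi * nu / k) / np.pi

    images = range(-n_images, n_images + 1) if aliased else (0,)

    def mass(a, b):
        total = np.zeros_like(np.broadcast_arrays(a, b)[0], dtype=float)
        for j in images:
            total += cdf(b + j * fs) - cdf(a + j * fs)
        return total

    lo = np.maximum(tf - d_nu / 2.0, 0.0)
    hi = tf + d_nu / 2.0
    # each one-sided bin collects the two-sided mass at +-nu; the DC bin's
    # two intervals abut at 0 and the Nyquist bin's two images coincide
    power = mass(lo, hi) + mass(-hi, -lo)
    power[-1] /= 2.0
    return power


def brute_force_spacetime_spectrum(
    trace: EyeTrace,
    stim: GratingStimulus,
    n_space: int = 64,
    spatial_extent: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial slice of the full space-time power spectrum, by direct 2D FFT.

    Samples the reconstructed retinal image on a 1D spatial grid along the
    grating orientation over ``spatial_extent`` degrees (default one spatial
    period) with periodic boundary, computes the 2D Fourier power, and reads
    out the temporal spectrum at the +-f_s spatial bins.  Intended as an
    equivalence oracle for :func:`demodulated_signal` on small instances;
    returns ``(tf_grid, psd)`` in the same normalization as
    :func:`temporal_power_spectrum`.
    """
    if spatial_extent is None:
        spatial_extent = 1.0 / stim.sf
    cycles = stim.sf * spatial_extent
    if abs(cycles - round(cycles)) > 1e-9 or round(cycles) < 1:
        raise ValueError("sf must be an integer number of cycles on the spatial grid")
    cycles = int(round(cycles))
    if n_space < 2 * cycles + 2:
        raise ValueError("spatial grid too coarse for this sf")
    n_t = int(round(stim.duration * trace.fs))
    if trace.n < n_t:
        raise ValueError("trace shorter than the stimulus")
    t = trace.t[:n_t] - trace.t[0]
    proj_deg = (
        trace.x[:n_t] * np.cos(stim.orientation) + trace.y[:n_t] * np.sin(stim.orientation)
    ) / ARCMIN_PER_DEG
    x = np.arange(n_space) * spatial_extent / n_space
    mod = _temporal_modulation(t, stim.temporal_mod) * contrast_envelope(t, stim.envelope)
    image = np.sin(
        2.0 * np.pi * stim.sf * (x[:, None] - proj_deg[None, :]) + stim.phase
    ) * mod[None, :]
    F = np.fft.fft2(image) / (n_space * n_t)
    # The grating's +-f_s components sit at spatial rows +-cycles; each row's
    # temporal spectrum folded one-sided carries |W(nu)|^2/4 + |W(-nu)|^2/4,
    # so summing the two rows and doubling reproduces the demodulation PSD.
    rows = np.abs(F[[cycles, -cycles], :]) ** 2
    folded = _fold_one_sided(rows).sum(axis=0) * 2.0
    d_nu = trace.fs / n_t
    tf = np.arange(folded.shape[-1]) * d_nu
    return tf, folded / d_nu


def hard_cutoff_mask(tf_grid: np.ndarray, cutoff: float) -> np.ndarray:
    """Boolean mask of bins kept by a hard low-frequency cutoff.

    The cutoff is snapped to the nearest bin edge: a bin is discarded when
    its center lies below ``cutoff - d_nu/2``.  On a 3.2 s grid (bins every
    0.3125 Hz) a 0.63 Hz cutoff therefore discards exactly the first two
    bins (0 and 0.3125 Hz), the integration starting from the 0.625 Hz bin.
    """
    tf = np.asarray(tf_grid, dtype=float)
    d_nu = tf[1] - tf[0]
    return tf >= cutoff - d_nu / 2.0


def power_decomposition(spec: SpectrumGrid, cutoff: float = 0.63) -> PowerDecomposition:
    """Split input power per spatial frequency into DC and dynamic parts.

    ``dc_power`` is the power in the 0 Hz bin; ``dynamic_power`` sums
    ``power * d_nu`` over bins at or above the cutoff (nearest-bin rule of
    :func:`hard_cutoff_mask`, excluding the DC bin).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    d_nu = spec.d_nu
    keep = hard_cutoff_mask(spec.tf_grid, cutoff)
    keep = keep & (spec.tf_grid > 0)
    dc = spec.power[:, 0] * d_nu
    dyn = (spec.power[:, keep] * d_nu).sum(axis=1)
    return PowerDecomposition(spec.sf_grid, dc, dyn, cutoff)
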