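"""Scripted, seeded model experiments with logged provenance.

Each experiment reproduces one of the model analyses as configurable runs:

* ``fig2_power``     — DC vs dynamic power redistribution by drift.
* ``fig3_static``    — static gratings with vs without fixational drift.
* ``fig4_modulated`` — temporally modulated gratings and the band-pass ->
                       low-pass transition frequency.
* ``fig5_stabilized``— normal drift (D=250) vs simulated retinal
                       stabilization (D=2).
* ``dog_fit``        — DoG surround strength needed for the spatial kernel
                       alone to match a band-pass CSF.

Outputs are per-condition CSVs, a ``summary.json`` with descriptors, seeds
and a config hash (byte-identical across reruns of the same config), and a
``run.log``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import retinal_input as ri
from .filters import LowFreqPolicy, default_cells, fit_dog_to_csf
from .pipeline import (
    CombinationParams,
    Condition,
    predict_csf,
    predict_csf_family,
    shape_descriptors,
    transition_frequency,
)
from .traces import (
    DiffusionSpec,
    EyeTrace,
    constant_trace,
    segment_by_speed,
    simulate_drift_ensemble,
    write_trace_csv,
)

EXPERIMENTS = ("fig2_power", "fig3_static", "fig4_modulated", "fig5_stabilized", "dog_fit")


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment run (all values recorded in outputs)."""

    name: str
    out_dir: str
    seed: int = 0
    D_normal: float = 250.0
    D_stabilized: float = 2.0
    n_trials: int = 100
    n_sf: int = 24
    sf_min: float = 0.1
    sf_max: float = 60.0
    n_orientations: int = 8
    n_phases: int = 4
    temporal_mods: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    duration: float = 3.2
    fs: float = 1000.0
    lam: float = 0.57
    cutoff: float = 0.63
    quick: bool = False

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}")

    def effective(self) -> "ExperimentConfig":
        """Apply the quick profile (fewer trials, coarser grids) if set."""
        if not self.quick:
            return self
        return dataclasses.replace(
            self,
            n_trials=min(self.n_trials, 20),
            n_sf=min(self.n_sf, 12),
            n_orientations=min(self.n_orientations, 4),
            temporal_mods=tuple(w for w in self.temporal_mods if w % 2 == 0),
        )

    def describe(self) -> dict:
        """Config as a dict, without the output location (pure science knobs)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.describe(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sf_grid(cfg: ExperimentConfig) -> np.ndarray:
    return np.geomspace(cfg.sf_min, cfg.sf_max, cfg.n_sf)


def _descriptor_dict(curve) -> dict:
    d = shape_descriptors(curve)
    return {
        "peak_sf_cpd": d.peak_sf,
        "peak_sensitivity": d.peak_sensitivity,
        "lowfreq_ratio": d.lowfreq_ratio,
        "shape_class": d.shape_class,
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment; writes result files and returns the summary dict."""
    eff = cfg.effective()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"experiment={cfg.name} config_hash={cfg.config_hash()}"]
    t0 = time.time()

    sf_grid = _sf_grid(eff)
    cells = default_cells()
    cp = CombinationParams(1.0, eff.lam)
    policy = LowFreqPolicy(cutoff=eff.cutoff)
    common = dict(duration=eff.duration, fs=eff.fs)
    kw = dict(
        cells=cells, combination=cp, policy=policy, sf_grid=sf_grid,
        n_orientations=eff.n_orientations, n_phases=eff.n_phases,
    )
    summary: dict = {
        "experiment": cfg.name,
        "config_hash": cfg.config_hash(),
        "seed": eff.seed,
        "config": eff.describe(),
        "results": {},
    }

    def save_curve(tag: str, curve) -> None:
        curve.to_csv(out / f"csf_{tag}.csv")
        summary["results"][tag] = _descriptor_dict(curve)
        log_lines.append(f"{tag}: {summary['results'][tag]}")

    if cfg.name == "fig2_power":
        cond = Condition.brownian(eff.D_normal, eff.n_trials, eff.seed, **common)
        stim = cond.stimulus()
        traces = cond.make_traces()
        spec_drift = ri.input_power_spectrum(
            traces, stim, sf_grid, eff.n_orientations, eff.n_phases
        )
        spec_none = ri.input_power_spectrum(
            [constant_trace(eff.duration, eff.fs)], stim, sf_grid, 1, eff.n_phases
        )
        for tag, spec in (("drift", spec_drift), ("no_drift", spec_none)):
            dec = ri.power_decomposition(spec, eff.cutoff)
            dec.to_csv(out / f"power_decomposition_{tag}.csv")
            summary["results"][f"dynamic_power_{tag}"] = {
                "sf_cpd": list(map(float, dec.sf_grid)),
                "dynamic_power": list(map(float, dec.dynamic_power)),
            }
        spec_drift.to_csv(out / "input_spectrum_drift.csv")

    elif cfg.name == "fig3_static":
        drift = predict_csf(Condition.brownian(eff.D_normal, eff.n_trials, eff.seed, **common), **kw)
        none = predict_csf(Condition.no_drift(**common), **kw)
        save_curve("drift", drift)
        save_curve("no_drift", none)

    elif cfg.name == "fig4_modulated":
        cond = Condition.brownian(eff.D_normal, eff.n_trials, eff.seed, **common)
        family = predict_csf_family(cond, eff.temporal_mods, **kw)
        for w, curve in sorted(family.items()):
            save_curve(f"mod_{w:g}Hz", curve)
        summary["results"]["transition_frequency_hz"] = transition_frequency(family)

    elif cfg.name == "fig5_stabilized":
        normal = predict_csf(Condition.brownian(eff.D_normal, eff.n_trials, eff.seed, **common), **kw)
        stab = predict_csf(Condition.brownian(eff.D_stabilized, eff.n_trials, eff.seed, **common), **kw)
        save_curve(f"D{eff.D_normal:g}", normal)
        save_curve(f"D{eff.D_stabilized:g}", stab)

    elif cfg.name == "dog_fit":
        # target: the model's own drift-condition CSF (band-pass); ask what
        # DoG parameters a purely spatial account would need to match it
        drift = predict_csf(Condition.brownian(eff.D_normal, eff.n_trials, eff.seed, **common), **kw)
        keep = drift.sensitivity > 0
        for name, cell in cells.items():
            fit = fit_dog_to_csf(drift.sf_grid[keep], drift.sensitivity[keep], init=cell.dog)
            summary["results"][f"dog_fit_{name}"] = {
                "success": fit.success,
                "fitted_balance": fit.params.surround_center_balance,
                "table_balance": cell.dog.surround_center_balance,
                "Ks": fit.params.Ks,
                "rs": fit.params.rs,
                "residual_rss": fit.residual_rss,
            }
        drift.to_csv(out / "csf_target.csv")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log_lines.append(f"elapsed_s={time.time() - t0:.1f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def plot_experiment(out_dir: str) -> list[Path]:
    """Optional write-only plots (PNG) of the CSF curves in an output dir."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    csvs = sorted(out.glob("csf_*.csv"))
    if csvs:
        fig, ax = plt.subplots()
        import pandas as pd

        for f in csvs:
            df = pd.read_csv(f)
            ax.loglog(df["sf_cpd"], df["csf_total"], label=f.stem.replace("csf_", ""))
        ax.set_xlabel("spatial frequency (cycles/deg)")
        ax.set_ylabel("predicted sensitivity (a.u.)")
        ax.legend()
        path = out / "csf_curves.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def generate_fixtures(out_dir: str, seed: int = 0) -> dict[str, Path]:
    """Write the small synthetic files used by the test suite and docs.

    Produces 5 Brownian traces (D=250, 3.2 s), a constant trace, a
    constructed trace containing exactly one saccade-speed excursion, a tiny
    synthetic input spectrum, and a synthetic DoG-generated CSF sample file.
    Regenerates identically under the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    brownian = simulate_drift_ensemble(5, 3.2, 1000.0, DiffusionSpec(250.0, seed))
    paths["brownian_traces"] = out / "brownian_traces.csv"
    write_trace_csv(brownian, paths["brownian_traces"])

    paths["constant_trace"] = out / "constant_trace.csv"
    write_trace_csv([constant_trace(3.2, 1000.0)], paths["constant_trace"])

    paths["saccade_trace"] = out / "saccade_trace.csv"
    write_trace_csv([saccade_trace()], paths["saccade_trace"])

    spec = ri.input_power_spectrum(
        brownian[:2], ri.GratingStimulus(sf=1.0), sf_grid=[1.0, 4.0, 16.0], n_orientations=2
    )
    paths["input_spectrum"] = out / "synthetic_input_spectrum.csv"
    spec.to_csv(paths["input_spectrum"])

    cells = default_cells()
    sf = np.geomspace(0.1, 40.0, 16)
    sens = 3.0 * np.maximum(
        np.pi * cells["P"].dog.Kc * cells["P"].dog.rc**2
        * np.exp(-np.pi * (cells["P"].dog.rc * 0.5 * sf) ** 2)
        - np.pi * cells["P"].dog.Ks * cells["P"].dog.rs**2
        * np.exp(-np.pi * (cells["P"].dog.rs * 0.5 * sf) ** 2),
        1e-6,
    )
    import pandas as pd

    paths["dog_csf"] = out / "synthetic_dog_csf.csv"
    pd.DataFrame({"sf_cpd": sf, "sensitivity": sens}).to_csv(paths["dog_csf"], index=False)
    return paths


def saccade_trace(fs: float = 1000.0) -> EyeTrace:
    """1 s still + 20 ms ramp at 10 deg/s + 1 s still: one saccade event."""
    n_still = int(fs)
    n_ramp = int(0.02 * fs)
    ramp = np.arange(1, n_ramp + 1) * (10.0 * 60.0 / fs)  # 10 deg/s in arcmin
    x = np.concatenate([np.zeros(n_still), ramp, np.full(n_still, ramp[-1])])
    t = np.arange(len(x)) / fs
    return EyeTrace(t, x, np.zeros_like(x), "saccade-fixture")


__all__ = [
    "EXPERIMENTS",
    "ExperimentConfig",
    "run_experiment",
    "plot_experiment",
    "generate_fixtures",
    "saccade_trace",
    "segment_by_speed",
]
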