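"""End-to-end orchestration and sampling-plan bookkeeping.

`run_pipeline` drives the full analysis for a declarative multi-system
configuration: descriptors → shared sketch-map → per-system landscapes and
minima → pairwise EMD comparison → interface SASA summaries, writing a
machine-readable report and a provenance log.  `SimulationPlan` reproduces
the simple arithmetic of sampling campaigns (conformations × replicas ×
duration) for planning and reporting.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import ConjugateTrajectory
from .descriptors import rmd_series
from .io import read_conjugate
from .landscape import (density2d, find_minima, free_energy_surface,
                        select_basin_frames)
from .compare import arrange_by_similarity, pairwise_emd
from .sasa import interface_report
from .sketchmap import SigmoidParams, fit_sketchmap, select_landmarks
from .synthetic import two_domain_ensemble

_US_PER_UNIT = {
    "fs": 1e-9, "ps": 1e-6, "ns": 1e-3,
    "us": 1.0, "μs": 1.0, "ms": 1e3, "s": 1e6,
}


@dataclass
class PlanEntry:
    """One line of a sampling plan: label, how many starting conformations,
    how many replicas each, and the duration per run."""

    label: str
    n_conformations: int
    n_replicas: int
    duration: float
    unit: str = "ns"

    def __post_init__(self) -> None:
        if self.n_conformations < 1 or self.n_replicas < 1:
            raise ValueError("counts must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.unit not in _US_PER_UNIT:
            raise ValueError(f"unknown time unit {self.unit!r}")

    @property
    def total_us(self) -> float:
        return (self.n_conformations * self.n_replicas * self.duration
                * _US_PER_UNIT[self.unit])


@dataclass
class SimulationPlan:
    entries: list[PlanEntry] = field(default_factory=list)


def plan_total_time(plan: SimulationPlan) -> dict:
    """Total sampled time per entry and overall, in μs.

    Values are exact; rounding happens only in :func:`format_duration`.
    """
    per_entry = {e.label: e.total_us for e in plan.entries}
    return {"entries": per_entry, "overall_us": sum(per_entry.values())}


def format_duration(us: float, sig: int = 2) -> str:
    """Display a μs duration rounded to ``sig`` significant figures."""
    if us == 0:
        return "0 μs"
    ndigits = sig - 1 - int(math.floor(math.log10(abs(us))))
    v = round(us, ndigits)
    if v == int(v):
        return f"{int(v)} μs"
    return f"{v} μs"


# ----------------------------------------------------------------------
# Run configuration

_REQUIRED_SEEDS = ("landmarks", "fit", "basin_frames")


@dataclass
class SystemConfig:
    """One system to analyse: a trajectory on disk or a synthetic recipe."""

    label: str
    trajectory: str | None = None
    topology_file: str | None = None
    linkage: dict | None = None
    cg: bool = False
    synthetic: dict | None = None

    def __post_init__(self) -> None:
        if (self.trajectory is None) == (self.synthetic is None):
            raise ValueError(
                f"system {self.label!r}: specify exactly one of "
                f"'trajectory' or 'synthetic'")
        if self.trajectory is not None and self.linkage is None:
            raise ValueError(f"system {self.label!r}: trajectory input "
                             f"needs a linkage spec")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    Every stochastic stage must have an explicit seed in ``seeds``
    (``landmarks``, ``fit``, ``basin_frames``, plus ``synthetic`` when any
    system is generated); a config omitting one is refused at validation.
    """

    systems: list[SystemConfig]
    seeds: dict
    stride: int = 1
    sigma: float = 5.9
    a_hd: float = 12.0
    b_hd: float = 4.0
    a_ld: float = 2.0
    b_ld: float = 4.0
    n_landmarks: int = 2000
    gamma: float = 0.1
    bins: int = 100
    temperature: float = 300.0
    k_minima: int = 5
    n_basin_minima: int = 4
    n_basin_random: int = 10
    basin_radius: float = float("inf")
    min_bin_count: float = 2.0
    probe_radius: float = 0.14
    n_sphere_points: int = 960
    projection_grid_fraction: float = 0.01
    compute_sasa: bool = True

    def __post_init__(self) -> None:
        if len(self.systems) < 1:
            raise ValueError("need at least one system")
        self.systems = [s if isinstance(s, SystemConfig)
                        else SystemConfig(**s) for s in self.systems]
        needed = list(_REQUIRED_SEEDS)
        if any(s.synthetic is not None for s in self.systems):
            needed.append("synthetic")
        missing = [k for k in needed if k not in self.seeds]
        if missing:
            raise ValueError(f"config omits required seeds: {missing}")
        for s in self.systems:
            for p in (s.trajectory, s.topology_file):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @property
    def sigmoid_params(self) -> SigmoidParams:
        return SigmoidParams(sigma=self.sigma, a_hd=self.a_hd,
                             b_hd=self.b_hd, a_ld=self.a_ld, b_ld=self.b_ld)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _load_system(system: SystemConfig, config: RunConfig
                 ) -> ConjugateTrajectory:
    if system.synthetic is not None:
        spec = dict(system.synthetic)
        spec.setdefault("seed", config.seeds["synthetic"])
        traj, _, _ = two_domain_ensemble(
            n_frames=spec.get("n_frames", 1000),
            weights=spec.get("weights", [1.0]),
            n_residues=spec.get("n_residues", 72),
            noise_sd=spec.get("noise_sd", 0.05),
            seed=spec["seed"])
        return traj
    return read_conjugate(system.trajectory, system.linkage,
                          topology_file=system.topology_file,
                          cg=system.cg)


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis and write report + provenance.

    Returns the report dictionary; ``report.json``, a ``proj_<label>.tsv``
    per system and ``provenance.json`` are written under ``out_dir``.  Any
    stage failure is re-raised with the stage name and the hash of its
    input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    rmds: dict[str, np.ndarray] = {}
    trajs: dict[str, ConjugateTrajectory] = {}
    try:
        for s in config.systems:
            trajs[s.label] = _load_system(s, config)
        stage = "rmd"
        for s in config.systems:
            rmds[s.label] = rmd_series(trajs[s.label], stride=config.stride)
        pooled = np.vstack([rmds[s.label] for s in config.systems])
        stage = "sketchmap"
        n_land = min(config.n_landmarks, len(pooled))
        landmarks = select_landmarks(pooled, n_land, gamma=config.gamma,
                                     seed=config.seeds["landmarks"])
        model = fit_sketchmap(landmarks, config.sigmoid_params,
                              seed=config.seeds["fit"])
        projections = {
            s.label: model.project(
                rmds[s.label],
                grid_fraction=config.projection_grid_fraction)
            for s in config.systems}
        stage = "landscape"
        all_proj = np.vstack(list(projections.values()))
        lo = all_proj.min(axis=0)
        hi = all_proj.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        extent = ((lo[0] - 0.05 * span[0], hi[0] + 0.05 * span[0]),
                  (lo[1] - 0.05 * span[1], hi[1] + 0.05 * span[1]))
        densities, minima_out, basin_out = {}, {}, {}
        for s in config.systems:
            dens = density2d(projections[s.label], bins=config.bins,
                             extent=extent)
            densities[s.label] = dens
            fes = free_energy_surface(dens, config.temperature)
            mins = find_minima(fes, config.k_minima,
                               min_count=config.min_bin_count)
            minima_out[s.label] = {
                "x": mins.x.tolist(), "y": mins.y.tolist(),
                "depth_kT": mins.depth.tolist(),
                "truncated": mins.truncated,
            }
            groups = select_basin_frames(
                fes, projections[s.label],
                n_minima=min(config.n_basin_minima, len(mins)),
                n_random=config.n_basin_random,
                radius=config.basin_radius,
                seed=config.seeds["basin_frames"],
                min_count=config.min_bin_count)
            basin_out[s.label] = [
                {"minimum": g["minimum"], "depth_kT": g["depth"],
                 "nearest_frame": int(g["nearest_frame"]),
                 "random_frames": [int(i) for i in g["random_frames"]]}
                for g in groups]
        stage = "compare"
        emd_block = None
        if len(config.systems) >= 2:
            labels = [s.label for s in config.systems]
            m = pairwise_emd([densities[la] for la in labels], labels,
                             normalize=True, max_support=4096)
            coords = arrange_by_similarity(m)
            emd_block = {
                "labels": labels,
                "matrix": m.values.tolist(),
                "normalized": m.normalized,
                "normalization_constant": m.normalization_constant,
                "arrangement": coords.tolist(),
            }
        stage = "sasa"
        sasa_block = {}
        if config.compute_sasa:
            for s in config.systems:
                rep = interface_report(
                    trajs[s.label], probe_radius=config.probe_radius,
                    n_points=config.n_sphere_points)
                sasa_block[s.label] = {"mean": rep.mean,
                                       "variance": rep.variance}
    except Exception as exc:
        pooled_hash = _sha(pooled) if rmds else "n/a"
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (input hash {pooled_hash})"
        ) from exc

    report = {
        "systems": [s.label for s in config.systems],
        "n_frames": {s.label: len(trajs[s.label]) for s in config.systems},
        "sketchmap": {
            "n_landmarks": int(landmarks.n),
            "stress": model.stress,
            "converged": model.converged,
        },
        "minima": minima_out,
        "basin_frames": basin_out,
        "emd": emd_block,
        "interface_sasa": sasa_block,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    for s in config.systems:
        np.savetxt(out_dir / f"proj_{s.label}.tsv", projections[s.label],
                   delimiter="\t", header="x\ty")
    provenance = {
        "conjmap_version": __version__,
        "numpy_version": np.__version__,
        "python": platform.python_version(),
        "seeds": config.seeds,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("systems", "seeds")},
        "input_hashes": {la: _sha(r) for la, r in rmds.items()},
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str))
    return report
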