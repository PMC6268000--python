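"""Synthetic two-domain conjugate ensembles with known ground truth.

Real conjugate ensembles come from long coarse-grained MD runs; for testing
every downstream stage (descriptors, sketch-map, free-energy landscapes,
EMD comparison, SASA) this module generates rigid-body stand-ins: a compact
self-avoiding backbone-site chain per subunit, and frames drawn from a
mixture of conformational *basins*, each a fixed relative pose of the
proximal subunit plus isotropic Gaussian positional noise.  Basin
occupancies, poses and noise levels are prescribed, so recovered landscape
minima, depths and interface burial can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .core import (DISTAL, PROXIMAL, ConjugateTopology, ConjugateTrajectory,
                   DEFAULT_ANALYSIS_RESIDUES)

#: Virtual backbone bond length, nm (Cα-Cα / CG backbone-bead scale).
BOND_LENGTH_NM = 0.38
#: Minimum distance between any two sites of a generated chain, nm.
MIN_SITE_SEPARATION_NM = 0.35
#: Default per-site positional noise within a basin, nm.
DEFAULT_NOISE_SD_NM = 0.05
#: Default bead radius for generated topologies, nm.
DEFAULT_BEAD_RADIUS_NM = 0.23


def make_toy_subunit(n_residues: int, seed: int,
                     n_proposals: int = 64) -> np.ndarray:
    """Generate a compact self-avoiding backbone-site chain.

    Sites are grown one bond at a time; among self-avoiding candidate
    placements the one closest to the current centroid is taken, which
    produces globule-like chains whose radius of gyration grows sublinearly
    with length.  Deterministic for a given seed.

    Returns an ``(n_residues, 3)`` coordinate array in nm, centered at the
    centroid.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        placed = coords[:i]
        centroid = placed.mean(axis=0)
        best = None
        best_d = np.inf
        trials = n_proposals
        while best is None:
            dirs = rng.normal(size=(trials, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            cand = coords[i - 1] + BOND_LENGTH_NM * dirs
            # self-avoidance against all previously placed sites
            dmin = cdist(cand, placed).min(axis=1)
            ok = dmin >= MIN_SITE_SEPARATION_NM - 1e-12
            # the bonded predecessor sits at exactly one bond length
            ok &= np.abs(cdist(cand, placed[i - 1:i])[:, 0]
                         - BOND_LENGTH_NM) < 1e-9
            for c in cand[ok]:
                d = np.linalg.norm(c - centroid)
                if d < best_d:
                    best, best_d = c, d
            trials *= 2
            if trials > 65536 and best is None:  # pragma: no cover
                raise RuntimeError("chain growth stalled; try another seed")
        coords[i] = best
    return coords - coords.mean(axis=0)


def make_conjugate_topology(n_residues: int = 72,
                            radius: float = DEFAULT_BEAD_RADIUS_NM,
                            analysis_residues: int = DEFAULT_ANALYSIS_RESIDUES,
                            ) -> ConjugateTopology:
    """Backbone-bead-only topology for two toy subunits of equal length.

    Polarity alternates along the chain (odd residues polar, even apolar),
    giving both polarity classes a presence in any interface.
    """
    n = 2 * n_residues
    residue_index = np.tile(np.arange(1, n_residues + 1), 2)
    subunit = np.array([DISTAL] * n_residues + [PROXIMAL] * n_residues,
                       dtype=object)
    polarity = np.where(residue_index % 2 == 1, "polar", "apolar"
                        ).astype(object)
    residue_name = np.where(polarity == "polar", "SER", "LEU").astype(object)
    return ConjugateTopology(
        residue_index=residue_index,
        subunit=subunit,
        residue_name=residue_name,
        is_backbone=np.ones(n, dtype=bool),
        polarity=polarity,
        radius=np.full(n, radius),
        analysis_residues=analysis_residues,
        particle_name=np.array(["BB"] * n, dtype=object),
    )


@dataclass
class BasinSpec:
    """Rigid-body pose of the proximal subunit defining one basin.

    ``rotation`` is applied to the proximal template (about its centroid)
    before translating its centroid to ``translation`` (nm, relative to the
    distal centroid at the origin).
    """

    rotation: np.ndarray
    translation: np.ndarray
    weight: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD_NM

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.weight <= 0:
            raise ValueError("basin weight must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def place(self, proximal_template: np.ndarray) -> np.ndarray:
        centered = proximal_template - proximal_template.mean(axis=0)
        return centered @ self.rotation.T + self.translation


@dataclass
class SyntheticEnsembleSpec:
    """Recipe for a rigid-body two-domain ensemble.

    Frames are drawn from the basin mixture (probabilities proportional to
    basin weights) with isotropic Gaussian site noise; frames whose linker
    distance (last distal residue to first proximal residue) exceeds
    ``linker_cap`` are resampled.
    """

    n_residues: int = 72
    basins: list[BasinSpec] = field(default_factory=list)
    n_frames: int = 1000
    seed: int = 0
    linker_cap: float | None = None
    template_seed: int = 2024
    clash_tolerance: float = 0.1  # minimum noiseless inter-subunit gap, nm

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.basins:
            raise ValueError("at least one basin is required")
        total = sum(b.weight for b in self.basins)
        if not np.isfinite(total) or total <= 0:
            raise ValueError("basin weights must be normalizable")


def _check_no_clashes(distal: np.ndarray, spec: SyntheticEnsembleSpec,
                      proximal_template: np.ndarray) -> None:
    for k, basin in enumerate(spec.basins):
        prox = basin.place(proximal_template)
        dmin = cdist(distal, prox).min()
        if dmin <= spec.clash_tolerance:
            raise ValueError(
                f"basin {k}: noiseless pose clashes with the distal subunit "
                f"(min inter-subunit distance {dmin:.3f} nm)")


def sample_conjugate_ensemble(spec: SyntheticEnsembleSpec
                              ) -> tuple[ConjugateTrajectory, np.ndarray]:
    """Draw an ensemble from a basin mixture.

    Returns the trajectory and the ground-truth basin label per frame (a
    sidecar array, so tests never have to re-infer basin membership).
    """
    rng = np.random.default_rng(spec.seed)
    distal = make_toy_subunit(spec.n_residues, spec.template_seed)
    proximal_template = make_toy_subunit(spec.n_residues,
                                         spec.template_seed + 1)
    _check_no_clashes(distal, spec, proximal_template)
    topology = make_conjugate_topology(spec.n_residues)

    weights = np.array([b.weight for b in spec.basins], dtype=float)
    weights /= weights.sum()
    labels = rng.choice(len(spec.basins), size=spec.n_frames, p=weights)

    placed = [b.place(proximal_template) for b in spec.basins]
    n_sites = 2 * spec.n_residues
    coords = np.empty((spec.n_frames, n_sites, 3))
    n_attempts = 0
    for f, lab in enumerate(labels):
        basin = spec.basins[lab]
        base = np.vstack([distal, placed[lab]])
        while True:
            n_attempts += 1
            frame = base + rng.normal(0.0, basin.noise_sd, size=base.shape) \
                if basin.noise_sd > 0 else base.copy()
            if spec.linker_cap is None:
                break
            linker = np.linalg.norm(frame[spec.n_residues - 1]
                                    - frame[spec.n_residues])
            if linker <= spec.linker_cap:
                break
            if n_attempts > 100 * (f + 1) and (f + 1) / n_attempts < 0.01:
                raise RuntimeError(
                    "linker-cap acceptance rate below 1%; loosen the cap or "
                    "move the basins closer")
        coords[f] = frame
    traj = ConjugateTrajectory.from_coordinates(topology, coords)
    return traj, labels


def default_basin_specs(n_basins: int,
                        weights: list[float] | None = None,
                        n_residues: int = 72,
                        noise_sd: float = DEFAULT_NOISE_SD_NM,
                        gap: float = 0.4,
                        template_seed: int = 2024) -> list[BasinSpec]:
    """Well-separated contact poses for ``n_basins`` basins.

    Basin *k* docks the proximal subunit against the distal one along the
    *k*-th of a fixed set of approach directions, rotated by a distinct
    angle, at the closest distance that keeps a ``gap`` nm clearance — i.e.
    distinct compact interfaces, as different linkage positions would give.
    """
    if weights is None:
        weights = [1.0] * n_basins
    if len(weights) != n_basins:
        raise ValueError("need one weight per basin")
    directions = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1], [1, 1, 1], [-1, -1, 1],
    ], dtype=float)
    if n_basins > len(directions):
        raise ValueError(f"at most {len(directions)} default basins")
    distal = make_toy_subunit(n_residues, template_seed)
    proximal = make_toy_subunit(n_residues, template_seed + 1)
    proximal = proximal - proximal.mean(axis=0)
    basins = []
    for k in range(n_basins):
        u = directions[k] / np.linalg.norm(directions[k])
        rot = Rotation.from_rotvec(2.0 * np.pi * k / max(n_basins, 2)
                                   * np.array([0.0, 0.0, 1.0])).as_matrix()
        rotated = proximal @ rot.T
        # closest centre distance along u with the required clearance:
        # shrink until the minimum inter-subunit distance hits gap
        lo, hi = 0.0, 20.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            dmin = cdist(distal, rotated + mid * u).min()
            if dmin < gap:
                lo = mid
            else:
                hi = mid
        basins.append(BasinSpec(rotation=rot, translation=hi * u,
                                weight=weights[k], noise_sd=noise_sd))
    return basins


def two_domain_ensemble(n_frames: int,
                        weights: list[float],
                        n_residues: int = 72,
                        noise_sd: float = DEFAULT_NOISE_SD_NM,
                        seed: int = 0
                        ) -> tuple[ConjugateTrajectory, np.ndarray,
                                   SyntheticEnsembleSpec]:
    """Convenience wrapper: default basins with given occupancy weights."""
    basins = default_basin_specs(len(weights), weights,
                                 n_residues=n_residues, noise_sd=noise_sd)
    spec = SyntheticEnsembleSpec(n_residues=n_residues, basins=basins,
                                 n_frames=n_frames, seed=seed)
    traj, labels = sample_conjugate_ensemble(spec)
    return traj, labels, spec
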