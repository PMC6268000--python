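"""Solvent-accessible surface area and interface analysis.

SASA is computed with a deterministic Shrake–Rupley scheme: a fixed
Fibonacci lattice of test points on each particle's probe-inflated sphere,
points occluded by any neighboring sphere removed, surviving fraction times
the sphere area.  On top of this sit the conjugate-interface quantities:

* the buried interface area  SA_interface = SASA_distal + SASA_proximal
  - SASA_conjugate,  split into apolar (a-SA) and polar (p-SA)
  contributions by attributing the burial particle-wise;
* accessibility of named surface patches (for ubiquitin: the Ile44 and
  Ile36 hydrophobic patches, the Phe4 patch and the TEK box) relative to
  the unobstructed subunit;
* the residue-wise mean SASA loss ΔSASA caused by the partner subunit,
  with error bars over independent runs.

Isolated-subunit SASA always reuses the same frame coordinates with the
partner's particles removed, so per-particle burial is non-negative by
construction and the polarity split partitions SA_interface exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import (DISTAL, PROXIMAL, SUBUNITS, ConjugateFrame,
                   ConjugateTopology, ConjugateTrajectory)

#: Default probe radii, nm.
PROBE_RADIUS_ATOMISTIC = 0.14
PROBE_RADIUS_CG = 0.21

#: Default number of Shrake–Rupley test points per sphere.
DEFAULT_N_POINTS = 960

#: Negative interface areas larger than this (nm^2) trigger a diagnostics
#: warning instead of being clamped to zero.
NEGATIVE_AREA_TOLERANCE = 1e-3


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors (deterministic Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = PROBE_RADIUS_ATOMISTIC,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-particle solvent-accessible surface area, nm^2.

    Deterministic for fixed ``n_points``: the same sphere-point lattice is
    used for every particle, so removing particles can only uncover points
    (monotonicity that downstream burial accounting relies on).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = np.flatnonzero(~np.isfinite(radii) | (radii <= 0))
        raise ValueError(f"missing/invalid radius for particles {bad}")
    n = len(coords)
    inflated = radii + probe_radius
    unit = fibonacci_sphere(n_points)
    out = np.empty(n)
    # neighbor lists from one full distance matrix; systems here are small
    d = cdist(coords, coords)
    for i in range(n):
        cutoff = inflated[i] + inflated
        neighbors = np.flatnonzero((d[i] < cutoff) & (np.arange(n) != i))
        pts = coords[i] + inflated[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            dd = pts - coords[j]
            accessible &= np.einsum("pk,pk->p", dd, dd) >= inflated[j] ** 2
            if not accessible.any():
                break
        out[i] = 4.0 * np.pi * inflated[i] ** 2 * accessible.mean()
    return out


@dataclass
class SASAResult:
    """Per-particle and per-residue SASA of one frame, nm^2."""

    per_particle: np.ndarray
    probe_radius: float
    n_points: int
    topology: ConjugateTopology

    def per_residue(self, subunit: str) -> tuple[np.ndarray, np.ndarray]:
        """(residue indices, summed SASA) for one subunit."""
        mask = self.topology.subunit == subunit
        resids = np.unique(self.topology.residue_index[mask])
        vals = np.array([
            self.per_particle[mask & (self.topology.residue_index == r)].sum()
            for r in resids])
        return resids, vals


def sasa_per_residue(frame: ConjugateFrame, topology: ConjugateTopology,
                     probe_radius: float = PROBE_RADIUS_ATOMISTIC,
                     n_points: int = DEFAULT_N_POINTS) -> SASAResult:
    """SASA of a conjugate frame, resolved per particle and per residue."""
    areas = shrake_rupley(frame.coordinates, topology.radius,
                          probe_radius=probe_radius, n_points=n_points)
    return SASAResult(per_particle=areas, probe_radius=probe_radius,
                      n_points=n_points, topology=topology)


def _burial_per_particle(frame: ConjugateFrame, topology: ConjugateTopology,
                         probe_radius: float, n_points: int) -> np.ndarray:
    """Isolated-subunit minus in-conjugate SASA, per particle (>= 0)."""
    full = shrake_rupley(frame.coordinates, topology.radius,
                         probe_radius=probe_radius, n_points=n_points)
    burial = np.empty_like(full)
    for su in SUBUNITS:
        idx = topology.particles_of(su)
        isolated = shrake_rupley(frame.coordinates[idx],
                                 topology.radius[idx],
                                 probe_radius=probe_radius,
                                 n_points=n_points)
        burial[idx] = isolated - full[idx]
    return burial


def interface_area(frame: ConjugateFrame, topology: ConjugateTopology,
                   probe_radius: float = PROBE_RADIUS_ATOMISTIC,
                   n_points: int = DEFAULT_N_POINTS
                   ) -> tuple[float, float, float]:
    """Buried interface area and its polarity split for one frame.

    Returns ``(SA_interface, a_SA, p_SA)`` in nm^2, where SA_interface is
    the sum of the two isolated-subunit SASAs minus the conjugate SASA and
    a-SA / p-SA are its apolar and polar particle-wise contributions
    (an exact partition: a-SA + p-SA = SA_interface).
    """
    burial = _burial_per_particle(frame, topology, probe_radius, n_points)
    apolar = topology.polarity == "apolar"
    a_sa = float(burial[apolar].sum())
    p_sa = float(burial[~apolar].sum())
    total = a_sa + p_sa
    if -NEGATIVE_AREA_TOLERANCE < total < 0.0:
        total, a_sa, p_sa = 0.0, 0.0, 0.0
    elif total < 0:  # pragma: no cover - cannot occur with shared lattice
        import warnings
        warnings.warn(f"negative interface area {total:.4f} nm^2 exceeds "
                      f"the sampling-noise tolerance")
    return total, a_sa, p_sa


@dataclass
class InterfaceReport:
    """Per-frame interface areas with ensemble statistics, nm^2."""

    sa_interface: np.ndarray
    a_sa: np.ndarray
    p_sa: np.ndarray

    @property
    def mean(self) -> dict[str, float]:
        return {"sa_interface": float(self.sa_interface.mean()),
                "a_sa": float(self.a_sa.mean()),
                "p_sa": float(self.p_sa.mean())}

    @property
    def variance(self) -> dict[str, float]:
        return {"sa_interface": float(self.sa_interface.var()),
                "a_sa": float(self.a_sa.var()),
                "p_sa": float(self.p_sa.var())}


def interface_report(traj: ConjugateTrajectory,
                     probe_radius: float = PROBE_RADIUS_ATOMISTIC,
                     n_points: int = DEFAULT_N_POINTS) -> InterfaceReport:
    """Interface areas for every frame of a trajectory."""
    rows = [interface_area(fr, traj.topology, probe_radius, n_points)
            for fr in traj.frames]
    arr = np.asarray(rows)
    return InterfaceReport(sa_interface=arr[:, 0], a_sa=arr[:, 1],
                           p_sa=arr[:, 2])


# ----------------------------------------------------------------------
# Patches

@dataclass
class PatchDefinition:
    """A named surface patch given as residue indices (1-based, within
    subunit)."""

    name: str
    residues: list[int]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("patch needs at least one residue")


def default_ubiquitin_patches() -> list[PatchDefinition]:
    """The four classical ubiquitin interaction patches.

    Residue memberships follow the common literature usage and are
    configuration data, not hard-coded truth — pass custom
    :class:`PatchDefinition` lists to override.  Residues 73-76 are outside
    the analysis range and therefore excluded.
    """
    return [
        PatchDefinition("Ile44", [8, 44, 68, 70]),
        PatchDefinition("Ile36", [36, 71]),
        PatchDefinition("Phe4", [2, 4, 14]),
        PatchDefinition("TEK", [6, 11, 12, 14, 34]),
    ]


def patch_accessibility(traj: ConjugateTrajectory,
                        patches: Sequence[PatchDefinition] | None = None,
                        monomer_reference: Mapping[str, Mapping[int, float]]
                        | None = None,
                        probe_radius: float = PROBE_RADIUS_ATOMISTIC,
                        n_points: int = DEFAULT_N_POINTS
                        ) -> dict[str, dict[str, float]]:
    """Mean accessibility fraction of surface patches, per subunit.

    For each frame the patch SASA in the conjugate is divided by its SASA
    in the reference monomer — by default the isolated subunit of the same
    frame (partner removed), or a user-supplied per-residue reference table
    ``{subunit: {residue: SASA}}``.  Fractions are averaged over frames and
    clipped to [0, 1].
    """
    if patches is None:
        patches = default_ubiquitin_patches()
    topology = traj.topology
    sums: dict[tuple[str, str], list[float]] = {
        (p.name, su): [] for p in patches for su in SUBUNITS}
    for fr in traj.frames:
        full = shrake_rupley(fr.coordinates, topology.radius,
                             probe_radius=probe_radius, n_points=n_points)
        for su in SUBUNITS:
            idx = topology.particles_of(su)
            if monomer_reference is None:
                iso = shrake_rupley(fr.coordinates[idx], topology.radius[idx],
                                    probe_radius=probe_radius,
                                    n_points=n_points)
                ref_by_res = {}
                for r in np.unique(topology.residue_index[idx]):
                    sel = topology.residue_index[idx] == r
                    ref_by_res[int(r)] = float(iso[sel].sum())
            else:
                ref_by_res = dict(monomer_reference[su])
            for p in patches:
                dimer = sum(
                    float(full[idx][topology.residue_index[idx] == r].sum())
                    for r in p.residues)
                ref = sum(ref_by_res.get(int(r), 0.0) for r in p.residues)
                if ref <= 0:
                    raise ValueError(
                        f"reference SASA of patch {p.name!r} on the {su} "
                        f"subunit is zero")
                sums[(p.name, su)].append(dimer / ref)
    return {p.name: {su: float(np.clip(np.mean(sums[(p.name, su)]), 0.0, 1.0))
                     for su in SUBUNITS}
            for p in patches}


# ----------------------------------------------------------------------
# Residue-wise ΔSASA

@dataclass
class DeltaSASAProfile:
    """Per-residue mean SASA loss caused by the partner subunit, nm^2.

    ``mean[subunit]`` is the per-residue average over all frames of all
    runs; ``error[subunit]`` is the standard deviation of the per-run
    means, the between-replica error bar.
    """

    residues: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    error: dict[str, np.ndarray]
    n_runs: int = 1


def _delta_sasa_frame(frame: ConjugateFrame, topology: ConjugateTopology,
                      probe_radius: float, n_points: int
                      ) -> dict[str, np.ndarray]:
    burial = _burial_per_particle(frame, topology, probe_radius, n_points)
    out = {}
    for su in SUBUNITS:
        mask = topology.subunit == su
        resids = np.unique(topology.residue_index[mask])
        out[su] = np.array([
            burial[mask & (topology.residue_index == r)].sum()
            for r in resids])
    return out


def delta_sasa_profile(runs: Sequence[ConjugateTrajectory],
                       probe_radius: float = PROBE_RADIUS_ATOMISTIC,
                       n_points: int = DEFAULT_N_POINTS) -> DeltaSASAProfile:
    """Residue-wise ΔSASA profile over one or more independent runs.

    Per frame, ΔSASA of a residue is its SASA with the partner subunit
    removed (same coordinates) minus its SASA in the conjugate — a
    non-negative measure of involvement in inter-domain contacts.
    """
    if not runs:
        raise ValueError("need at least one run")
    ref = runs[0].topology
    resids = {su: ref.residues_of(su) for su in SUBUNITS}
    for t in runs[1:]:
        for su in SUBUNITS:
            if not np.array_equal(t.topology.residues_of(su), resids[su]):
                raise ValueError(
                    f"inconsistent {su} residue sets across runs")
    run_means = {su: [] for su in SUBUNITS}
    for t in runs:
        acc = {su: np.zeros(len(resids[su])) for su in SUBUNITS}
        for fr in t.frames:
            per = _delta_sasa_frame(fr, t.topology, probe_radius, n_points)
            for su in SUBUNITS:
                acc[su] += per[su]
        for su in SUBUNITS:
            run_means[su].append(acc[su] / len(t.frames))
    mean = {su: np.mean(run_means[su], axis=0) for su in SUBUNITS}
    error = {su: np.std(run_means[su], axis=0) for su in SUBUNITS}
    return DeltaSASAProfile(residues=resids, mean=mean, error=error,
                            n_runs=len(runs))
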