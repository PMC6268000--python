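"""Core data model for two-domain protein conjugates.

A *conjugate* is a pair of covalently linked subunits (e.g. the distal and
proximal moieties of a ubiquitin dimer).  The topology assigns every particle
— an atom in atomistic structures, a bead in coarse-grained ones — to a
residue, every residue to one subunit, and flags the single *backbone site*
per residue (the Cα atom atomistically, the backbone bead in CG models) on
which all inter-subunit descriptors operate.  Coordinates are always stored
in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

DISTAL = "distal"
PROXIMAL = "proximal"
SUBUNITS = (DISTAL, PROXIMAL)

#: Default number of analysis residues per subunit.  For ubiquitin the four
#: highly flexible C-terminal residues 73-76 are excluded, leaving 1..72.
DEFAULT_ANALYSIS_RESIDUES = 72


class TopologyError(ValueError):
    """Raised when a conjugate topology violates its invariants."""


@dataclass
class ConjugateTopology:
    """Per-particle annotation of a two-subunit conjugate.

    Parameters
    ----------
    residue_index
        1-based residue index *within its subunit*, one entry per particle.
    subunit
        Subunit label per particle, ``"distal"`` or ``"proximal"``.
    residue_name
        Residue name per particle (3-letter codes for standard amino acids).
    is_backbone
        True for the single backbone-site particle of each residue.
    polarity
        ``"polar"`` or ``"apolar"`` per particle, used to split interface
        area into p-SA and a-SA contributions.
    radius
        Particle radius in nm, used by SASA calculations.
    analysis_residues
        Residues ``1..analysis_residues`` of each subunit enter the
        residue-wise minimum-distance descriptor; residues beyond the range
        (e.g. the flexible ubiquitin tail 73-76) are retained for SASA only.
    """

    residue_index: np.ndarray
    subunit: np.ndarray
    residue_name: np.ndarray
    is_backbone: np.ndarray
    polarity: np.ndarray
    radius: np.ndarray
    analysis_residues: int = DEFAULT_ANALYSIS_RESIDUES
    particle_ids: np.ndarray = None  # type: ignore[assignment]
    particle_name: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.subunit = np.asarray(self.subunit, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.is_backbone = np.asarray(self.is_backbone, dtype=bool)
        self.polarity = np.asarray(self.polarity, dtype=object)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.particle_ids is None:
            self.particle_ids = np.arange(self.n_particles)
        self.particle_ids = np.asarray(self.particle_ids, dtype=int)
        if self.particle_name is None:
            # default naming: backbone sites get the Cα convention, the
            # rest are enumerated within their residue
            names = []
            counter: dict[tuple, int] = {}
            for su, ri, bb in zip(self.subunit, self.residue_index,
                                  self.is_backbone):
                if bb:
                    names.append("CA")
                else:
                    k = counter.get((su, ri), 0) + 1
                    counter[(su, ri)] = k
                    names.append(f"X{k}")
            self.particle_name = np.asarray(names, dtype=object)
        self.particle_name = np.asarray(self.particle_name, dtype=object)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.residue_index)

    def validate(self) -> None:
        n = self.n_particles
        for name in ("subunit", "residue_name", "is_backbone", "polarity",
                     "radius", "particle_ids", "particle_name"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise TopologyError(
                    f"field {name!r} has {len(arr)} entries, expected {n}")
        bad = set(self.subunit) - set(SUBUNITS)
        if bad:
            raise TopologyError(f"unknown subunit labels: {sorted(bad)}")
        bad = set(self.polarity) - {"polar", "apolar"}
        if bad:
            raise TopologyError(f"unknown polarity classes: {sorted(bad)}")
        for su in SUBUNITS:
            mask = self.subunit == su
            for resid in np.unique(self.residue_index[mask]):
                nbb = int(np.sum(self.is_backbone & mask
                                 & (self.residue_index == resid)))
                if nbb != 1:
                    raise TopologyError(
                        f"residue {resid} of the {su} subunit has {nbb} "
                        f"backbone-site particles, expected exactly 1")

    # ------------------------------------------------------------------
    def particles_of(self, subunit: str) -> np.ndarray:
        """Indices of all particles belonging to one subunit."""
        if subunit not in SUBUNITS:
            raise ValueError(f"unknown subunit {subunit!r}")
        return np.flatnonzero(self.subunit == subunit)

    def backbone_indices(self, subunit: str, analysis_only: bool = True
                         ) -> np.ndarray:
        """Particle indices of backbone sites of one subunit.

        Ordered by residue index.  With ``analysis_only`` (default) only
        residues ``1..analysis_residues`` are returned.
        """
        mask = (self.subunit == subunit) & self.is_backbone
        if analysis_only:
            mask &= (self.residue_index >= 1) & \
                    (self.residue_index <= self.analysis_residues)
        idx = np.flatnonzero(mask)
        return idx[np.argsort(self.residue_index[idx], kind="stable")]

    def residues_of(self, subunit: str) -> np.ndarray:
        """Sorted residue indices present in one subunit."""
        return np.unique(self.residue_index[self.subunit == subunit])

    def n_residues(self, subunit: str) -> int:
        return len(self.residues_of(subunit))

    def swap_subunits(self) -> "ConjugateTopology":
        """Return a copy with the distal/proximal labels exchanged."""
        swapped = np.where(self.subunit == DISTAL, PROXIMAL, DISTAL)
        return ConjugateTopology(
            residue_index=self.residue_index.copy(),
            subunit=swapped,
            residue_name=self.residue_name.copy(),
            is_backbone=self.is_backbone.copy(),
            polarity=self.polarity.copy(),
            radius=self.radius.copy(),
            analysis_residues=self.analysis_residues,
            particle_ids=self.particle_ids.copy(),
            particle_name=self.particle_name.copy(),
        )


@dataclass
class ConjugateFrame:
    """One frame of particle coordinates, in nm."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class ConjugateTrajectory:
    """An ordered sequence of frames sharing one topology."""

    topology: ConjugateTopology
    frames: list[ConjugateFrame] = field(default_factory=list)
    stride_ps: float | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_particles
        times = []
        for i, fr in enumerate(self.frames):
            if fr.n_particles != n:
                raise ValueError(
                    f"frame {i} has {fr.n_particles} particles, topology "
                    f"has {n}")
            times.append(fr.time)
        if times and np.any(np.diff(times) < 0):
            raise ValueError("frame time stamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ConjugateFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> ConjugateFrame:
        return self.frames[i]

    @property
    def coordinates(self) -> np.ndarray:
        """All coordinates stacked as an (n_frames, n_particles, 3) array."""
        return np.stack([fr.coordinates for fr in self.frames])

    @classmethod
    def from_coordinates(cls, topology: ConjugateTopology,
                         coords: np.ndarray,
                         times: Sequence[float] | None = None,
                         stride_ps: float | None = None
                         ) -> "ConjugateTrajectory":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if times is None:
            times = np.arange(len(coords), dtype=float)
        frames = [ConjugateFrame(c, time=float(t))
                  for c, t in zip(coords, times)]
        return cls(topology=topology, frames=frames, stride_ps=stride_ps)
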