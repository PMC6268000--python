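"""Reading and writing conjugate structures and trajectories.

Standard formats are handled by MDAnalysis: multi-model PDB files and
GRO structure + XTC trajectory pairs are read into a
:class:`~conjmap.core.ConjugateTrajectory`; selected frames are exported as
PDB.  Subunit assignment comes from a *linkage spec* mapping each subunit to
either a chain/segment identifier or an inclusive 1-based range of residue
ordinals in file order.  Coordinates are converted from the Å conventions of
the file formats to nm on read and back on write.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .core import (DISTAL, PROXIMAL, SUBUNITS, ConjugateFrame,
                   ConjugateTopology, ConjugateTrajectory, TopologyError,
                   DEFAULT_ANALYSIS_RESIDUES)

A_PER_NM = 10.0

#: van der Waals radii by element, nm (Bondi-style values).
ELEMENT_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180,
}
DEFAULT_ELEMENT_RADIUS_NM = 0.170

#: Generic coarse-grained bead radius, nm (MARTINI bead scale).
CG_BEAD_RADIUS_NM = 0.23

#: Elements counted as polar for interface-polarity decomposition.
POLAR_ELEMENTS = {"N", "O"}

#: CG bead-name prefixes counted as polar (MARTINI polar/charged classes).
CG_POLAR_PREFIXES = ("P", "Q", "N")


def _element_of(name: str) -> str:
    """Crude element guess from an atom name (PDB naming conventions)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _is_polar_atom(name: str, prev_heavy_element: str | None) -> bool:
    elem = _element_of(name)
    if elem == "H":
        # PDB ordering puts hydrogens after their heavy atom; inherit
        return prev_heavy_element in POLAR_ELEMENTS
    return elem in POLAR_ELEMENTS


def _resolve_linkage(universe: "mda.Universe",
                     linkage_spec: Mapping[str, object]) -> dict[str, np.ndarray]:
    """Map each subunit to a sorted array of residue indices (0-based,
    file order) in the universe."""
    missing = set(SUBUNITS) - set(linkage_spec)
    if missing:
        raise ValueError(f"linkage_spec missing subunits: {sorted(missing)}")
    n_res = len(universe.residues)
    assignment: dict[str, np.ndarray] = {}
    for su in SUBUNITS:
        spec = linkage_spec[su]
        if isinstance(spec, str):
            # chain / segment identifier
            sel = np.array([
                i for i, res in enumerate(universe.residues)
                if getattr(res.atoms[0], "chainID", "") == spec
                or res.segment.segid.strip() == spec
            ])
            if len(sel) == 0:
                raise ValueError(
                    f"linkage_spec chain {spec!r} matches no residues")
        else:
            start, end = spec  # type: ignore[misc]
            if not (1 <= start <= end <= n_res):
                raise ValueError(
                    f"linkage_spec range {spec} out of bounds for "
                    f"{n_res} residues")
            sel = np.arange(start - 1, end)
        assignment[su] = sel
    overlap = np.intersect1d(assignment[DISTAL], assignment[PROXIMAL])
    if len(overlap):
        raise TopologyError(
            f"linkage_spec assigns residues {overlap + 1} (file order) to "
            f"both subunits")
    covered = len(assignment[DISTAL]) + len(assignment[PROXIMAL])
    if covered != n_res:
        raise ValueError(
            f"linkage_spec covers {covered} of {n_res} residues; every "
            f"residue must belong to exactly one subunit")
    return assignment


def topology_from_universe(universe: "mda.Universe",
                           linkage_spec: Mapping[str, object],
                           backbone_site: str = "CA",
                           analysis_residues: int = DEFAULT_ANALYSIS_RESIDUES,
                           cg: bool = False,
                           radius_table: Mapping[str, float] | None = None,
                           ) -> ConjugateTopology:
    """Build a :class:`ConjugateTopology` from an MDAnalysis universe."""
    assignment = _resolve_linkage(universe, linkage_spec)
    res_subunit = np.empty(len(universe.residues), dtype=object)
    res_number = np.zeros(len(universe.residues), dtype=int)
    for su in SUBUNITS:
        sel = assignment[su]
        res_subunit[sel] = su
        res_number[sel] = np.arange(1, len(sel) + 1)

    n = len(universe.atoms)
    residue_index = np.zeros(n, dtype=int)
    subunit = np.empty(n, dtype=object)
    residue_name = np.empty(n, dtype=object)
    is_backbone = np.zeros(n, dtype=bool)
    polarity = np.empty(n, dtype=object)
    radius = np.zeros(n, dtype=float)
    names = np.empty(n, dtype=object)

    prev_heavy: str | None = None
    for i, atom in enumerate(universe.atoms):
        ri = atom.residue.resindex
        residue_index[i] = res_number[ri]
        subunit[i] = res_subunit[ri]
        residue_name[i] = atom.resname
        name = atom.name.strip()
        names[i] = name
        is_backbone[i] = name == backbone_site
        if cg:
            polarity[i] = ("polar" if name.upper().startswith(CG_POLAR_PREFIXES)
                           and name != backbone_site else "apolar")
            radius[i] = CG_BEAD_RADIUS_NM
        else:
            polarity[i] = ("polar"
                           if _is_polar_atom(name, prev_heavy) else "apolar")
            elem = _element_of(name)
            if elem != "H":
                prev_heavy = elem
            table = radius_table or ELEMENT_RADII_NM
            radius[i] = table.get(elem, DEFAULT_ELEMENT_RADIUS_NM)
        if radius_table and name in radius_table:
            radius[i] = radius_table[name]

    # hard error naming the residue if a backbone site is missing
    for su in SUBUNITS:
        sel = assignment[su]
        for local, ri in enumerate(sel, start=1):
            atoms_mask = (subunit == su) & (residue_index == local)
            if not np.any(is_backbone & atoms_mask):
                raise TopologyError(
                    f"residue {local} ({universe.residues[ri].resname}) of "
                    f"the {su} subunit has no backbone site "
                    f"{backbone_site!r}")

    return ConjugateTopology(
        residue_index=residue_index, subunit=subunit,
        residue_name=residue_name, is_backbone=is_backbone,
        polarity=polarity, radius=radius,
        analysis_residues=analysis_residues,
        particle_name=names,
    )


def read_conjugate(path: str | Path,
                   linkage_spec: Mapping[str, object],
                   *,
                   topology_file: str | Path | None = None,
                   backbone_site: str | None = None,
                   analysis_residues: int = DEFAULT_ANALYSIS_RESIDUES,
                   cg: bool = False,
                   radius_table: Mapping[str, float] | None = None,
                   ) -> ConjugateTrajectory:
    """Read a conjugate trajectory from standard files.

    Parameters
    ----------
    path
        A multi-model PDB file, or a trajectory file (e.g. XTC) when
        ``topology_file`` is given.
    linkage_spec
        ``{"distal": ..., "proximal": ...}`` where each value is either a
        chain identifier or an inclusive 1-based ``(start, end)`` range of
        residue ordinals in file order.
    topology_file
        A structure file (e.g. GRO) defining atoms when ``path`` is a
        coordinate-only trajectory.
    backbone_site
        Atom/bead name of the one backbone site per residue.  Defaults to
        ``"CA"`` (atomistic) or ``"BB"`` when ``cg`` is set.
    cg
        Treat the input as coarse-grained: backbone beads named ``"BB"``,
        bead radii and bead-class polarity.
    """
    if backbone_site is None:
        backbone_site = "BB" if cg else "CA"
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology_file is not None:
            universe = mda.Universe(str(topology_file), str(path))
        else:
            universe = mda.Universe(str(path))
    topology = topology_from_universe(
        universe, linkage_spec, backbone_site=backbone_site,
        analysis_residues=analysis_residues, cg=cg,
        radius_table=radius_table)
    frames = []
    for ts in universe.trajectory:
        box = None
        if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float) / A_PER_NM
        t = float(ts.time) if ts.time is not None else float(ts.frame)
        frames.append(ConjugateFrame(
            coordinates=np.asarray(ts.positions, dtype=float) / A_PER_NM,
            box=box, time=t))
    return ConjugateTrajectory(topology=topology, frames=frames)


# ----------------------------------------------------------------------
# Writing

def _universe_from_topology(topology: ConjugateTopology) -> "mda.Universe":
    n = topology.n_particles
    # residues in combined ordering: distal block first, then proximal
    res_keys: list[tuple] = []
    atom_resindex = np.zeros(n, dtype=int)
    order = np.argsort([0 if s == DISTAL else 1 for s in topology.subunit],
                       kind="stable")
    keymap: dict[tuple, int] = {}
    for i in order:
        key = (topology.subunit[i], int(topology.residue_index[i]))
        if key not in keymap:
            keymap[key] = len(res_keys)
            res_keys.append(key)
    for i in range(n):
        atom_resindex[i] = keymap[(topology.subunit[i],
                                   int(topology.residue_index[i]))]
    n_res = len(res_keys)
    res_segindex = np.array([0 if su == DISTAL else 1
                             for su, _ in res_keys])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n_res, n_segments=2,
                               atom_resindex=atom_resindex,
                               residue_segindex=res_segindex,
                               trajectory=True)
        u.add_TopologyAttr("names", topology.particle_name)
        resnames = np.empty(n_res, dtype=object)
        resids = np.zeros(n_res, dtype=int)
        for i in range(n):
            resnames[atom_resindex[i]] = topology.residue_name[i]
            resids[atom_resindex[i]] = topology.residue_index[i]
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        u.add_TopologyAttr("segids", ["A", "B"])
        u.add_TopologyAttr("chainIDs",
                           ["A" if topology.subunit[i] == DISTAL else "B"
                            for i in range(n)])
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
    return u


def write_trajectory(traj: ConjugateTrajectory, path: str | Path) -> Path:
    """Write all frames as one multi-model PDB file."""
    path = Path(path)
    u = _universe_from_topology(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_particles,
                        multiframe=True) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates * A_PER_NM
                w.write(u.atoms)
    return path


def write_frames(traj: ConjugateTrajectory,
                 indices: Sequence[int],
                 out_dir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    """Export selected frames, one PDB file per frame index.

    Files are named ``{prefix}_{index:05d}.pdb``.  An empty index list
    produces no files but succeeds with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    indices = list(indices)
    n = len(traj)
    bad = [i for i in indices if not (0 <= i < n)]
    if bad:
        raise IndexError(
            f"frame indices out of range for {n}-frame trajectory: {bad}")
    if not indices:
        warnings.warn("write_frames called with an empty index list; "
                      "no files written")
        return []
    u = _universe_from_topology(traj.topology)
    paths = []
    for i in indices:
        p = out_dir / f"{prefix}_{i:05d}.pdb"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.positions = traj.frames[i].coordinates * A_PER_NM
            u.atoms.write(str(p))
        paths.append(p)
    return paths
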