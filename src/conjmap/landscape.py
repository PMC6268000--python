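"""Free-energy landscapes from 2D projections.

A projected ensemble is histogrammed into a normalized 2D density ``p`` and
Boltzmann-inverted, ``F = -kT ln p``, shifted so the lowest populated bin is
at zero.  Local minima of the surface identify conformational basins;
representative frames can be drawn from around each minimum, mirroring the
selection of basin structures for atomistic re-simulation (the four lowest
minima plus ten randomly chosen neighbors each).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: Boltzmann constant, kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.0083145


@dataclass
class Density2D:
    """Normalized 2D histogram of projected samples."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    masses: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (len(self.x_edges) - 1,
                                 len(self.y_edges) - 1):
            raise ValueError("masses grid does not match bin edges")
        if np.any(self.masses < 0):
            raise ValueError("bin masses must be non-negative")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("bin masses must sum to 1")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def counts(self) -> np.ndarray:
        return self.masses * self.n_samples

    def support(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin-center coordinates and masses of populated bins."""
        ix, iy = np.nonzero(self.masses)
        pts = np.column_stack([self.x_centers[ix], self.y_centers[iy]])
        return pts, self.masses[ix, iy]


@dataclass
class FESurface:
    """Boltzmann-inverted free-energy surface on a 2D grid.

    ``energies`` holds NaN on unpopulated bins (``mask`` is True there);
    populated bins are shifted so the global minimum is exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    energies: np.ndarray
    mask: np.ndarray
    temperature: float
    units: str = "kT"
    reference_shift: float = 0.0
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        populated = self.energies[~self.mask]
        if populated.size and abs(populated.min()) > 1e-9:
            raise ValueError("populated minimum must be shifted to 0")

    @property
    def kT(self) -> float:
        """Thermal energy in kJ/mol at the surface's temperature."""
        return KB_KJ_PER_MOL_K * self.temperature

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class MinimaList:
    """Local FES minima sorted by depth (global minimum first, depth 0)."""

    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    bin_index: list[tuple[int, int]]
    requested: int
    truncated: bool = False  # True when fewer minima exist than requested

    def __len__(self) -> int:
        return len(self.depth)


def density2d(points: np.ndarray, bins: int | tuple[int, int] = 100,
              extent: tuple | None = None,
              bin_width: float | None = None,
              smoothing_sigma: float = 0.0) -> Density2D:
    """Histogram 2D projected points into a normalized density.

    ``extent`` is ``((xmin, xmax), (ymin, ymax))``; by default the point
    bounding box padded by 5%.  ``bin_width`` overrides ``bins`` with
    square bins of the given side (map units) — useful when the projection
    is strongly anisotropic and per-axis bin counts would slice basins
    thinner along one axis than the other.  Optional Gaussian smoothing
    (in bins) is applied to the histogram before normalization; default
    off.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("need at least one point")
    if points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if extent is None:
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        lo = lo - 0.05 * span
        hi = hi + 0.05 * span
        extent = ((lo[0], hi[0]), (lo[1], hi[1]))
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        bins = (max(1, math.ceil((extent[0][1] - extent[0][0]) / bin_width)),
                max(1, math.ceil((extent[1][1] - extent[1][0]) / bin_width)))
    hist, x_edges, y_edges = np.histogram2d(
        points[:, 0], points[:, 1], bins=bins, range=extent)
    if hist.sum() < len(points):
        raise ValueError("grid does not cover all points")
    if smoothing_sigma > 0:
        hist = ndimage.gaussian_filter(hist, smoothing_sigma)
    masses = hist / hist.sum()
    return Density2D(x_edges=x_edges, y_edges=y_edges, masses=masses,
                     n_samples=len(points))


def free_energy_surface(density: Density2D, temperature: float = 300.0,
                        units: str = "kT") -> FESurface:
    """Boltzmann inversion ``F = -kT ln p`` of a 2D density.

    ``units`` is ``"kT"`` or ``"kJ/mol"``; unpopulated bins are masked.
    The surface is shifted so the global populated minimum is 0 and the
    shift is recorded.
    """
    if units not in ("kT", "kJ/mol"):
        raise ValueError("units must be 'kT' or 'kJ/mol'")
    p = density.masses
    mask = p <= 0
    energies = np.full(p.shape, np.nan)
    with np.errstate(divide="ignore"):
        energies[~mask] = -np.log(p[~mask])
    if units == "kJ/mol":
        energies *= KB_KJ_PER_MOL_K * temperature
    shift = np.nanmin(energies[~mask])
    energies[~mask] -= shift
    return FESurface(x_edges=density.x_edges, y_edges=density.y_edges,
                     energies=energies, mask=mask, temperature=temperature,
                     units=units, reference_shift=float(shift),
                     counts=density.counts)


def find_minima(fes: FESurface, k: int, min_count: float = 2.0
                ) -> MinimaList:
    """The ``k`` lowest local minima of a free-energy surface.

    A populated bin is a local minimum when it is strictly lower than every
    populated 8-neighbor; a connected plateau of equal values lower than
    its whole populated surround counts once, at its centroid bin.  Bins
    holding fewer than ``min_count`` samples are treated as unpopulated to
    suppress single-sample noise minima.  If fewer than ``k`` minima exist,
    all are returned and the result is flagged truncated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = fes.mask.copy()
    if fes.counts is not None and min_count > 0:
        mask |= fes.counts < min_count
    if not np.any(~mask):
        raise ValueError("no populated bins")
    e = np.where(mask, np.inf, np.nan_to_num(fes.energies, nan=np.inf))

    # minimum over the 8 neighbors of each bin (inf beyond the grid /
    # on unpopulated bins)
    padded = np.pad(e, 1, constant_values=np.inf)
    neighbor_min = np.full(e.shape, np.inf)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            shifted = padded[1 + dx:1 + dx + e.shape[0],
                             1 + dy:1 + dy + e.shape[1]]
            neighbor_min = np.minimum(neighbor_min, shifted)

    # bins with no strictly-lower populated neighbor; adjacent bins inside
    # this set necessarily share the same energy (else the higher one would
    # have a lower neighbor), so connected components are flat plateaus
    ok = ~mask & (e <= neighbor_min)
    eight = np.ones((3, 3), dtype=int)
    labels, n_regions = ndimage.label(ok, structure=eight)
    candidates: list[tuple[float, tuple[int, int]]] = []
    for lab in range(1, n_regions + 1):
        region = labels == lab
        cells = np.argwhere(region)
        level = float(e[cells[0][0], cells[0][1]])
        # every populated bin on the region's rim must be strictly higher
        grown = ndimage.binary_dilation(region, structure=eight)
        ring = grown & ~region & ~mask
        if ring.any() and not np.all(e[ring] > level):
            continue
        cx, cy = cells.mean(axis=0)
        ci = cells[np.argmin(((cells - [cx, cy]) ** 2).sum(axis=1))]
        candidates.append((level, (int(ci[0]), int(ci[1]))))

    candidates.sort(key=lambda t: (t[0], t[1]))
    truncated = len(candidates) < k
    if truncated:
        warnings.warn(f"found {len(candidates)} minima, fewer than the "
                      f"requested {k}")
    chosen = candidates[:k]
    xs = np.array([fes.x_centers[i] for _, (i, _j) in chosen])
    ys = np.array([fes.y_centers[j] for _, (_i, j) in chosen])
    depths = np.array([lev for lev, _ in chosen])
    if len(depths):
        depths = depths - depths[0]
    return MinimaList(x=xs, y=ys, depth=depths,
                      bin_index=[b for _, b in chosen], requested=k,
                      truncated=truncated)


def select_basin_frames(fes: FESurface, projection: np.ndarray,
                        n_minima: int = 4, n_random: int = 10,
                        radius: float = np.inf, seed: int = 0,
                        min_count: float = 2.0
                        ) -> list[dict]:
    """Representative frame indices for the lowest free-energy basins.

    For each of the ``n_minima`` lowest minima: the frame projected nearest
    to the minimum, plus ``n_random`` distinct frames drawn uniformly
    (seeded) from frames within ``radius`` map units of it.  With the
    defaults (4, 10) this yields up to 44 frames, the selection used to
    seed backmapped atomistic simulations.
    """
    projection = np.atleast_2d(np.asarray(projection, dtype=float))
    minima = find_minima(fes, n_minima, min_count=min_count)
    rng = np.random.default_rng(seed)
    groups = []
    for m in range(len(minima)):
        center = np.array([minima.x[m], minima.y[m]])
        dist = np.linalg.norm(projection - center, axis=1)
        nearest = int(np.argmin(dist))
        pool = np.flatnonzero(dist <= radius)
        pool = pool[pool != nearest]
        if len(pool) == 0 and n_random > 0:
            warnings.warn(f"minimum {m}: no frames within radius {radius}; "
                          f"group contains only the nearest frame")
            sampled = np.empty(0, dtype=int)
        else:
            take = min(n_random, len(pool))
            sampled = rng.choice(pool, size=take, replace=False) \
                if take else np.empty(0, dtype=int)
        groups.append({
            "minimum": m,
            "center": center,
            "depth": float(minima.depth[m]),
            "nearest_frame": nearest,
            "random_frames": np.sort(sampled).astype(int),
        })
    return groups
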