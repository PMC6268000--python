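"""Quantitative comparison of 2D conformational landscapes.

Projected densities of different systems (e.g. differently linked ubiquitin
dimers) are compared by the Earth Mover Distance: the minimal cost of
transporting the probability mass of one histogram into the other, with the
Euclidean distance between bin centers as ground metric.  With a metric
ground distance the EMD is itself a metric, so the full pairwise matrix can
be embedded with classical multidimensional scaling to arrange systems by
conformational similarity.

The transport problem is solved exactly as a linear program over the
populated bins of both histograms (HiGHS); histograms with very large
supports are optionally coarsened by bin aggregation first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .landscape import Density2D
from .sketchmap import classical_mds

#: Refuse exact transport problems larger than this many flow variables
#: unless coarsening is allowed.
MAX_FLOW_VARIABLES = 4_000_000


@dataclass
class EMDMatrix:
    """Symmetric pairwise Earth-Mover-Distance matrix between systems."""

    labels: list[str]
    values: np.ndarray
    normalized: bool = False
    normalization_constant: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(self.values - self.values.T) > 1e-9):
            raise ValueError("matrix must be symmetric")


def coarsen_density(density: Density2D, factor: int) -> Density2D:
    """Aggregate ``factor x factor`` blocks of bins into one bin."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return density
    m = density.masses
    nx = math.ceil(m.shape[0] / factor) * factor
    ny = math.ceil(m.shape[1] / factor) * factor
    padded = np.zeros((nx, ny))
    padded[:m.shape[0], :m.shape[1]] = m
    coarse = padded.reshape(nx // factor, factor,
                            ny // factor, factor).sum(axis=(1, 3))
    dx = density.x_edges[1] - density.x_edges[0]
    dy = density.y_edges[1] - density.y_edges[0]
    x_edges = density.x_edges[0] + dx * factor * np.arange(nx // factor + 1)
    y_edges = density.y_edges[0] + dy * factor * np.arange(ny // factor + 1)
    return Density2D(x_edges=x_edges, y_edges=y_edges,
                     masses=coarse / coarse.sum(),
                     n_samples=density.n_samples)


def _transport_cost(src_pts: np.ndarray, src_mass: np.ndarray,
                    dst_pts: np.ndarray, dst_mass: np.ndarray) -> float:
    """Exact optimal-transport cost between weighted point sets."""
    m, n = len(src_mass), len(dst_mass)
    cost = cdist(src_pts, dst_pts).ravel()
    # flow conservation: rows for sources, columns for sinks; one redundant
    # equality dropped for numerical rank
    rows_src = np.repeat(np.arange(m), n)
    cols_src = np.arange(m * n)
    jj = np.arange(n - 1)
    rows_dst = np.repeat(m + jj, m)
    cols_dst = (jj[:, None] + n * np.arange(m)[None, :]).ravel()
    rows = np.concatenate([rows_src, rows_dst])
    cols = np.concatenate([cols_src, cols_dst])
    a_eq = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                             shape=(m + n - 1, m * n))
    b_eq = np.concatenate([src_mass, dst_mass[:-1]])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def emd2d(density_a: Density2D, density_b: Density2D,
          max_support: int | None = None) -> float:
    """Earth Mover Distance between two normalized 2D densities.

    Exact discrete optimal transport between the populated bins of the two
    histograms, Euclidean ground distance between bin centers, in map
    units.  The grids may differ but must share the coordinate system.
    ``max_support`` (populated bins per side) triggers bin aggregation for
    oversized inputs; the coarsening factor is reported in a warning.
    """
    for d in (density_a, density_b):
        if abs(d.masses.sum() - 1.0) > 1e-9:
            raise ValueError("densities must be normalized to total mass 1")
    pts_a, mass_a = density_a.support()
    pts_b, mass_b = density_b.support()
    if max_support is not None:
        for which, dens in (("first", density_a), ("second", density_b)):
            pts, _ = dens.support()
            if len(pts) > max_support:
                factor = math.ceil(math.sqrt(len(pts) / max_support))
                warnings.warn(f"coarsening {which} density by factor "
                              f"{factor} for the transport solve")
                coarse = coarsen_density(dens, factor)
                if which == "first":
                    pts_a, mass_a = coarse.support()
                else:
                    pts_b, mass_b = coarse.support()
    if len(mass_a) * len(mass_b) > MAX_FLOW_VARIABLES:
        raise ValueError(
            f"transport problem with {len(mass_a)}x{len(mass_b)} supports "
            f"is too large for an exact solve; pass max_support to coarsen")
    return _transport_cost(pts_a, mass_a, pts_b, mass_b)


def pairwise_emd(densities: list[Density2D],
                 labels: list[str] | None = None,
                 normalize: bool = False,
                 max_support: int | None = None) -> EMDMatrix:
    """All-pairs EMD matrix, optionally max-normalized.

    With ``normalize`` the matrix is divided by its largest off-diagonal
    entry, so the most dissimilar pair scores exactly 1.0; the constant is
    stored.  Normalization of an all-zero matrix is skipped with a warning.
    """
    if len(densities) < 2:
        raise ValueError("need at least 2 densities")
    if labels is None:
        labels = [f"system{i}" for i in range(len(densities))]
    n = len(densities)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = emd2d(
                densities[i], densities[j], max_support=max_support)
    const = 1.0
    normalized = False
    if normalize:
        vmax = values.max()
        if vmax <= 0:
            warnings.warn("all pairwise EMDs are zero; "
                          "normalization skipped")
        else:
            values = values / vmax
            # force the extremal pair to exactly 1.0 against roundoff
            values[values > 1.0] = 1.0
            const = float(vmax)
            normalized = True
    return EMDMatrix(labels=list(labels), values=values,
                     normalized=normalized, normalization_constant=const)


def arrange_by_similarity(matrix: EMDMatrix, seed: int = 0) -> np.ndarray:
    """2D arrangement of systems from their pairwise EMDs.

    Classical metric MDS of the distance matrix, centered at the origin,
    with a deterministic sign convention (the first system's coordinate is
    non-negative on each axis); ``seed`` is accepted for interface
    uniformity but the embedding is deterministic.
    """
    coords = classical_mds(matrix.values, k=2)
    coords = coords - coords.mean(axis=0)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        anchor = next((v for v in col if abs(v) > 1e-12), 1.0)
        if anchor < 0:
            coords[:, axis] = -col
    return coords
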