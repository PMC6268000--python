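"""Matplotlib helpers for landscapes, comparisons and ΔSASA profiles."""

from __future__ import annotations

import numpy as np

from .compare import EMDMatrix
from .landscape import FESurface, MinimaList
from .sasa import DeltaSASAProfile


def plot_fes(fes: FESurface, minima: MinimaList | None = None, ax=None,
             cmap: str = "viridis"):
    """Heatmap of a free-energy surface with optional minima markers."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    z = np.where(fes.mask, np.nan, fes.energies)
    im = ax.pcolormesh(fes.x_edges, fes.y_edges, z.T, cmap=cmap,
                       shading="auto")
    plt.colorbar(im, ax=ax, label=f"free energy ({fes.units})")
    if minima is not None and len(minima):
        ax.scatter(minima.x, minima.y, c="k", s=15, zorder=3)
        for x, y, d in zip(minima.x, minima.y, minima.depth):
            ax.annotate(f"{d:.2f}", (x, y), fontsize=7,
                        textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("sketch-map x")
    ax.set_ylabel("sketch-map y")
    return ax


def plot_similarity_arrangement(matrix: EMDMatrix, coords: np.ndarray,
                                ax=None):
    """Scatter of systems arranged by pairwise landscape EMD."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(coords[:, 0], coords[:, 1])
    for label, (x, y) in zip(matrix.labels, coords):
        ax.annotate(label, (x, y), textcoords="offset points",
                    xytext=(4, 4))
    ax.set_aspect("equal")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    return ax


def plot_dsasa(profile: DeltaSASAProfile, axes=None):
    """Residue-wise ΔSASA bars for the distal and proximal subunits."""
    import matplotlib.pyplot as plt
    if axes is None:
        _, axes = plt.subplots(1, 2, sharey=True, figsize=(10, 3))
    for ax, su in zip(axes, ("distal", "proximal")):
        ax.bar(profile.residues[su], profile.mean[su],
               yerr=profile.error[su], color="k", error_kw={"lw": 0.5})
        ax.set_title(su)
        ax.set_xlabel("residue")
    axes[0].set_ylabel(r"$\Delta$SASA (nm$^2$)")
    return axes
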