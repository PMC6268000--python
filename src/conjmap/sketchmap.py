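"""Sketch-map: landmark-based nonlinear multidimensional scaling.

Sketch-map embeds high-dimensional descriptors (here RMD vectors) in 2D by
matching *sigmoid-transformed* distances rather than raw ones: with

    F(r) = 1 - (1 + (2^{a/b} - 1) (r/sigma)^a)^{-b/a}

distances well below the switching distance ``sigma`` map near 0 and
distances well above it map near 1, so the optimization concentrates on the
intermediate range where conformational basins separate.  Different
exponent pairs are used in high dimension (``a_hd``, ``b_hd``) and in the
2D map (``a_ld``, ``b_ld``).  A subset of N landmarks is embedded by
minimizing the weighted stress

    chi^2 = sum_{i<j} w_i w_j [F_hd(R_ij) - F_ld(r_ij)]^2

starting from a classical (Torgerson) MDS configuration; every other point
is then placed out-of-sample at the 2D position best matching its
transformed distances to the landmarks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform


# ----------------------------------------------------------------------
# Sigmoid switching function

def sigmoid_transform(r, sigma: float, a: float, b: float):
    """The sketch-map switching function ``F(r)``, elementwise.

    Monotone from ``F(0) = 0`` to 1 as ``r -> inf``, with ``F(sigma) = 1/2``
    for any valid exponents.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if sigma <= 0 or a <= 0 or b <= 0:
        raise ValueError("sigma and both exponents must be positive")
    c = 2.0 ** (a / b) - 1.0
    return 1.0 - (1.0 + c * (r / sigma) ** a) ** (-b / a)


def sigmoid_gradient(r, sigma: float, a: float, b: float):
    """d F / d r, elementwise (used by the stress optimizer)."""
    r = np.asarray(r, dtype=float)
    c = 2.0 ** (a / b) - 1.0
    u = c * (r / sigma) ** a
    with np.errstate(divide="ignore", invalid="ignore"):
        dudr = c * a * r ** (a - 1.0) / sigma ** a
    if a < 1:  # derivative diverges at 0 for a<1; clamp for the optimizer
        dudr = np.where(r == 0, 0.0, dudr)
    return (b / a) * (1.0 + u) ** (-b / a - 1.0) * dudr


def invert_sigmoid(f: float, sigma: float, a: float, b: float) -> float:
    """Distance ``r`` with ``F(r) = f`` (closed-form inverse, 0 <= f < 1)."""
    if not 0 <= f < 1:
        raise ValueError("f must be in [0, 1)")
    c = 2.0 ** (a / b) - 1.0
    return sigma * (((1.0 - f) ** (-a / b) - 1.0) / c) ** (1.0 / a)


@dataclass
class SigmoidParams:
    """Sigmoid parameters for the high-dimensional and map-space transforms.

    Defaults are tuned for RMD vectors of two-domain ubiquitin conjugates
    (switching distance on the nm scale of raw RMDs).
    """

    sigma: float = 5.9
    a_hd: float = 12.0
    b_hd: float = 4.0
    a_ld: float = 2.0
    b_ld: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name in ("a_hd", "b_hd", "a_ld", "b_ld"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def hd(self, r):
        return sigmoid_transform(r, self.sigma, self.a_hd, self.b_hd)

    def ld(self, r):
        return sigmoid_transform(r, self.sigma, self.a_ld, self.b_ld)

    def ld_grad(self, r):
        return sigmoid_gradient(r, self.sigma, self.a_ld, self.b_ld)


# ----------------------------------------------------------------------
# Landmark selection

@dataclass
class LandmarkSet:
    """Landmark rows selected from a descriptor matrix.

    ``weights[i]`` counts the input rows whose nearest landmark is ``i``
    (including the landmark itself), so weights sum to the number of rows.
    """

    indices: np.ndarray
    vectors: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("landmark indices must be unique")

    @property
    def n(self) -> int:
        return len(self.indices)


def _chunked_min_dist(vectors: np.ndarray, targets: np.ndarray,
                      chunk: int = 4096) -> np.ndarray:
    out = np.empty(len(vectors))
    for s in range(0, len(vectors), chunk):
        out[s:s + chunk] = cdist(vectors[s:s + chunk], targets).min(axis=1)
    return out


def select_landmarks(vectors: np.ndarray, n: int, gamma: float = 0.1,
                     seed: int = 0) -> LandmarkSet:
    """Mixed random / farthest-point (minmax) landmark selection.

    ``ceil(gamma * n)`` landmarks are drawn uniformly at random (seeded);
    the remainder are added greedily, each maximizing its minimum
    high-dimensional Euclidean distance to the landmarks chosen so far.
    With ``gamma = 0`` the selection is purely farthest-point, started from
    the globally most distant pair of rows.
    """
    vectors = np.asarray(vectors, dtype=float)
    rows = len(vectors)
    if not 1 <= n <= rows:
        raise ValueError(f"need 1 <= n <= {rows}, got {n}")
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if gamma > 0:
        n_random = min(n, max(1, math.ceil(gamma * n)))
        chosen = list(rng.choice(rows, size=n_random, replace=False))
    else:
        # start from the most distant pair so the extremes are landmarks
        if n == 1:
            chosen = [0]
        else:
            d = squareform(pdist(vectors)) if rows <= 4096 else None
            if d is not None:
                i, j = np.unravel_index(np.argmax(d), d.shape)
            else:  # two-pass approximation refuses nothing at this scale
                far = np.argmax(_chunked_min_dist(vectors, vectors[:1]))
                i = int(far)
                j = int(np.argmax(
                    _chunked_min_dist(vectors, vectors[i:i + 1])))
            chosen = [int(i), int(j)]
    chosen = chosen[:n]
    if len(chosen) < n:
        dmin = _chunked_min_dist(vectors, vectors[chosen])
        dmin[chosen] = -1.0  # never re-pick a chosen row (ties at 0)
        while len(chosen) < n:
            cand = int(np.argmax(dmin))
            chosen.append(cand)
            np.minimum(dmin,
                       np.linalg.norm(vectors - vectors[cand], axis=1),
                       out=dmin)
            dmin[cand] = -1.0
    idx = np.asarray(chosen[:n], dtype=int)
    # weights: multiplicity of input rows by nearest landmark
    weights = np.zeros(n)
    for s in range(0, rows, 4096):
        nearest = cdist(vectors[s:s + 4096], vectors[idx]).argmin(axis=1)
        np.add.at(weights, nearest, 1.0)
    return LandmarkSet(indices=idx, vectors=vectors[idx], weights=weights)


# ----------------------------------------------------------------------
# Stress and fitting

def classical_mds(dissimilarity: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson scaling: embed a dissimilarity matrix in ``k`` dimensions."""
    d2 = np.asarray(dissimilarity, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress_and_grad(x_flat: np.ndarray, fhd: np.ndarray, wprod: np.ndarray,
                     params: SigmoidParams, n: int
                     ) -> tuple[float, np.ndarray]:
    x = x_flat.reshape(n, 2)
    diff = x[:, None, :] - x[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iu = np.triu_indices(n, k=1)
    fld = params.ld(r[iu])
    resid = fld - fhd
    stress = float(np.sum(wprod * resid ** 2))
    # gradient
    coef = np.zeros((n, n))
    rr = r[iu]
    g = params.ld_grad(rr)
    safe = np.where(rr > 0, rr, 1.0)
    c = 2.0 * wprod * resid * g / safe
    coef[iu] = c
    coef += coef.T
    grad = (coef[:, :, None] * diff).sum(axis=1)
    return stress, grad.ravel()


@dataclass
class SketchMapModel:
    """A fitted sketch-map: landmark positions plus the sigmoid transforms.

    Produced by :func:`fit_sketchmap`; carries the final stress, whether the
    optimizer converged, and a per-iteration stress log.  Out-of-sample
    points are placed with :func:`project`.
    """

    params: SigmoidParams
    landmarks: LandmarkSet
    coordinates: np.ndarray
    stress: float
    converged: bool
    iteration_log: list = field(default_factory=list)
    use_weights: bool = True

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.landmarks.n, 2):
            raise ValueError("need one 2D coordinate per landmark")
        if self.stress < 0:
            raise ValueError("stress must be >= 0")

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        payload = {
            "params": vars(self.params),
            "landmark_indices": self.landmarks.indices.tolist(),
            "landmark_vectors": self.landmarks.vectors.tolist(),
            "landmark_weights": self.landmarks.weights.tolist(),
            "coordinates": self.coordinates.tolist(),
            "stress": self.stress,
            "converged": self.converged,
            "iteration_log": list(self.iteration_log),
            "use_weights": self.use_weights,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SketchMapModel":
        d = json.loads(Path(path).read_text())
        return cls(
            params=SigmoidParams(**d["params"]),
            landmarks=LandmarkSet(
                indices=np.asarray(d["landmark_indices"]),
                vectors=np.asarray(d["landmark_vectors"]),
                weights=np.asarray(d["landmark_weights"])),
            coordinates=np.asarray(d["coordinates"]),
            stress=float(d["stress"]),
            converged=bool(d["converged"]),
            iteration_log=list(d["iteration_log"]),
            use_weights=bool(d.get("use_weights", True)),
        )

    def project(self, vectors: np.ndarray, **kwargs) -> np.ndarray:
        return project(vectors, self, **kwargs)


def landmark_stress(coords: np.ndarray, landmarks: LandmarkSet,
                    params: SigmoidParams, use_weights: bool = True) -> float:
    """Weighted sketch-map stress of a landmark configuration."""
    n = landmarks.n
    iu = np.triu_indices(n, k=1)
    fhd = params.hd(pdist(landmarks.vectors))
    w = landmarks.weights if use_weights else np.ones(n)
    wprod = (w[:, None] * w[None, :])[iu]
    fld = params.ld(pdist(np.asarray(coords, dtype=float)))
    return float(np.sum(wprod * (fld - fhd) ** 2))


def fit_sketchmap(landmarks: LandmarkSet,
                  params: SigmoidParams | None = None,
                  seed: int = 0,
                  max_iter: int = 1000,
                  tol: float = 1e-6,
                  n_restarts: int = 0,
                  use_weights: bool = True) -> SketchMapModel:
    """Embed landmarks in 2D by minimizing the sketch-map stress.

    The optimization starts from classical MDS of the F_hd-transformed
    distances (plus ``n_restarts`` seeded perturbations of it, keeping the
    best) and uses L-BFGS with the analytic stress gradient.  On hitting
    ``max_iter`` the best configuration so far is returned with
    ``converged=False`` rather than raising.
    """
    if params is None:
        params = SigmoidParams()
    n = landmarks.n
    if n < 3:
        raise ValueError("need at least 3 landmarks to fit a map")
    fhd_mat = params.hd(squareform(pdist(landmarks.vectors)))
    iu = np.triu_indices(n, k=1)
    fhd = fhd_mat[iu]
    w = landmarks.weights if use_weights else np.ones(n)
    wprod = (w[:, None] * w[None, :])[iu]

    x0 = classical_mds(fhd_mat)
    # map F-space MDS lengths onto the map-distance scale: F_ld spans its
    # dynamic range around sigma, so rescale the init to that scale
    spread = np.max(pdist(x0)) if n > 1 else 1.0
    if spread > 0:
        x0 = x0 * (params.sigma / spread) * 2.0

    rng = np.random.default_rng(seed)
    inits = [x0]
    for _ in range(n_restarts):
        inits.append(x0 + rng.normal(scale=0.1 * params.sigma,
                                     size=x0.shape))

    best = None
    log: list[float] = []
    for x_init in inits:
        this_log: list[float] = []

        def cb(xk):
            s, _ = _stress_and_grad(xk, fhd, wprod, params, n)
            this_log.append(s)

        res = minimize(_stress_and_grad, x_init.ravel(), jac=True,
                       args=(fhd, wprod, params, n), method="L-BFGS-B",
                       callback=cb,
                       options={"maxiter": max_iter, "ftol": tol,
                                "gtol": 1e-12})
        if best is None or res.fun < best[0]:
            init_stress = _stress_and_grad(
                x_init.ravel(), fhd, wprod, params, n)[0]
            took_init = res.fun <= init_stress
            best = (res.fun, res.x.reshape(n, 2),
                    bool(res.success) and took_init,
                    x_init, init_stress)
            log = this_log
    stress, coords, converged, x_init, init_stress = best
    if stress > init_stress:  # optimizer diverged; keep the init
        coords, stress = x_init, init_stress
        converged = False
    return SketchMapModel(params=params, landmarks=landmarks,
                          coordinates=coords, stress=float(stress),
                          converged=converged, iteration_log=log,
                          use_weights=use_weights)


# ----------------------------------------------------------------------
# Out-of-sample projection

def _placement_objective(xy: np.ndarray, fhd_x: np.ndarray,
                         model: SketchMapModel, w: np.ndarray) -> np.ndarray:
    """Objective for candidate positions ``xy`` (m, 2) against one or many
    transformed landmark-distance rows ``fhd_x`` (m, N)."""
    r = cdist(xy, model.coordinates)
    fld = model.params.ld(r)
    return np.sum(w * (fld - fhd_x) ** 2, axis=1)


def project(vectors: np.ndarray, model: SketchMapModel,
            grid_fraction: float = 0.01,
            polish_iters: int = 150,
            chunk: int = 20000) -> np.ndarray:
    """Place points on a fitted map (deterministic out-of-sample embedding).

    Each point goes to the 2D position minimizing the weighted mismatch
    between its F_hd-transformed distances to the landmarks and the
    F_ld-transformed map distances.  A grid scan over the padded landmark
    bounding box (spacing = ``grid_fraction`` of the box diagonal) supplies
    the starting position; vectorized gradient descent with per-point
    backtracking polishes it.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != model.landmarks.vectors.shape[1]:
        raise ValueError(
            f"input dimension {vectors.shape[1]} does not match landmark "
            f"dimension {model.landmarks.vectors.shape[1]}")
    # duplicate rows place identically; solve unique rows once
    unique, inverse = np.unique(vectors, axis=0, return_inverse=True)
    if len(unique) < len(vectors):
        placed = project(unique, model, grid_fraction=grid_fraction,
                         polish_iters=polish_iters, chunk=chunk)
        return placed[inverse]
    w = (model.landmarks.weights if model.use_weights
         else np.ones(model.landmarks.n))

    lo = model.coordinates.min(axis=0)
    hi = model.coordinates.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo -= 0.1 * span
    hi += 0.1 * span
    n_grid = int(np.clip(round(1.0 / grid_fraction), 8, 200))
    gx = np.linspace(lo[0], hi[0], n_grid)
    gy = np.linspace(lo[1], hi[1], n_grid)
    grid = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1
                    ).reshape(-1, 2)
    fld_grid = model.params.ld(cdist(grid, model.coordinates))  # (G, N)
    wf = fld_grid * w  # (G, N)
    g_const = np.sum(w * fld_grid ** 2, axis=1)  # (G,)

    out = np.empty((len(vectors), 2))
    for s in range(0, len(vectors), chunk):
        block = vectors[s:s + chunk]
        fhd = model.params.hd(cdist(block, model.landmarks.vectors))
        # cost(x, g) = const_x - 2 fhd W fld^T + g_const
        cross = fhd @ wf.T  # (m, G)
        best_g = np.argmin(g_const[None, :] - 2.0 * cross, axis=1)
        xy = grid[best_g].copy()
        obj = _placement_objective(xy, fhd, model, w)
        step = np.full(len(block), 0.1 * span.max())
        for _ in range(polish_iters):
            r = cdist(xy, model.coordinates)
            fld = model.params.ld(r)
            gld = model.params.ld_grad(r)
            resid = fld - fhd
            safe = np.where(r > 0, r, 1.0)
            coef = 2.0 * w * resid * gld / safe  # (m, N)
            diff = xy[:, None, :] - model.coordinates[None, :, :]
            grad = np.einsum("mn,mnk->mk", coef, diff)
            gnorm = np.linalg.norm(grad, axis=1)
            direction = -grad / np.where(gnorm > 0, gnorm, 1.0)[:, None]
            trial = xy + step[:, None] * direction
            trial_obj = _placement_objective(trial, fhd, model, w)
            improved = trial_obj < obj
            xy[improved] = trial[improved]
            obj[improved] = trial_obj[improved]
            step = np.where(improved, step * 1.2, step * 0.5)
            if np.all(step < 1e-10):
                break
        out[s:s + len(block)] = xy
    return out
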