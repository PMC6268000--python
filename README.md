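# conjmap

Ensemble characterization of covalently linked two-domain protein
conjugates — built for ubiquitin dimers (diUb), applicable to any
two-subunit conjugate.

Multi-microsecond coarse-grained simulations of the eight natively linked
ubiquitin dimers sample a rich conformational ensemble whose structure —
how many basins, how deep, how similar across linkage types, and which
surface patches each basin buries — is what distinguishes one linkage from
another. `conjmap` implements the analysis chain that turns such
trajectories (or synthetic stand-ins) into comparable free-energy
landscapes and interface statistics:

1. **Residue-wise minimum distances (RMDs).** A frame of a conjugate with
   72 analysis residues per subunit is described by a 144-vector: for each
   backbone site (Cα atom or CG backbone bead) of the distal subunit, the
   minimum distance to the proximal backbone sites, and vice versa. RMDs
   are internal coordinates — invariant under rigid-body motion and
   identical between atomistic and coarse-grained representations.
2. **Sketch-map.** Landmark-based nonlinear MDS. Distances are passed
   through the sigmoid F(r) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a} with
   separate exponents in high dimension (A, B) and in the map (a, b)
   (defaults σ = 5.9, A = 12, B = 4, a = 2, b = 4), and N landmark points
   (selected by a seeded random + farthest-point "minmax" scheme with
   mixing fraction γ) are embedded in 2D by minimizing the weighted stress
   χ² = Σ_{i<j} w_i w_j [F_hd(R_ij) − F_ld(r_ij)]². All other frames are
   placed out-of-sample against the fitted landmarks.
3. **Free-energy landscapes.** Projected densities p are Boltzmann-inverted,
   F = −kT ln p, the k lowest local minima located, and representative
   frames selected around each basin (the lowest four minima plus ten
   random neighbors each is the conventional selection for backmapping to
   atomistic resolution).
4. **Landscape comparison.** Exact Earth Mover Distance (discrete optimal
   transport, Euclidean ground metric between bin centers) between the 2D
   densities of different systems; after max-normalization the most
   dissimilar pair scores 1.0. Classical MDS arranges the systems in 2D by
   similarity.
5. **Interface SASA.** Shrake–Rupley solvent-accessible surface areas give
   the buried interface area SA_interface = SASA_distal + SASA_proximal −
   SASA_conjugate, partitioned exactly into apolar (a-SA) and polar (p-SA)
   contributions; accessibility of the classical Ub patches (Ile44, Ile36,
   Phe4, TEK box); and the residue-wise mean SASA loss ΔSASA with error
   bars over independent runs.

A synthetic-ensemble generator (`conjmap.synthetic`) produces rigid-body
two-domain ensembles with prescribed basins, occupancies and noise, so the
whole chain is testable end-to-end with known ground truth and no MD data.

## Worked example

```python
import math
import numpy as np
from conjmap import (ConjugateTrajectory, two_domain_ensemble, rmd_series,
                     select_landmarks, fit_sketchmap, density2d,
                     free_energy_surface, find_minima, pairwise_emd,
                     interface_report)

# two synthetic diUb-like systems with mirrored basin occupancies
trajA, labelsA, _ = two_domain_ensemble(4000, [0.7, 0.3], seed=1)
trajB, labelsB, _ = two_domain_ensemble(4000, [0.3, 0.7], seed=2)

rmdA = rmd_series(trajA)           # (4000, 144) descriptor matrix
rmdB = rmd_series(trajB)
print("RMD matrix:", rmdA.shape)

pooled = np.vstack([rmdA, rmdB])   # one shared map for both systems
landmarks = select_landmarks(pooled, 150, gamma=0.1, seed=3)
model = fit_sketchmap(landmarks, seed=4)   # sigma=5.9, A=12, B=4, a=2, b=4
print(f"sketch-map stress: {model.stress:.1f} (converged={model.converged})")

projA = model.project(rmdA)
projB = model.project(rmdB)
lo = np.vstack([projA, projB]).min(axis=0)
hi = np.vstack([projA, projB]).max(axis=0)
extent = ((lo[0], hi[0]), (lo[1], hi[1]))
span = hi[0] - lo[0]

densA = density2d(projA, bin_width=span / 10, extent=extent)
densB = density2d(projB, bin_width=span / 10, extent=extent)
fesA = free_energy_surface(densA, temperature=300.0)
minima = find_minima(fesA, 2)
print("system A minima depths (kT):", np.round(minima.depth, 3))
print("expected ln(0.7/0.3)       :", round(math.log(7 / 3), 3))

emd = pairwise_emd([densA, densB], ["A", "B"], normalize=True)
print("normalized EMD matrix:\n", emd.values)

short = ConjugateTrajectory(trajA.topology, trajA.frames[:20])
sasa = interface_report(short)
print("mean interface area (nm^2):", round(sasa.mean["sa_interface"], 2),
      "apolar:", round(sasa.mean["a_sa"], 2),
      "polar:", round(sasa.mean["p_sa"], 2))
```

Output:

```
RMD matrix: (4000, 144)
sketch-map stress: 208.6 (converged=True)
system A minima depths (kT): [0.    0.879]
expected ln(0.7/0.3)       : 0.847
normalized EMD matrix:
 [[0. 1.]
 [1. 0.]]
mean interface area (nm^2): 1.36 apolar: 0.65 polar: 0.72
```

The two free-energy minima of system A differ by ≈ ln(0.7/0.3) kT, the
Boltzmann-inverted signature of its 70/30 basin occupancies; the two
systems, having different occupancies, are maximally dissimilar in the
2-system normalized EMD matrix; and roughly half of the ~1.4 nm² buried
interface is apolar in this toy conjugate.

The same stages are available as a CLI (`conjmap synth / rmd /
sketchmap fit / sketchmap project / landscape / compare / interface /
dsasa / extract / run`); `conjmap run --config config.yaml` drives the
whole chain for a declarative list of systems.

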