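"""SASA tests: closed-form sphere geometry oracles, interface partition,
patch accessibility and ΔSASA accounting."""

import numpy as np
import pytest

from conjmap.core import ConjugateFrame, ConjugateTopology, \
    ConjugateTrajectory
from conjmap.sasa import (PatchDefinition, delta_sasa_profile,
                          fibonacci_sphere, interface_area, interface_report,
                          patch_accessibility, sasa_per_residue,
                          shrake_rupley)
from conjmap.synthetic import (default_basin_specs, make_conjugate_topology,
                               SyntheticEnsembleSpec,
                               sample_conjugate_ensemble)

from conftest import make_frame

PROBE = 0.14


def two_sphere_accessible_area(r1, r2, d, probe):
    """Analytic accessible area of two overlapping probe-inflated spheres.

    Spherical-cap geometry: sphere i of inflated radius Ri loses a cap of
    height hi = Ri - (d^2 + Ri^2 - Rj^2) / (2 d), area 2 pi Ri hi.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1 ** 2 + R2 ** 2)
    total = 0.0
    for Ra, Rb in ((R1, R2), (R2, R1)):
        if d + Ra <= Rb:
            cap = 4 * np.pi * Ra ** 2  # fully engulfed
        else:
            h = Ra - (d ** 2 + Ra ** 2 - Rb ** 2) / (2 * d)
            cap = 2 * np.pi * Ra * max(h, 0.0)
        total += 4 * np.pi * Ra ** 2 - cap
    return total


class TestShrakeRupley:
    def test_single_sphere_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([0.23]),
                             probe_radius=PROBE, n_points=960)
        expected = 4 * np.pi * (0.23 + PROBE) ** 2
        assert area[0] == pytest.approx(expected, rel=1e-12)

    def test_far_spheres_are_additive(self):
        coords = np.array([[0, 0, 0], [10.0, 0, 0]])
        radii = np.array([0.2, 0.3])
        areas = shrake_rupley(coords, radii, probe_radius=PROBE)
        for a, r in zip(areas, radii):
            assert a == pytest.approx(4 * np.pi * (r + PROBE) ** 2,
                                      rel=1e-12)

    @pytest.mark.parametrize("d", [0.3, 0.45, 0.6])
    def test_two_overlapping_spheres_match_cap_geometry(self, d):
        coords = np.array([[0, 0, 0], [d, 0, 0]])
        radii = np.array([0.23, 0.20])
        got = shrake_rupley(coords, radii, probe_radius=PROBE,
                            n_points=960).sum()
        expected = two_sphere_accessible_area(0.23, 0.20, d, PROBE)
        assert got == pytest.approx(expected, rel=0.01)

    def test_area_scales_quadratically(self, rng):
        coords = rng.normal(scale=0.5, size=(10, 3))
        radii = np.full(10, 0.2)
        a1 = shrake_rupley(coords, radii, probe_radius=PROBE).sum()
        lam = 2.0
        a2 = shrake_rupley(coords * lam, radii * lam,
                           probe_radius=PROBE * lam).sum()
        assert a2 == pytest.approx(lam ** 2 * a1, rel=1e-9)

    def test_missing_radius_named(self):
        with pytest.raises(ValueError, match="1"):
            shrake_rupley(np.zeros((2, 3)), np.array([0.2, np.nan]))

    def test_fibonacci_points_are_unit_and_deterministic(self):
        pts = fibonacci_sphere(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(500))


@pytest.fixture(scope="module")
def contact_system():
    """Two 8-residue subunits in contact (one basin, no noise)."""
    basins = default_basin_specs(1, n_residues=8, noise_sd=0.0)
    spec = SyntheticEnsembleSpec(n_residues=8, basins=basins, n_frames=1,
                                 seed=0)
    traj, _ = sample_conjugate_ensemble(spec)
    return traj


class TestInterface:
    def test_separated_subunits_have_zero_interface(self):
        topology = make_conjugate_topology(4)
        coords = np.zeros((8, 3))
        coords[:4] = np.arange(4)[:, None] * [0.4, 0, 0]
        coords[4:] = np.arange(4)[:, None] * [0.4, 0, 0] + [0, 0, 8.0]
        sa, a_sa, p_sa = interface_area(make_frame(coords), topology)
        assert sa == 0.0 and a_sa == 0.0 and p_sa == 0.0

    def test_polarity_split_partitions_interface_exactly(self, contact_system):
        frame = contact_system.frames[0]
        sa, a_sa, p_sa = interface_area(frame, contact_system.topology)
        assert sa > 0
        assert a_sa + p_sa == pytest.approx(sa, abs=1e-9)

    def test_invariant_under_subunit_label_swap(self, contact_system):
        frame = contact_system.frames[0]
        sa1 = interface_area(frame, contact_system.topology)
        sa2 = interface_area(frame, contact_system.topology.swap_subunits())
        assert sa1[0] == pytest.approx(sa2[0], abs=1e-9)
        assert sa1[1] == pytest.approx(sa2[1], abs=1e-9)

    def test_eq1_equals_per_particle_burial_sum(self):
        """Two routes to the buried area agree: subunit-SASA difference
        (Eq-1 style) vs summed per-particle burial."""
        topology = make_conjugate_topology(3)
        rng = np.random.default_rng(5)
        coords = np.vstack([rng.normal(scale=0.3, size=(3, 3)),
                            rng.normal(scale=0.3, size=(3, 3)) + 0.5])
        frame = make_frame(coords)
        sa, _, _ = interface_area(frame, topology)
        full = shrake_rupley(coords, topology.radius, PROBE, 960)
        iso_d = shrake_rupley(coords[:3], topology.radius[:3], PROBE, 960)
        iso_p = shrake_rupley(coords[3:], topology.radius[3:], PROBE, 960)
        eq1 = iso_d.sum() + iso_p.sum() - full.sum()
        assert sa == pytest.approx(eq1, abs=1e-9)

    def test_report_statistics(self, contact_system):
        rep = interface_report(contact_system)
        assert rep.mean["sa_interface"] == pytest.approx(
            rep.a_sa.mean() + rep.p_sa.mean(), abs=1e-9)


class TestPerResidue:
    def test_per_residue_sums_member_particles(self, contact_system):
        res = sasa_per_residue(contact_system.frames[0],
                               contact_system.topology)
        resids, vals = res.per_residue("distal")
        assert len(resids) == 8
        assert vals.sum() == pytest.approx(
            res.per_particle[contact_system.topology.particles_of(
                "distal")].sum(), abs=1e-12)
        assert np.all(res.per_particle >= 0)


class TestPatches:
    def test_far_apart_fraction_one(self):
        topology = make_conjugate_topology(8)
        chain = np.arange(8)[:, None] * [0.38, 0, 0]
        coords = np.vstack([chain, chain + [0, 0, 10.0]])
        traj = ConjugateTrajectory.from_coordinates(topology, coords)
        patches = [PatchDefinition("toy", [2, 4])]
        acc = patch_accessibility(traj, patches)
        assert acc["toy"]["distal"] == pytest.approx(1.0, abs=1e-9)
        assert acc["toy"]["proximal"] == pytest.approx(1.0, abs=1e-9)

    def test_buried_patch_fraction_near_zero(self):
        """A single-residue patch fully sandwiched by the partner."""
        topology = make_conjugate_topology(1)
        # proximal particle right on top of the distal one
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0.05]])
        traj = ConjugateTrajectory.from_coordinates(topology, coords)
        acc = patch_accessibility(traj, [PatchDefinition("p", [1])])
        assert acc["p"]["distal"] < 0.6

    def test_half_time_buried_patch_fraction_near_half(self):
        """Burial schedule oracle: patch covered in half of the frames."""
        topology = make_conjugate_topology(1)
        covered = np.array([[0.0, 0, 0], [0.0, 0, 0.05]])
        free = np.array([[0.0, 0, 0], [0.0, 0, 10.0]])
        frames = np.stack([covered, free] * 5)
        traj = ConjugateTrajectory.from_coordinates(topology, frames)
        acc = patch_accessibility(traj, [PatchDefinition("p", [1])])
        half_buried = patch_accessibility(
            ConjugateTrajectory.from_coordinates(topology, covered),
            [PatchDefinition("p", [1])])["p"]["distal"]
        expected = 0.5 * (1.0 + half_buried)
        assert acc["p"]["distal"] == pytest.approx(expected, abs=1e-9)

    def test_zero_reference_rejected(self, contact_system):
        ref = {"distal": {int(r): 0.0 for r in range(1, 9)},
               "proximal": {int(r): 1.0 for r in range(1, 9)}}
        with pytest.raises(ValueError, match="zero"):
            patch_accessibility(contact_system,
                                [PatchDefinition("p", [1])],
                                monomer_reference=ref)


class TestDeltaSASA:
    def test_far_separated_all_zero(self):
        topology = make_conjugate_topology(4)
        chain = np.arange(4)[:, None] * [0.38, 0, 0]
        coords = np.vstack([chain, chain + [0, 0, 12.0]])
        traj = ConjugateTrajectory.from_coordinates(topology, coords)
        prof = delta_sasa_profile([traj])
        np.testing.assert_allclose(prof.mean["distal"], 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.mean["proximal"], 0.0, atol=1e-12)

    def test_sums_to_interface_area(self, contact_system):
        """Accounting identity: sum of per-residue ΔSASA over both
        subunits equals SA_interface of the same frame."""
        prof = delta_sasa_profile([contact_system])
        sa, _, _ = interface_area(contact_system.frames[0],
                                  contact_system.topology)
        total = prof.mean["distal"].sum() + prof.mean["proximal"].sum()
        assert total == pytest.approx(sa, abs=1e-9)

    def test_nonnegative_per_residue(self, contact_system):
        prof = delta_sasa_profile([contact_system])
        assert np.all(prof.mean["distal"] >= 0)
        assert np.all(prof.mean["proximal"] >= 0)

    def test_identical_runs_have_zero_error_bars(self, contact_system):
        prof = delta_sasa_profile([contact_system] * 12)
        assert prof.n_runs == 12
        np.testing.assert_allclose(prof.error["distal"], 0.0, atol=1e-15)
        np.testing.assert_allclose(prof.error["proximal"], 0.0, atol=1e-15)

    def test_inconsistent_residue_sets_rejected(self, contact_system):
        basins = default_basin_specs(1, n_residues=5, noise_sd=0.0)
        other, _ = sample_conjugate_ensemble(
            SyntheticEnsembleSpec(n_residues=5, basins=basins, n_frames=1,
                                  seed=0))
        with pytest.raises(ValueError, match="inconsistent"):
            delta_sasa_profile([contact_system, other])
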