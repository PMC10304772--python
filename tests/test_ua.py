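"""Core energy model: rotations, energy terms, profiles, heatmaps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from uacorona.synthetic import (SyntheticPMFSpec, SyntheticProteinSpec,
                                make_pmf, make_protein)
from uacorona.types import (AdsorptionHeatmap, BeadProtein, SurfacePMFSet,
                            SolutionConditions, SurfaceSpec)
from uacorona import ua

angles = st.floats(-720, 720, allow_nan=False)


def bead_protein(positions, residues=None, charges=None, radii=None,
                 name="p"):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    residues = residues or ["GLY"] * n
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    radii = np.full(n, 0.5) if radii is None else np.asarray(radii, float)
    return BeadProtein(name=name, residues=residues, positions=positions,
                       charges=charges, radii=radii)


class TestOrient:
    def test_zero_angles_identity(self, toy_protein):
        np.testing.assert_array_equal(ua.orient(toy_protein, 0.0, 0.0),
                                      toy_protein.positions)

    def test_half_turn_twice_is_identity(self, toy_protein):
        once = ua.orient(toy_protein, 180.0, 0.0)
        rot = BeadProtein(name="r", residues=toy_protein.residues,
                          positions=once, charges=toy_protein.charges,
                          radii=toy_protein.radii)
        np.testing.assert_allclose(ua.orient(rot, 180.0, 0.0),
                                   toy_protein.positions, atol=1e-12)

    @given(theta=angles, phi=angles)
    @settings(max_examples=30, deadline=None)
    def test_rigid_rotation_preserves_distances(self, theta, phi):
        rng = np.random.default_rng(5)
        prot = bead_protein(rng.normal(size=(6, 3)))
        rotated = ua.orient(prot, theta, phi)
        d0 = np.linalg.norm(prot.positions[:, None] - prot.positions[None, :],
                            axis=-1)
        d1 = np.linalg.norm(rotated[:, None] - rotated[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)
        R = ua.rotation_matrix(theta, phi)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_rotation_maps_direction_to_z(self):
        R = ua.rotation_matrix(37.0, 122.0)
        n = ua.direction_from_angles(37.0, 122.0)
        np.testing.assert_allclose(R @ n, [0, 0, 1], atol=1e-12)


class TestElectrostatics:
    def test_uncharged_is_zero(self, conditions):
        surf = SurfaceSpec(geometry="flat", zeta_potential=-25.0,
                           conditions=conditions)
        assert ua.electrostatic_energy(np.array([[0, 0, 1.0]]),
                                       np.array([0.0]), surf) == 0.0

    def test_bjerrum_length_definition(self):
        """Unit charges one Bjerrum length apart, unscreened: exactly
        -1 kBT for opposite signs."""
        cond = SolutionConditions(ionic_strength=0.0)
        lb = cond.bjerrum_length
        surf = SurfaceSpec(
            geometry="flat",
            surface_charges=(np.array([[0.0, 0.0, 0.0]]), np.array([-1.0])),
            conditions=cond)
        e = ua.electrostatic_energy(np.array([[0.0, 0.0, lb]]),
                                    np.array([+1.0]), surf)
        assert e == pytest.approx(-1.0, rel=1e-12)

    def test_brute_force_oracle(self, conditions):
        """3 beads vs 4 discrete surface charges match an explicit
        double-loop screened-Coulomb sum to 1e-9 relative."""
        rng = np.random.default_rng(11)
        beads = rng.uniform(0.5, 2.0, size=(3, 3))
        qi = np.array([1.0, -2.0, 0.5])
        spos = rng.uniform(-1.0, 1.0, size=(4, 3))
        spos[:, 2] = 0.0
        qj = np.array([-1.0, 1.0, 2.0, -0.5])
        surf = SurfaceSpec(geometry="flat", surface_charges=(spos, qj),
                           conditions=conditions)
        got = ua.electrostatic_energy(beads, qi, surf)
        lb, kappa = conditions.bjerrum_length, conditions.debye_kappa
        expected = 0.0
        for i in range(3):
            for j in range(4):
                r = math.dist(beads[i], spos[j])
                expected += lb * qi[i] * qj[j] * math.exp(-kappa * r) / r
        assert got == pytest.approx(expected, rel=1e-9)

    def test_coincident_charge_raises(self, conditions):
        surf = SurfaceSpec(geometry="flat",
                           surface_charges=(np.zeros((1, 3)), np.array([1.0])),
                           conditions=conditions)
        with pytest.raises(ValueError, match="r = 0"):
            ua.electrostatic_energy(np.zeros((1, 3)), np.array([1.0]), surf)


def _pairwise_r6_integral(r1, r2, d):
    """Numerical pairwise integration of 1/r^6 over two spheres (reduced
    to nested 1-D quadratures by spherical symmetry)."""
    def sphere_point(t, a):
        def f(r):
            return 2 * np.pi * r * r / (4 * t * r) * ((t - r) ** -4
                                                      - (t + r) ** -4)
        return quad(f, 0, a, epsrel=1e-10)[0]

    def outer(rho):
        def g(mu):
            s = math.sqrt(d * d + rho * rho - 2 * d * rho * mu)
            return sphere_point(s, r2)
        return 2 * np.pi * rho * rho * quad(g, -1, 1, epsrel=1e-9)[0]

    return quad(outer, 0, r1, epsrel=1e-9, limit=200)[0]


class TestHamaker:
    def test_zero_constant(self):
        assert ua.hamaker_sphere_sphere(0.5, 80.0, 85.0, 0.0) == 0.0
        assert ua.hamaker_sphere_plate(0.5, 1.0, 0.0) == 0.0

    def test_far_field_decay(self):
        assert abs(ua.hamaker_sphere_sphere(0.5, 80.0, 1e5, 1.0)) < 1e-9
        assert abs(ua.hamaker_sphere_plate(0.5, 1e4, 1.0)) < 1e-9

    @pytest.mark.parametrize("r1,r2,d", [(0.5, 3.0, 4.0), (0.5, 80.0, 80.8)])
    def test_numerical_integration_oracle(self, r1, r2, d):
        """The closed form equals -(A/pi^2) times the direct pairwise
        1/r^6 integral over both spheres (Hamaker normalisation)."""
        a123 = 2.5
        oracle = -(a123 / np.pi ** 2) * _pairwise_r6_integral(r1, r2, d)
        got = ua.hamaker_sphere_sphere(r1, r2, d, a123)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_plate_is_large_sphere_limit(self):
        gap = 0.7
        r_aa = 0.5
        big = 1e6
        sphere = ua.hamaker_sphere_sphere(r_aa, big, big + r_aa + gap, 1.0)
        plate = ua.hamaker_sphere_plate(r_aa, gap, 1.0)
        assert sphere == pytest.approx(plate, rel=1e-5)

    def test_overlap_and_nonpositive_distance_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            ua.hamaker_sphere_sphere(0.5, 80.0, 80.2, 1.0)
        with pytest.raises(ValueError, match="positive"):
            ua.hamaker_sphere_sphere(0.5, 80.0, -1.0, 1.0)
        with pytest.raises(ValueError, match="gap"):
            ua.hamaker_sphere_plate(0.5, 0.0, 1.0)


class TestShortRange:
    def test_single_bead_at_well(self, small_pmf_set):
        assert ua.short_range_energy([0.25], ["GLY"], small_pmf_set) == \
            pytest.approx(-5.0, abs=1e-9)

    def test_beyond_range_zero(self, small_pmf_set):
        assert ua.short_range_energy([5.0, 7.0], ["GLY", "LYS"],
                                     small_pmf_set) == 0.0

    def test_brute_force_sum(self, small_pmf_set, toy_protein):
        rng = np.random.default_rng(4)
        ssd = rng.uniform(0.1, 1.5, toy_protein.n_beads)
        got = ua.short_range_energy(ssd, toy_protein.residues, small_pmf_set)
        expected = sum(float(small_pmf_set[c](s))
                       for c, s in zip(toy_protein.residues, ssd))
        assert got == pytest.approx(expected, rel=1e-12)


class TestEnergyProfile:
    def test_single_bead_profile_is_pmf(self, single_bead, flat_surface,
                                        small_pmf_set):
        prof = ua.energy_profile(single_bead, flat_surface, small_pmf_set,
                                 0.0, 0.0)
        np.testing.assert_allclose(prof.total,
                                   small_pmf_set["GLY"](prof.z), atol=1e-12)

    def test_additivity_exact(self, toy_protein, conditions, small_pmf_set):
        surf = SurfaceSpec(geometry="flat", hamaker_A123=0.8,
                           zeta_potential=-5.0, conditions=conditions)
        prof = ua.energy_profile(toy_protein, surf, small_pmf_set, 33.0, 71.0)
        total = sum(prof.terms.values())
        np.testing.assert_array_equal(prof.total, total)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_far_field_neutrality(self, seed, conditions, small_pmf_set):
        """At 100 nm separation every term has decayed: |U| < 1e-6 kBT."""
        prot = make_protein(SyntheticProteinSpec(
            n_residues=8, target_radius=0.8, seed=seed,
            composition={"GLY": 4, "LYS": 2, "ASP": 2}))
        surf = SurfaceSpec(geometry="flat", hamaker_A123=1.0,
                           zeta_potential=-5.0, conditions=conditions)
        prof = ua.energy_profile(prot, surf, small_pmf_set, 25.0, 130.0,
                                 span=100.0, step=0.5)
        assert abs(prof.total[-1]) < 1e-6

    def test_bead_order_irrelevant(self, flat_surface, small_pmf_set):
        """Swapping beads of identical composition leaves the profile
        unchanged (symmetry oracle)."""
        pos = np.array([[0.0, 0.0, -0.4], [0.0, 0.0, 0.4]])
        a = bead_protein(pos, residues=["GLY", "GLY"])
        b = bead_protein(pos[::-1], residues=["GLY", "GLY"])
        pa = ua.energy_profile(a, flat_surface, small_pmf_set, 40.0, 10.0)
        pb = ua.energy_profile(b, flat_surface, small_pmf_set, 40.0, 10.0)
        np.testing.assert_allclose(pa.total, pb.total, atol=1e-12)

    def test_sphere_reduces_to_flat_for_large_np(self, single_bead,
                                                 conditions, small_pmf_set):
        flat = SurfaceSpec(geometry="flat", hamaker_A123=0.0,
                           conditions=conditions)
        sphere = SurfaceSpec(geometry="sphere", np_radius=1e5,
                             hamaker_A123=0.0, conditions=conditions)
        pf = ua.energy_profile(single_bead, flat, small_pmf_set, 0, 0)
        ps = ua.energy_profile(single_bead, sphere, small_pmf_set, 0, 0)
        np.testing.assert_allclose(ps.total, pf.total, atol=1e-6)


def square_well_profile(depth, frac, a=1.0, step=0.001, start=0.3):
    z = np.arange(0.0, a + step / 2, step)
    u = np.where((z >= start) & (z < start + frac * a), -depth, 0.0)
    return ua.EnergyProfile(theta=0, phi=0, z=z, total=u, terms={},
                            contact=0.0, geometry="flat")


class TestOrientationEnergy:
    def test_zero_potential_gives_exact_zero(self):
        prof = square_well_profile(0.0, 0.5)
        e, a = ua.orientation_energy(prof, a_tol=0.0, a_cap=10.0)
        assert e == 0.0

    @pytest.mark.parametrize("depth,frac", [(5.0, 0.4), (2.0, 0.25),
                                            (20.0, 0.1)])
    def test_square_well_closed_form(self, depth, frac):
        """Trapezoid quadrature of the log-Boltzmann integral reproduces
        E = -ln(f e^W + 1 - f) to better than 0.1%."""
        prof = square_well_profile(depth, frac)
        e, _ = ua.orientation_energy(prof, a_tol=0.0, a_cap=10.0)
        expected = -math.log(frac * math.exp(depth) + 1.0 - frac)
        assert abs(e - expected) / abs(expected) < 1e-3

    def test_deep_well_asymptote_and_monotonicity(self):
        """For a deep narrow well, E ~ -W + ln(a/width); E decreases
        monotonically with W."""
        energies = []
        for depth in [30.0, 40.0, 50.0]:
            prof = square_well_profile(depth, 0.02)
            e, _ = ua.orientation_energy(prof, a_tol=0.0, a_cap=10.0)
            energies.append(e)
            assert e == pytest.approx(-depth + math.log(1.0 / 0.02), abs=0.1)
        assert energies[0] > energies[1] > energies[2]

    def test_nonfinite_integrand_raises(self):
        prof = square_well_profile(5.0, 0.4)
        prof.total[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ua.orientation_energy(prof)


class TestHeatmap:
    def test_single_bead_constant(self, single_bead, flat_surface,
                                  small_pmf_set):
        hm = ua.build_heatmap(single_bead, flat_surface, small_pmf_set,
                              grid_step=45.0)
        assert np.ptp(hm.energies) < 1e-10
        assert hm.e_ads == pytest.approx(hm.e_min, abs=1e-9)

    def test_dipolar_argmin_faces_attractive_bead(self, flat_surface,
                                                  small_pmf_set):
        """A two-bead protein with one strongly and one weakly binding bead
        orients the strong binder toward the surface; the coarse-grid
        minimum agrees with an exhaustive fine-grid scan."""
        pos = np.array([[0.0, 0.0, -0.4], [0.0, 0.0, 0.4]])
        prot = bead_protein(pos, residues=["LYS", "ALA"])  # LYS deep well
        hm = ua.build_heatmap(prot, flat_surface, small_pmf_set,
                              grid_step=30.0)
        th, ph = hm.argmin_angles
        # LYS sits at -z in the protein frame; the surface-facing direction
        # is -n, so the minimum requires n ~ +z, i.e. theta near 0 or 360
        n = ua.direction_from_angles(th, ph)
        heights = prot.centered_positions() @ n
        assert heights[0] < heights[1]  # LYS is the lower bead
        fine = min(
            ua.orientation_energy(
                ua.energy_profile(prot, flat_surface, small_pmf_set, t, p))[0]
            for t in np.arange(0, 360, 10.0) for p in (0.0, 90.0))
        assert hm.e_min == pytest.approx(fine, abs=0.05)

    def test_rotational_consistency_phi_shift(self, flat_surface,
                                              small_pmf_set):
        """Pre-rotating the protein about z by a grid-commensurate angle
        permutes the heatmap columns."""
        prot = make_protein(SyntheticProteinSpec(
            n_residues=6, target_radius=0.7, seed=9,
            composition={"GLY": 3, "LYS": 2, "ASP": 1}))
        step = 45.0
        hm0 = ua.build_heatmap(prot, flat_surface, small_pmf_set,
                               grid_step=step)
        phi0 = 90.0
        q = ua.rotation_matrix(0.0, -phi0)  # rotation about z by +phi0
        rotated = bead_protein(prot.centered_positions() @ q.T,
                               residues=prot.residues)
        hm1 = ua.build_heatmap(rotated, flat_surface, small_pmf_set,
                               grid_step=step)
        shift = int(phi0 / step)
        np.testing.assert_allclose(hm1.energies,
                                   np.roll(hm0.energies, shift, axis=1),
                                   atol=1e-8)

    def test_grid_refinement_stability(self, toy_protein, flat_surface,
                                       small_pmf_set):
        """Halving the distance-quadrature step changes E by < 0.5%."""
        e1, _ = ua.orientation_energy(ua.energy_profile(
            toy_protein, flat_surface, small_pmf_set, 70.0, 20.0, step=0.01))
        e2, _ = ua.orientation_energy(ua.energy_profile(
            toy_protein, flat_surface, small_pmf_set, 70.0, 20.0, step=0.005))
        assert abs(e2 - e1) / abs(e2) < 0.005

    def test_bounds_invariant(self, toy_protein, flat_surface, small_pmf_set):
        hm = ua.build_heatmap(toy_protein, flat_surface, small_pmf_set,
                              grid_step=60.0)
        assert hm.e_min <= hm.e_ads <= hm.energies.max()
        hm.validate()
        assert hm.r_min > 0


class TestBoltzmannAverage:
    def test_constant_heatmap(self):
        hm = AdsorptionHeatmap(theta=[30, 90], phi=[0, 180],
                               energies=np.full((2, 2), -7.3))
        assert ua.boltzmann_average(hm) == pytest.approx(-7.3, abs=1e-12)

    def test_dominant_pose_limit(self):
        e = np.zeros((4, 4))
        e[2, 1] = -100.0
        hm = AdsorptionHeatmap(theta=[30, 60, 90, 120], phi=[0, 90, 180, 270],
                               energies=e)
        assert abs(ua.boltzmann_average(hm) - (-100.0)) < 0.1

    def test_two_by_two_hand_computation(self):
        """Frozen arithmetic oracle for the weighted average with
        P_kl = sin(theta_k) exp(-E_kl)."""
        hm = AdsorptionHeatmap(theta=[30, 90], phi=[0, 180],
                               energies=[[-1.0, -2.0], [-3.0, -4.0]])
        assert ua.boltzmann_average(hm) == pytest.approx(-3.60430070196393,
                                                         rel=1e-12)

    def test_overflow_safe_for_deep_minima(self):
        hm = AdsorptionHeatmap(theta=[30, 90], phi=[0, 180],
                               energies=[[-343.0, -300.0], [-200.0, 0.0]])
        assert hm.e_ads == pytest.approx(-343.0, abs=1e-6)

    def test_all_zero_weights_raise(self):
        hm = AdsorptionHeatmap(theta=[0.0], phi=[0.0, 90.0],
                               energies=np.zeros((1, 2)))
        with pytest.raises(ValueError, match="weights"):
            ua.boltzmann_average(hm)


class TestRanking:
    def test_engineered_depths_order(self):
        def fake(name, e_min):
            e = np.zeros((2, 2))
            e[1, 1] = e_min
            return AdsorptionHeatmap(theta=[30, 90], phi=[0, 180], energies=e,
                                     metadata={"protein": name}, r_min=0.1)
        df = ua.rank_proteins([fake("shallow", -5.0), fake("deep", -10.0)])
        assert list(df["protein"]) == ["deep", "shallow"]
        single = ua.rank_proteins([fake("only", -1.0)])
        assert len(single) == 1

    def test_tie_broken_by_name(self):
        def fake(name):
            return AdsorptionHeatmap(theta=[30, 90], phi=[0, 180],
                                     energies=np.full((2, 2), -2.0),
                                     metadata={"protein": name})
        df = ua.rank_proteins([fake("b"), fake("a")])
        assert list(df["protein"]) == ["a", "b"]
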