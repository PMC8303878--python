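"""Structural metrics: superposition RMSD, contacts, RGyr, SASA, helix
content, residue distances, LOWESS."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from confcube.core import Frame
from confcube.ensemble import BasinSpec, EnsembleSpec, generate_basin_ensemble
from confcube.errors import (
    DegenerateFitError,
    NotComputableError,
    UndefinedFncError,
    ValidationError,
)
from confcube.metrics import (
    fraction_native_contacts,
    helix_content,
    lowess_smooth,
    native_contacts,
    radius_of_gyration,
    residue_distance,
    rmsd,
    sasa,
    superpose,
)

from conftest import bead_frame


def brute_force_fit_rmsd(P, Q, n_grid=200_000, grid_seed=0):
    """Oracle: best RMSD over a large random rotation grid, locally refined."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    n = len(P)
    rots = Rotation.random(n_grid, random_state=grid_seed)
    # evaluate in chunks to bound memory
    best_val, best_rv = np.inf, None
    for start in range(0, n_grid, 20_000):
        chunk = rots[start : start + 20_000]
        diff = np.einsum("rij,nj->rni", chunk.as_matrix(), Pc) - Qc
        ssd = (diff**2).sum(axis=(1, 2))
        i = int(ssd.argmin())
        if ssd[i] < best_val:
            best_val = float(ssd[i])
            best_rv = chunk[i].as_rotvec()

    def objective(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return (((Pc @ R.T) - Qc) ** 2).sum()

    res = minimize(objective, best_rv, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20_000})
    return np.sqrt(res.fun / n)


class TestSuperpose:
    def test_identity(self):
        f = bead_frame(np.random.default_rng(0).normal(size=(6, 3)))
        R, t, v = superpose(f, f)
        assert v == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self):
        coords = np.random.default_rng(1).normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([1.0, -2.0, 0.5])
        a, b = bead_frame(coords), bead_frame(moved)
        assert rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_rotation_grid(self):
        rng = np.random.default_rng(42)
        P, Q = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        ours = rmsd(bead_frame(P), bead_frame(Q))
        oracle = brute_force_fit_rmsd(P, Q)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_collinear_toy_matches_independent_kabsch(self):
        # the value stays well-defined when one structure is collinear
        a = bead_frame([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        b = bead_frame([(0, 0, 0), (1, 0, 0), (2, 0.3, 0)])
        P, Q = a.coords, b.coords
        _, rssd = Rotation.align_vectors(
            Q - Q.mean(0), P - P.mean(0), return_sensitivity=False
        )
        assert rmsd(a, b) == pytest.approx(rssd / np.sqrt(3), abs=1e-9)

    def test_degenerate_selection_raises(self):
        collinear = bead_frame([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        target = bead_frame(np.random.default_rng(2).normal(size=(3, 3)))
        with pytest.raises(DegenerateFitError):
            superpose(collinear, target)
        two = bead_frame([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(DegenerateFitError):
            superpose(two, two)

    def test_rmsd_is_pseudometric(self):
        rng = np.random.default_rng(3)
        frames = [bead_frame(rng.normal(size=(7, 3))) for _ in range(4)]
        for x in frames:
            # exact-zero self-distance up to float cancellation in the
            # Kabsch trace formula
            assert rmsd(x, x) == pytest.approx(0.0, abs=1e-7)
        for x in frames:
            for y in frames:
                assert rmsd(x, y) >= 0
                assert rmsd(x, y) == pytest.approx(rmsd(y, x), abs=1e-9)

    def test_uniform_shift_gives_zero(self):
        coords = np.random.default_rng(4).normal(size=(5, 3))
        a, b = bead_frame(coords), bead_frame(coords + 0.1)
        assert rmsd(a, b) == pytest.approx(0.0, abs=1e-12)


class TestNativeContacts:
    def test_linear_chain_has_no_contacts(self):
        coords = np.array([(0.4 * i, 0.0, 0.0) for i in range(12)])
        cs = native_contacts(bead_frame(coords), cutoff=0.45,
                             min_sequence_separation=3)
        assert len(cs) == 0

    def test_hairpin_cross_strand_pairs(self):
        # two strands 0.4 nm apart; cross-strand pairs (i, 7-i) are contacts
        # except (3, 4), whose sequence separation 1 is below the minimum
        up = [(0.0, 0.4 * i, 0.0) for i in range(4)]
        down = [(0.4, 0.4 * (3 - i), 0.0) for i in range(4)]
        frame = bead_frame(np.array(up + down))
        cs = native_contacts(frame, cutoff=0.45, min_sequence_separation=3)
        expected = {(0, 7), (1, 6), (2, 5)}
        got = {tuple(p) for p in cs.pairs}
        assert got == expected

    def test_empty_selection_gives_empty_set(self, reference):
        cs = native_contacts(reference, cutoff=0.8, selection=np.array([], dtype=int))
        assert len(cs) == 0

    def test_non_positive_cutoff_rejected(self, reference):
        with pytest.raises(ValidationError):
            native_contacts(reference, cutoff=0.0)


class TestFractionNativeContacts:
    def test_reference_scores_one(self, reference):
        cs = native_contacts(reference)
        assert fraction_native_contacts(reference, cs) == 1.0

    def test_fully_displaced_scores_zero(self, reference):
        cs = native_contacts(reference)
        spread = Frame(reference.topology, reference.coords * 50.0)
        assert fraction_native_contacts(spread, cs) == 0.0

    def test_half_broken_toy(self):
        # two contacts (0-4) and (0-5); break the second to 2x cutoff
        coords = np.array(
            [(0, 0, 0), (0.9, 0, 0), (1.8, 0, 0), (2.7, 0, 0),
             (0.5, 0, 0), (0, 0.5, 0)]
        )
        frame = bead_frame(coords)
        cs = native_contacts(frame, cutoff=0.6, min_sequence_separation=4)
        assert {tuple(p) for p in cs.pairs} == {(0, 4), (0, 5)}
        moved = coords.copy()
        moved[5] = (0, 1.5, 0)
        assert fraction_native_contacts(bead_frame(moved), cs) == 0.5

    def test_empty_contact_set_is_an_error(self, reference):
        cs = native_contacts(reference, cutoff=0.8, selection=np.array([], dtype=int))
        with pytest.raises(UndefinedFncError):
            fraction_native_contacts(reference, cs)

    def test_rigid_motion_invariance(self, reference):
        cs = native_contacts(reference)
        rot = Rotation.from_euler("xyz", [10, 80, -30], degrees=True).as_matrix()
        moved = Frame(reference.topology, reference.coords @ rot.T + 3.0)
        assert fraction_native_contacts(moved, cs) == 1.0

    def test_mean_fnc_decreases_with_basin_displacement(self, reference):
        """Final-frame phi falls strictly as the planted basin moves away."""
        from confcube.ensemble import make_basin_targets

        cs = native_contacts(reference)
        means = []
        for sep, unfold in [(0.8, 0.0), (1.6, 0.15), (2.4, 0.30)]:
            basins = make_basin_targets(
                reference, separations=(sep,), unfold_fractions=(unfold,),
                weights=(1.0,),
            )
            spec = EnsembleSpec(6, 3, 1, seed=9, reference=reference)
            ens = generate_basin_ensemble(spec, basins)
            finals = [
                fraction_native_contacts(t.frame(t.n_frames - 1), cs)
                for t in ens.trajectories
            ]
            means.append(np.mean(finals))
        assert means[0] > means[1] > means[2]


class TestRadiusOfGyration:
    def test_coincident_atoms(self):
        f = bead_frame(np.zeros((5, 3)))
        assert radius_of_gyration(f) == 0.0

    def test_two_equal_masses(self):
        f = bead_frame([(0, 0, 0), (0, 0, 2.0)])
        assert radius_of_gyration(f) == pytest.approx(1.0, abs=1e-12)

    def test_unit_cube_corners(self):
        corners = np.array(
            [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)], float
        )
        assert radius_of_gyration(bead_frame(corners)) == pytest.approx(
            np.sqrt(3) / 2, abs=1e-12
        )

    def test_rigid_motion_invariance(self, reference):
        rot = Rotation.from_euler("y", 123, degrees=True).as_matrix()
        moved = Frame(reference.topology, reference.coords @ rot.T - 7.0)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(reference), abs=1e-12
        )

    def test_mass_weighting(self):
        f = bead_frame([(0, 0, 0), (0, 0, 1.0)], masses=np.array([3.0, 1.0]))
        # COM at z=0.25; rgyr = sqrt((3*0.0625 + 1*0.5625)/4)
        assert radius_of_gyration(f) == pytest.approx(np.sqrt(0.1875), abs=1e-12)


class TestSasa:
    def test_single_sphere_analytic(self):
        f = bead_frame(np.zeros((1, 3)))
        area = sasa(f, probe_radius=0.14, n_points=960, radii={"C": 1.9})
        analytic = 4 * np.pi * (1.9 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_coincident_atoms_occlude_to_one_sphere(self):
        f = bead_frame(np.zeros((2, 3)))
        one = sasa(bead_frame(np.zeros((1, 3))), n_points=960)
        two = sasa(f, n_points=960)
        assert two == pytest.approx(one, rel=0.01)

    def test_distant_atoms_add_up(self):
        f = bead_frame([(0, 0, 0), (10.0, 0, 0)])  # 100 A apart
        one = sasa(bead_frame(np.zeros((1, 3))), n_points=960)
        assert sasa(f, n_points=960) == pytest.approx(2 * one, rel=0.01)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(8)
        f = bead_frame(0.3 * rng.normal(size=(10, 3)))
        coarse = sasa(f, n_points=960)
        fine = sasa(f, n_points=1920)
        assert abs(fine - coarse) / fine < 0.005

    def test_unknown_element_rejected(self):
        f = bead_frame(np.zeros((1, 3)), element="Xx")
        with pytest.raises(ValidationError, match="Xx"):
            sasa(f)


class TestHelixContent:
    def test_ideal_helix_is_100(self):
        dih = np.tile([-57.0, -47.0], (10, 1))
        f = bead_frame(np.random.default_rng(0).normal(size=(10, 3)), dihedrals=dih)
        assert helix_content(f) == 100.0

    def test_extended_chain_is_0(self):
        dih = np.tile([180.0, 180.0], (10, 1))
        f = bead_frame(np.random.default_rng(0).normal(size=(10, 3)), dihedrals=dih)
        assert helix_content(f) == 0.0

    def test_half_helix_half_extended(self):
        dih = np.vstack([np.tile([-57.0, -47.0], (8, 1)), np.tile([180.0, 180.0], (8, 1))])
        f = bead_frame(np.random.default_rng(0).normal(size=(16, 3)), dihedrals=dih)
        assert helix_content(f) == pytest.approx(50.0, abs=100.0 / 16)

    def test_short_runs_do_not_count(self):
        flags = [True, True, True, False] * 4  # runs of 3 < minimum run 4
        dih = np.array([[-57.0, -47.0] if f else [180.0, 180.0] for f in flags])
        f = bead_frame(np.random.default_rng(0).normal(size=(16, 3)), dihedrals=dih)
        assert helix_content(f) == 0.0

    def test_missing_backbone_and_metadata_raises(self):
        f = bead_frame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(NotComputableError):
            helix_content(f)


class TestResidueDistance:
    def test_residue_with_itself(self, reference):
        assert residue_distance(reference, 10, 10) == 0.0

    def test_unit_conversion_to_angstrom(self):
        f = bead_frame([(0, 0, 0), (0, 0, 2.13)])
        assert residue_distance(f, 1, 2) == pytest.approx(21.3, abs=1e-9)

    def test_triangle_toy(self):
        f = bead_frame([(0, 0, 0), (0.3, 0, 0), (0.3, 0.4, 0)])
        assert residue_distance(f, 1, 3) == pytest.approx(5.0, abs=1e-9)

    def test_missing_residue_raises(self, reference):
        with pytest.raises(ValidationError):
            residue_distance(reference, 10, 9999)


class TestLowess:
    def test_constant_series_unchanged(self):
        y = np.full(50, 3.5)
        np.testing.assert_allclose(lowess_smooth(y, frac=0.3), y, atol=1e-12)

    def test_linear_series_unchanged(self):
        y = 0.2 * np.arange(40) + 1.0
        np.testing.assert_allclose(lowess_smooth(y, frac=0.4), y, atol=1e-9)

    def test_noise_variance_reduced_about_signal(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 2 * np.pi, 200)
        signal = np.sin(x)
        noisy = signal + 0.1 * rng.normal(size=len(x))
        smoothed = lowess_smooth(noisy, frac=0.3, x=x)
        assert np.var(smoothed - signal) < np.var(noisy - signal)

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_frac_validation(self, frac):
        with pytest.raises(ValidationError):
            lowess_smooth(np.arange(10.0), frac=frac)

    def test_too_short_series(self):
        with pytest.raises(ValidationError):
            lowess_smooth(np.array([1.0, 2.0]))
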