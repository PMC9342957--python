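"""Membrane geometry, ensemble RMSD/R_g, and RDF metrics on known fixtures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import build_traj, lipid_row, peptide_row
from pepmem.errors import ConfigError, DataError
from pepmem.synthetic import BilayerSpec, SyntheticTruth, make_bilayer_trajectory
from pepmem.traj_analysis import (
    area_per_lipid,
    bilayer_thickness,
    ensemble_stats,
    fraction_below_rmsd,
    insertion_depth,
    lateral_rdf,
    radius_of_gyration,
    superpose_rmsd,
)


def _bilayer_rows():
    """Four phosphates per leaflet plus acyl beads; COM at z = 0 by symmetry."""
    rows, coords = [], []
    resid = 0
    for sign in (1.0, -1.0):
        for k in range(4):
            resid += 1
            rows.append(lipid_row("P", "P", resid, "headgroup"))
            coords.append([10.0 * k, 10.0, sign * 19.0])
            rows.append(lipid_row("ACY", "C", resid, "acyl"))
            coords.append([10.0 * k, 10.0, sign * 5.0])
    return rows, coords


class TestInsertionDepth:
    def test_atom_at_bilayer_com_has_zero_depth(self):
        rows, coords = _bilayer_rows()
        rows.append(peptide_row("CB", 1))
        coords.append([5.0, 5.0, 0.0])
        traj = build_traj([coords], rows=rows)
        profile = insertion_depth(traj)
        assert profile.mean[0] == pytest.approx(0.0, abs=1e-12)

    def test_lower_leaflet_depth_reflected_positive(self):
        rows, coords = _bilayer_rows()
        rows.append(peptide_row("CB", 1))
        coords.append([5.0, 5.0, -15.0])
        traj = build_traj([coords], rows=rows)
        profile = insertion_depth(traj)
        assert profile.mean[0] == pytest.approx(15.0, abs=1e-12)
        assert profile.phosphate_plane == pytest.approx(19.0, abs=1e-12)

    def test_missing_selection_rejected(self):
        rows, coords = _bilayer_rows()
        traj = build_traj([coords], rows=rows)
        with pytest.raises(DataError, match="CB"):
            insertion_depth(traj)

    def test_recovers_generator_truth_within_three_se(self):
        truth = SyntheticTruth(
            seed=7, residue_depths=(12.0, 12.0, 12.0, 12.0), depth_jitter=1.0,
            lipid_z_jitter=0.0, lipid_xy_jitter=0.0, peptide_xy_jitter=0.0,
            apl_jitter=0.0,
        )
        traj = make_bilayer_trajectory(BilayerSpec(), 20, truth, 500)
        profile = insertion_depth(traj)
        # sample-mean oracle on the generated Cβ depth series itself
        idx = traj.atoms.index[
            (traj.atoms["role"] == "peptide") & (traj.atoms["name"] == "CB")
        ].to_numpy()
        samples = np.abs(traj.coords[:, idx, 2]).ravel()
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(np.mean(profile.mean) - 12.0) < 3 * se + 1e-9

    def test_invariance_under_translation_and_z_rotation(self, small_bilayer):
        ref = insertion_depth(small_bilayer).mean
        traj = small_bilayer
        shifted = build_traj(
            traj.coords + np.array([3.0, -7.0, 11.0]), rows=traj.atoms.to_dict("records")
        )
        assert np.allclose(insertion_depth(shifted).mean, ref, atol=1e-9)
        rot = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        rotated = build_traj(
            traj.coords @ rot.T, rows=traj.atoms.to_dict("records")
        )
        assert np.allclose(insertion_depth(rotated).mean, ref, atol=1e-9)


class TestThicknessAndArea:
    def test_frozen_planes_give_exact_thickness(self, small_bilayer):
        series, stats = bilayer_thickness(small_bilayer)
        assert np.allclose(series, 38.0, atol=1e-9)
        assert stats.mean == pytest.approx(38.0, abs=1e-9)

    def test_thickness_invariant_under_rigid_z_translation(self, small_bilayer):
        traj = small_bilayer
        shifted = build_traj(
            traj.coords + np.array([0.0, 0.0, 25.0]), rows=traj.atoms.to_dict("records")
        )
        s1, _ = bilayer_thickness(traj)
        s2, _ = bilayer_thickness(shifted)
        assert np.allclose(s1, s2, atol=1e-9)

    def test_thickness_recovery_on_noisy_fixture(self):
        truth = SyntheticTruth(
            seed=11, thickness=39.0, lipid_z_jitter=0.5,
            depth_jitter=0.0, lipid_xy_jitter=0.0, peptide_xy_jitter=0.0,
            apl_jitter=0.0,
        )
        traj = make_bilayer_trajectory(BilayerSpec(), 20, truth, 400)
        series, stats = bilayer_thickness(traj)
        se = series.std(ddof=1) / np.sqrt(series.size)
        assert abs(stats.mean - 39.0) < 3 * se + 1e-9

    def test_missing_leaflet_rejected(self):
        rows = [lipid_row("P", "P", 1, "headgroup"),
                lipid_row("ACY", "C", 1, "acyl")]
        coords = [[0.0, 0.0, 19.0], [0.0, 0.0, 5.0]]
        traj = build_traj([coords], rows=rows)
        with pytest.raises(DataError):
            bilayer_thickness(traj)

    def test_area_per_lipid_arithmetic_and_scaling(self, small_bilayer):
        traj = build_traj(
            small_bilayer.coords, box=(78.0, 78.0, 80.0),
            rows=small_bilayer.atoms.to_dict("records"),
        )
        series, stats = area_per_lipid(traj, 75)
        assert np.allclose(series, 81.12)
        doubled = build_traj(
            small_bilayer.coords, box=(156.0, 156.0, 80.0),
            rows=small_bilayer.atoms.to_dict("records"),
        )
        series2, _ = area_per_lipid(doubled, 75)
        assert np.allclose(series2, 4 * series)
        with pytest.raises(ConfigError):
            area_per_lipid(traj, 0)

    def test_area_recovery_at_composition_weighted_target(self):
        truth = SyntheticTruth(seed=13, apl_jitter=0.5)
        traj = make_bilayer_trajectory(BilayerSpec(), 20, truth, 300)
        _, stats = area_per_lipid(traj, 75)
        assert abs(stats.mean - 81.8) < 3 * stats.se + 0.05


class TestEnsembleStats:
    def test_identical_copies_have_zero_rmsd(self, rng):
        base = rng.normal(size=(9, 3))
        stats = ensemble_stats(np.stack([base] * 5))
        assert np.allclose(stats.rmsd, 0.0, atol=1e-9)

    def test_rigid_motion_removed_by_superposition(self, rng):
        base = rng.normal(size=(9, 3))
        rot = Rotation.from_euler("xyz", [30, -60, 12], degrees=True).as_matrix()
        moved = base @ rot.T + np.array([5.0, -2.0, 8.0])
        assert superpose_rmsd(moved, base) == pytest.approx(0.0, abs=1e-9)

    def test_two_unit_points_rg_is_one(self):
        assert radius_of_gyration(
            np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        ) == pytest.approx(1.0)

    def test_superposition_agrees_with_scipy_align_vectors(self, rng):
        # independent route: scipy's Kabsch implementation
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        ours = superpose_rmsd(b, a)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        _, rssd = Rotation.align_vectors(ac, bc)
        assert ours == pytest.approx(rssd / np.sqrt(12), rel=1e-9)

    def test_mismatched_atom_lists_rejected(self, rng):
        with pytest.raises(DataError):
            ensemble_stats(rng.normal(size=(1, 5, 3)))
        with pytest.raises(DataError):
            superpose_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestFractionBelowRMSD:
    def _chain_traj(self, frames_coords):
        rows = [peptide_row(f"C{i}", i + 1) for i in range(4)]
        return build_traj(np.asarray(frames_coords), rows=rows)

    def test_frozen_copies_give_fraction_one(self, rng):
        ref = rng.normal(size=(4, 3))
        traj = self._chain_traj([ref] * 6)
        out = fraction_below_rmsd(traj, ref, 3.0)
        assert out["P01"] == 1.0
        assert out["ensemble"] == 1.0

    def test_internally_displaced_reference_gives_zero(self, rng):
        ref = rng.normal(size=(4, 3))
        far = ref.copy()
        far[0] += np.array([40.0, 0.0, 0.0])   # internal deformation >> threshold
        traj = self._chain_traj([far] * 6)
        assert fraction_below_rmsd(traj, ref, 3.0)["P01"] == 0.0

    def test_alternating_conformers_give_half(self, rng):
        ref = rng.normal(size=(4, 3)) * 2.0
        near = ref + rng.normal(scale=0.3, size=(4, 3))      # ~sub-Å RMSD
        far = ref.copy()
        far[0] += np.array([15.0, 0.0, 0.0])
        assert superpose_rmsd(near, ref) < 3.0 < superpose_rmsd(far, ref)
        traj = self._chain_traj([near, far] * 5)
        assert fraction_below_rmsd(traj, ref, 3.0)["P01"] == pytest.approx(0.5)

    def test_monotone_in_threshold(self, rng):
        ref = rng.normal(size=(4, 3)) * 2.0
        frames = [ref + rng.normal(scale=s, size=(4, 3)) for s in
                  (0.1, 0.5, 1.0, 2.0, 4.0, 8.0)]
        traj = self._chain_traj(frames)
        fracs = [
            fraction_below_rmsd(traj, ref, thr)["P01"] for thr in (0.5, 1.0, 3.0, 10.0)
        ]
        assert fracs == sorted(fracs)

    def test_unmappable_reference_rejected(self, rng):
        traj = self._chain_traj([rng.normal(size=(4, 3))])
        with pytest.raises(DataError):
            fraction_below_rmsd(traj, rng.normal(size=(7, 3)))


class TestLateralRDF:
    def test_uniform_points_give_unity(self, rng):
        n = 2000
        box = 100.0
        coords = np.zeros((3, n, 3))
        coords[:, :, 0] = rng.uniform(0, box, size=(3, n))
        coords[:, :, 1] = rng.uniform(0, box, size=(3, n))
        rows = [
            {"name": "P", "element": "P", "resid": i + 1, "chain": "L",
             "role": "headgroup", "radius": 1.8}
            for i in range(n)
        ]
        traj = build_traj(coords, box=(box, box, 50.0), rows=rows)
        idx = np.arange(n)
        prof = lateral_rdf(traj, idx, idx, np.arange(5.0, 45.0, 2.0))
        assert np.all(np.abs(prof.g - 1.0) < 0.1)

    def test_square_lattice_excludes_below_spacing(self):
        d = 8.0
        xs, ys = np.meshgrid(np.arange(10) * d, np.arange(10) * d)
        coords = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(100)])
        rows = [
            {"name": "P", "element": "P", "resid": i + 1, "chain": "L",
             "role": "headgroup", "radius": 1.8}
            for i in range(100)
        ]
        traj = build_traj([coords], box=(10 * d, 10 * d, 50.0), rows=rows)
        idx = np.arange(100)
        prof = lateral_rdf(traj, idx, idx, np.linspace(0.5, d - 0.5, 8))
        assert np.allclose(prof.g, 0.0)

    def test_six_point_configuration_matches_hand_count(self):
        box = 10.0
        pts = np.array([
            [1.0, 1.0, 0.0], [4.0, 1.0, 0.0], [8.0, 1.0, 0.0],
            [1.0, 6.0, 0.0], [5.0, 5.0, 0.0], [9.0, 9.0, 0.0],
        ])
        rows = [
            {"name": "P", "element": "P", "resid": i + 1, "chain": "L",
             "role": "headgroup", "radius": 1.8}
            for i in range(6)
        ]
        traj = build_traj([pts], box=(box, box, 20.0), rows=rows)
        edges = np.linspace(0.0, 7.5, 6)
        prof = lateral_rdf(traj, np.arange(6), np.arange(6), edges)
        # brute-force pair enumeration with minimum image in x and y
        expected = np.zeros(len(edges) - 1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                dx = pts[j, 0] - pts[i, 0]
                dy = pts[j, 1] - pts[i, 1]
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                r = np.hypot(dx, dy)
                for b in range(len(edges) - 1):
                    if edges[b] <= r < edges[b + 1]:
                        expected[b] += 1
        assert np.array_equal(prof.counts, expected)

    def test_pair_count_sum_invariant(self, rng):
        n_ref, n_tgt = 15, 40
        box = 30.0
        coords = np.zeros((2, n_ref + n_tgt, 3))
        coords[:, :, :2] = rng.uniform(0, box, size=(2, n_ref + n_tgt, 2))
        rows = [
            {"name": "P", "element": "P", "resid": i + 1, "chain": "L",
             "role": "headgroup", "radius": 1.8}
            for i in range(n_ref + n_tgt)
        ]
        traj = build_traj(coords, box=(box, box, 20.0), rows=rows)
        edges = np.linspace(0.0, box * np.sqrt(2) / 2 + 0.1, 30)
        prof = lateral_rdf(traj, np.arange(n_ref), np.arange(n_ref, n_ref + n_tgt), edges)
        assert prof.counts.sum() == 2 * n_ref * n_tgt   # two frames, disjoint sets

    def test_bad_bins_rejected(self, small_bilayer):
        idx = small_bilayer.role_indices("headgroup")
        with pytest.raises(ConfigError):
            lateral_rdf(small_bilayer, idx, idx, np.array([5.0, 4.0, 3.0]))
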