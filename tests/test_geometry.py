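"""Geometry: PDB IO, superposition, centroids, tilt/twist, p(r), superhelix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from igh_elastica.geometry import (
    Domain,
    StructureModel,
    build_synthetic_superhelix,
    domain_centroids,
    neighbor_distance_stats,
    pair_distance_distribution,
    read_pdb,
    superpose_shared_domain,
    tilt_twist,
    write_pdb,
)


def _single_atom_model(pos=(0.0, 0.0, 0.0)):
    return StructureModel(
        coords=np.array([pos]),
        chain_ids=np.array(["A"]),
        residue_indices=np.array([1]),
        atom_names=np.array(["CA"]),
        elements=np.array(["C"]),
    )


class TestReadWritePDB:
    def test_single_atom_at_origin(self, tmp_path):
        p = tmp_path / "one.pdb"
        write_pdb(_single_atom_model(), p)
        model = read_pdb(p)
        assert len(model) == 1
        assert np.allclose(model.coords[0], 0.0)

    def test_write_read_round_trip(self, tmp_path):
        model = build_synthetic_superhelix(3, points_per_module=5, seed=1)
        p = tmp_path / "helix.pdb"
        write_pdb(model, p)
        back = read_pdb(p)
        assert len(back) == len(model)
        assert np.allclose(back.coords, model.coords, atol=1.5e-3)
        assert np.array_equal(back.residue_indices, model.residue_indices)

    def test_hetatm_only_file_rejected(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(ValueError, match="no ATOM records"):
            read_pdb(p)

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1      xx.000   0.000   0.000"
            "  1.00  0.00           C\n"
        )
        with pytest.raises(ValueError, match=r":1:"):
            read_pdb(p)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises((FileNotFoundError, OSError, ValueError)):
            read_pdb(tmp_path / "absent.pdb")

    def test_insertion_codes_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1A      0.000   0.000   0.000"
            "  1.00  0.00           C\n"
        )
        with pytest.raises(ValueError, match="insertion"):
            read_pdb(p)


class TestSuperposition:
    def test_self_superposition_is_identity(self, superhelix):
        tf, rmsd, moved = superpose_shared_domain(superhelix, superhelix, "M1")
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(moved.coords, superhelix.coords, atol=1e-9)

    def test_known_rigid_motion_recovered(self, superhelix):
        R = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        t = np.array([5.0, -2.0, 1.0])
        moved = superhelix.transformed(R, t)
        tf, rmsd, back = superpose_shared_domain(moved, superhelix, "M4")
        assert rmsd < 1e-6
        assert np.allclose(back.coords, superhelix.coords, atol=1e-6)
        # the recovered transform inverts the applied motion
        assert np.allclose(tf.rotation, R.T, atol=1e-9)

    def test_superposition_idempotent(self, superhelix):
        moved = superhelix.transformed(
            Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix(),
            np.array([1.0, 2.0, 3.0]),
        )
        _, rmsd1, once = superpose_shared_domain(moved, superhelix, "M2")
        _, rmsd2, _ = superpose_shared_domain(once, superhelix, "M2")
        assert abs(rmsd2 - rmsd1) < 1e-9

    def test_too_few_shared_atoms_rejected(self):
        a = StructureModel(
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            chain_ids=np.array(["A", "A"]),
            residue_indices=np.array([1, 2]),
            atom_names=np.array(["CA", "CA"]),
            elements=np.array(["C", "C"]),
            domain_boundaries=[Domain("D", "A", 1, 2)],
        )
        with pytest.raises(ValueError, match="shared CA"):
            superpose_shared_domain(a, a, "D")

    def test_collinear_points_flagged(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        a = StructureModel(
            coords=coords,
            chain_ids=np.array(["A"] * 4),
            residue_indices=np.arange(1, 5),
            atom_names=np.array(["CA"] * 4),
            elements=np.array(["C"] * 4),
            domain_boundaries=[Domain("D", "A", 1, 4)],
        )
        with pytest.raises(ValueError, match="collinear"):
            superpose_shared_domain(a, a, "D")


class TestCentroids:
    def test_two_atom_centroid(self):
        m = StructureModel(
            coords=np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            chain_ids=np.array(["A", "A"]),
            residue_indices=np.array([1, 2]),
            atom_names=np.array(["CA", "CA"]),
            elements=np.array(["C", "C"]),
            domain_boundaries=[Domain("D", "A", 1, 2)],
        )
        cents = domain_centroids(m)
        assert cents[0][0] == "D"
        assert np.allclose(cents[0][1], [1.0, 0, 0])

    def test_translation_equivariance(self, superhelix):
        t = np.array([3.0, -7.0, 11.0])
        shifted = superhelix.transformed(np.eye(3), t)
        c0 = domain_centroids(superhelix)
        c1 = domain_centroids(shifted)
        for (_, a), (_, b) in zip(c0, c1):
            assert np.allclose(b, a + t, atol=1e-9)

    def test_merge_pairs_reduces_count(self, superhelix):
        merged = domain_centroids(superhelix, merge_pairs=(("M5", "M6"),))
        assert len(merged) == 9
        plain = dict(domain_centroids(superhelix))
        lbls = [l for l, _ in merged]
        assert "M6" not in lbls
        expected = 0.5 * (plain["M5"] + plain["M6"])
        got = dict(merged)["M5"]
        assert np.allclose(got, expected, atol=1e-9)

    def test_domain_without_ca_rejected(self):
        m = StructureModel(
            coords=np.array([[0.0, 0, 0]]),
            chain_ids=np.array(["A"]),
            residue_indices=np.array([1]),
            atom_names=np.array(["CB"]),
            elements=np.array(["C"]),
            domain_boundaries=[Domain("D", "A", 1, 1)],
        )
        with pytest.raises(ValueError, match="no CA"):
            domain_centroids(m)


class TestNeighborDistances:
    def test_collinear_equal_spacing(self):
        cents = [(f"D{i}", np.array([4.0 * i, 0.0, 0.0])) for i in range(6)]
        for k in (1, 2, 3):
            mean, sd, n = neighbor_distance_stats(cents, k)
            assert mean == pytest.approx(4.0 * k)
            assert sd == pytest.approx(0.0, abs=1e-12)
            assert n == 6 - k

    def test_superhelix_matches_closed_form(self, superhelix):
        cents = domain_centroids(superhelix)
        mean, sd, _ = neighbor_distance_stats(cents, 1)
        rise, twist, radius = 49.8, math.radians(26.0), 5.0
        pred = math.sqrt(rise**2 + (2 * radius * math.sin(twist / 2)) ** 2)
        assert mean == pytest.approx(pred, rel=1e-9)
        assert sd < 1e-9

    def test_order_too_large_rejected(self):
        cents = [("a", np.zeros(3)), ("b", np.ones(3))]
        with pytest.raises(ValueError):
            neighbor_distance_stats(cents, 2)


class TestTiltTwist:
    def test_identical_domain_zero_angles(self, superhelix):
        arr = tilt_twist(superhelix, "M3", "M3")
        assert arr.tilt == 0.0
        assert arr.twist == 0.0

    def test_rotation_about_own_long_axis_gives_pure_twist(self):
        rng = np.random.default_rng(3)
        cloud = rng.normal(size=(40, 3)) * np.array([10.0, 3.0, 1.5])
        cloud -= cloud.mean(axis=0)
        # find the long axis, rotate the copy 30 deg about it, shift along it
        evals, evecs = np.linalg.eigh(cloud.T @ cloud)
        axis = evecs[:, -1]
        R = Rotation.from_rotvec(np.radians(30.0) * axis).as_matrix()
        copy = cloud @ R.T + 25.0 * axis
        coords = np.vstack([cloud, copy])
        n = len(cloud)
        m = StructureModel(
            coords=coords,
            chain_ids=np.array(["A"] * 2 * n),
            residue_indices=np.arange(1, 2 * n + 1),
            atom_names=np.array(["CA"] * 2 * n),
            elements=np.array(["C"] * 2 * n),
            domain_boundaries=[Domain("A1", "A", 1, n), Domain("A2", "A", n + 1, 2 * n)],
        )
        arr = tilt_twist(m, "A1", "A2")
        assert arr.tilt == pytest.approx(0.0, abs=1e-4)
        assert arr.twist == pytest.approx(30.0, abs=1e-4)

    def test_superhelix_twist_recovered_within_0p1_deg(self, superhelix):
        for a, b in (("M1", "M2"), ("M4", "M5"), ("M8", "M9")):
            arr = tilt_twist(superhelix, a, b)
            assert arr.twist == pytest.approx(26.0, abs=0.1)

    def test_spherical_cloud_flagged_degenerate(self):
        n = 12
        # vertices of an icosahedron: perfectly isotropic inertia
        phi = (1 + math.sqrt(5)) / 2
        verts = []
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                verts += [(0, s1, s2 * phi), (s1, s2 * phi, 0), (s2 * phi, 0, s1)]
        coords = np.array(verts, dtype=float)
        m = StructureModel(
            coords=coords,
            chain_ids=np.array(["A"] * n),
            residue_indices=np.arange(1, n + 1),
            atom_names=np.array(["CA"] * n),
            elements=np.array(["C"] * n),
            domain_boundaries=[Domain("S", "A", 1, n)],
        )
        with pytest.raises(ValueError, match="degenerate"):
            tilt_twist(m, "S", "S")


class TestPairDistanceDistribution:
    def test_two_points(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        dd = pair_distance_distribution(pts, 2.0)
        assert dd.dmax == pytest.approx(10.0)
        assert dd.rg == pytest.approx(5.0)
        assert dd.counts.sum() == 1
        assert dd.counts[np.digitize(10.0, dd.bin_edges) - 1] == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(200, 3)) * 15.0
        dd = pair_distance_distribution(pts, 2.0)
        brute = np.zeros_like(dd.counts)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = float(np.linalg.norm(pts[i] - pts[j]))
                brute[np.searchsorted(dd.bin_edges, d, side="right") - 1] += 1
        assert np.array_equal(brute, dd.counts)
        assert dd.counts.sum() == 200 * 199 / 2

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pair_distance_distribution(np.zeros((1, 3)), 2.0)

    def test_rg_bounded_by_dmax_and_counts_vanish_beyond(self, superhelix):
        dd = pair_distance_distribution(superhelix, 2.0)
        assert dd.rg <= dd.dmax
        nz = np.nonzero(dd.counts)[0]
        assert dd.bin_edges[nz[-1]] <= dd.dmax

    def test_superhelix_pr_maxima_track_module_spacing(self, superhelix):
        """A periodic filament's p(r) shows maxima near multiples of the
        consecutive-centroid spacing."""
        dd = pair_distance_distribution(superhelix, 2.0)
        maxima = dd.maxima(min_r=30.0)
        d1 = neighbor_distance_stats(domain_centroids(superhelix), 1)[0]
        first = maxima[np.argmin(np.abs(maxima - d1))]
        assert abs(first - d1) <= 4.0  # within two bins


class TestRigidMotionInvariance:
    @given(
        angles=st.tuples(*[st.floats(-180.0, 180.0)] * 3),
        shift=st.tuples(*[st.floats(-50.0, 50.0)] * 3),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_geometry_outputs_invariant(self, angles, shift, superhelix):
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        moved = superhelix.transformed(R, np.asarray(shift))
        d0 = pair_distance_distribution(superhelix, 2.0)
        d1 = pair_distance_distribution(moved, 2.0)
        assert np.array_equal(d0.counts, d1.counts)
        assert d1.rg == pytest.approx(d0.rg, rel=1e-9)
        assert d1.dmax == pytest.approx(d0.dmax, rel=1e-9)
        a0 = tilt_twist(superhelix, "M2", "M3")
        a1 = tilt_twist(moved, "M2", "M3")
        assert a1.tilt == pytest.approx(a0.tilt, abs=1e-6)
        assert a1.twist == pytest.approx(a0.twist, abs=1e-6)
        assert a1.centroid_distance == pytest.approx(a0.centroid_distance, rel=1e-9)


class TestSuperhelixBuilder:
    def test_single_module_at_helix_start(self):
        m = build_synthetic_superhelix(1, seed=0)
        assert len(m.domain_boundaries) == 1
        cents = domain_centroids(m)
        assert np.allclose(cents[0][1], [5.0, 0.0, 0.0], atol=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_synthetic_superhelix(0)
        with pytest.raises(ValueError):
            build_synthetic_superhelix(3, radius=-1.0)
        with pytest.raises(ValueError):
            build_synthetic_superhelix(3, points_per_module=2)
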