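"""Geometry: minimum-image distances, slab stoichiometry, Kabsch RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from pepsorb.geometry import (
    Frame, PeriodicBox, SlabModel, backbone_rmsd, extract_distance_series,
    min_image_distance, min_image_distance_matrix, peptide_surface_min_distance,
    residue_surface_min_distances,
)
from pepsorb.series import Condition, read_series

from conftest import make_topology, random_frame


def brute_force_min_image(p1, p2, box: PeriodicBox) -> float:
    """Independent oracle: wrap both points into the primary box, then take
    the minimum over the 27 neighbouring image translations."""
    p1 = np.mod(np.asarray(p1, dtype=float), box.lengths)
    p2 = np.mod(np.asarray(p2, dtype=float), box.lengths)
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz]) * box.lengths
                best = min(best, np.linalg.norm(np.asarray(p2) + shift - p1))
    return best


class TestMinImage:
    def test_wraps_across_boundary(self, cube_box):
        assert min_image_distance((0, 0, 0), (9.9, 0, 0), cube_box) == \
            pytest.approx(0.1)

    def test_identity(self, cube_box):
        assert min_image_distance((1.2, 3.4, 5.6), (1.2, 3.4, 5.6),
                                  cube_box) == 0.0

    def test_matches_27_image_brute_force(self, box):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-1, 2, size=(1000, 2, 3)) * box.lengths
        for p1, p2 in pts:
            assert min_image_distance(p1, p2, box) == \
                pytest.approx(brute_force_min_image(p1, p2, box), abs=1e-12)

    def test_matrix_agrees_with_scalar(self, box):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, size=(5, 3)) * box.lengths
        b = rng.uniform(0, 1, size=(7, 3)) * box.lengths
        mat = min_image_distance_matrix(a, b, box)
        for i in range(5):
            for j in range(7):
                assert mat[i, j] == pytest.approx(
                    min_image_distance(a[i], b[j], box), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(-20, 20), min_size=6, max_size=6))
    def test_symmetric_and_below_naive(self, coords):
        box = PeriodicBox(10.11, 4.90, 10.70)
        p1, p2 = np.array(coords[:3]), np.array(coords[3:])
        d12 = min_image_distance(p1, p2, box)
        assert d12 == pytest.approx(min_image_distance(p2, p1, box), abs=1e-12)
        assert d12 <= np.linalg.norm(p2 - p1) + 1e-12
        assert d12 >= 0.0

    def test_rejects_non_finite(self, cube_box):
        with pytest.raises(ValueError, match="non-finite"):
            min_image_distance((np.nan, 0, 0), (1, 1, 1), cube_box)


class TestSlabModel:
    @pytest.mark.parametrize("n_ti", [1, 10, 3475])
    def test_stoichiometric_build(self, n_ti, box):
        slab = SlabModel.build_stoichiometric(n_ti, box)
        assert slab.n_ti == n_ti
        assert slab.n_o == 2 * n_ti
        assert slab.stoichiometry == pytest.approx(2.0)

    def test_rejects_empty_or_unknown_roles(self):
        with pytest.raises(ValueError):
            SlabModel(positions=np.empty((0, 3)), roles=np.array([]))
        with pytest.raises(ValueError, match="role"):
            SlabModel(positions=np.zeros((1, 3)), roles=np.array(["X"]))


class TestResidueDistances:
    def test_collinear_pair(self, cube_box):
        topo = make_topology([1])
        slab = SlabModel(positions=np.array([[1.0, 1.0, 0.8]]),
                         roles=np.array(["Ti"]))
        frame = Frame(0.0, np.array([[1.0, 1.0, 1.0]]))
        d = residue_surface_min_distances(frame, slab, topo, cube_box,
                                          atom_scope="all")
        assert d == pytest.approx([0.2])

    def test_periodic_image_closer_than_direct(self, cube_box):
        topo = make_topology([1])
        slab = SlabModel(positions=np.array([[0.5, 5.0, 0.2]]),
                         roles=np.array(["Ti"]))
        # atom near the top of the box: image of the slab through z wrap wins
        frame = Frame(0.0, np.array([[0.5, 5.0, 9.9]]))
        d = residue_surface_min_distances(frame, slab, topo, cube_box,
                                          atom_scope="all")
        oracle = brute_force_min_image([0.5, 5.0, 9.9], [0.5, 5.0, 0.2],
                                       cube_box)
        assert d[0] == pytest.approx(oracle, abs=1e-12)
        assert d[0] < 9.7  # beats the unwrapped distance

    def test_identical_residues_identical_distances(self, cube_box, flat_slab):
        topo = make_topology([1, 1])
        frame = Frame(0.0, np.array([[2.0, 2.0, 3.0], [2.0, 2.0, 3.0]]))
        d = residue_surface_min_distances(frame, topo=topo, slab=flat_slab,
                                          box=cube_box, atom_scope="all")
        assert d[0] == d[1]

    def test_peptide_min_is_min_over_residues(self, cube_box, flat_slab):
        rng = np.random.default_rng(3)
        topo = make_topology([3, 4, 3])
        for _ in range(5):
            frame = random_frame(rng, topo, cube_box)
            d_res = residue_surface_min_distances(frame, flat_slab, topo,
                                                  cube_box)
            d_pep = peptide_surface_min_distance(frame, flat_slab, topo,
                                                 cube_box)
            assert d_pep == pytest.approx(d_res.min(), abs=1e-12)

    def test_matches_all_pairs_brute_force(self, cube_box, flat_slab):
        rng = np.random.default_rng(4)
        topo = make_topology([3, 3])
        frame = random_frame(rng, topo, cube_box)
        d_res = residue_surface_min_distances(frame, flat_slab, topo, cube_box,
                                              atom_scope="all")
        for i in range(topo.n_residues):
            atoms = frame.positions[topo.atom_residue_index == i]
            oracle = min(brute_force_min_image(a, s, cube_box)
                         for a in atoms for s in flat_slab.positions)
            assert d_res[i] == pytest.approx(oracle, abs=1e-12)

    def test_atom_count_mismatch_rejected(self, cube_box, flat_slab):
        topo = make_topology([2])
        frame = Frame(0.0, np.zeros((5, 3)))
        with pytest.raises(ValueError, match="atoms"):
            residue_surface_min_distances(frame, flat_slab, topo, cube_box)


def quaternion_superposition_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Independent oracle: optimal-rotation RMSD via Horn's quaternion method."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    ssd = float((pc ** 2).sum() + (qc ** 2).sum() - 2.0 * lam)
    return np.sqrt(max(ssd, 0.0) / p.shape[0])


def rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestBackboneRmsd:
    topo = None

    def setup_method(self):
        self.topo = make_topology([4], all_backbone=True)
        rng = np.random.default_rng(11)
        self.ref = Frame(0.0, rng.normal(size=(4, 3)))

    def test_self_rmsd_zero(self):
        assert backbone_rmsd(self.ref, self.ref, self.topo) == \
            pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        moved = Frame(1.0, self.ref.positions @ rotation_z(np.pi / 2).T
                      + np.array([1.0, 2.0, 3.0]))
        assert backbone_rmsd(moved, self.ref, self.topo) == \
            pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        frame = Frame(1.0, self.ref.positions + 0.05 * rng.normal(size=(4, 3)))
        ab = backbone_rmsd(frame, self.ref, self.topo)
        ba = backbone_rmsd(self.ref, frame, self.topo)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 0

    def test_matches_quaternion_oracle(self):
        ref = Frame(0.0, np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0],
                                   [0.3, 0.3, 0.0], [0.0, 0.3, 0.3]]))
        disp = ref.positions.copy()
        disp[2] += [0.0, 0.0, 0.1]   # one atom displaced by 0.1 nm
        frame = Frame(1.0, disp @ rotation_z(0.7).T + 0.5)
        got = backbone_rmsd(frame, ref, self.topo)
        oracle = quaternion_superposition_rmsd(frame.positions, ref.positions)
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_too_few_or_collinear_backbone_rejected(self):
        tiny = make_topology([2])
        with pytest.raises(ValueError, match="at least 3"):
            backbone_rmsd(Frame(0, np.zeros((2, 3))),
                          Frame(0, np.zeros((2, 3))), tiny)
        line = Frame(0.0, np.array([[0.0, 0, 0], [1.0, 0, 0],
                                    [2.0, 0, 0], [3.0, 0, 0]]))
        with pytest.raises(ValueError, match="collinear"):
            backbone_rmsd(line, line, self.topo)


class TestExtraction:
    def test_hand_computed_three_frames(self, cube_box):
        topo = make_topology([1, 1, 1])
        slab = SlabModel(positions=np.array([[5.0, 5.0, 0.0]]),
                         roles=np.array(["Ti"]))
        heights = [[0.4, 0.2, 0.7], [0.5, 0.9, 0.3], [1.5, 1.1, 2.0]]
        frames = [Frame(10.0 * t, np.array([[5.0, 5.0, h] for h in hs]))
                  for t, hs in enumerate(heights)]
        s = extract_distance_series(frames, slab, topo, cube_box,
                                    Condition("TOY", 1.0, 1),
                                    rmsd_reference=None)
        np.testing.assert_allclose(s.d_res, heights, atol=1e-12)
        np.testing.assert_allclose(s.d_min, [0.2, 0.3, 1.1], atol=1e-12)
        np.testing.assert_allclose(s.times, [0.0, 10.0, 20.0])

    def test_stride(self, cube_box, flat_slab):
        rng = np.random.default_rng(5)
        topo = make_topology([3])
        frames = [random_frame(rng, topo, cube_box, time=10.0 * t)
                  for t in range(10)]
        s = extract_distance_series(frames, flat_slab, topo, cube_box,
                                    Condition("TOY", 1.0, 1), stride=2,
                                    rmsd_reference=None)
        assert s.n_frames == 5
        np.testing.assert_allclose(s.times, [0, 20, 40, 60, 80])

    def test_round_trip_bit_exact(self, cube_box, flat_slab, tmp_path):
        rng = np.random.default_rng(6)
        topo = make_topology([3, 3], ["K", "R"])
        frames = [random_frame(rng, topo, cube_box, time=10.0 * t)
                  for t in range(8)]
        s = extract_distance_series(frames, flat_slab, topo, cube_box,
                                    Condition("KR", 50.0, 3))
        path = s.write(tmp_path / "kr.csv")
        back = read_series(path)
        np.testing.assert_array_equal(back.d_res, s.d_res)
        np.testing.assert_array_equal(back.d_min, s.d_min)
        np.testing.assert_array_equal(back.times, s.times)
        np.testing.assert_array_equal(back.rmsd, s.rmsd)
        assert back.condition == s.condition
        assert back.residue_names == s.residue_names
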