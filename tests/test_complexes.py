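"""Synthetic complex generation, voxelization, blur and splitting."""

import numpy as np
import pytest

from quanvnet.complexes import (
    AtomRecord,
    FeatureGrid,
    N_FEATURES,
    feature_vector,
    gaussian_blur,
    generate_complex,
    stratified_split,
    voxelize,
)


def _atom(element="C", position=(8.0, 8.0, 8.0), vdw=1.7, charge=0.1,
          mol=1, flags=(True, False, True, False, True)):
    return AtomRecord(element=element, position=position, vdw_radius=vdw,
                      hybridization=3, heavy_bonds=2, hetero_bonds=1,
                      structural_flags=flags, partial_charge=charge,
                      molecule_type=mol)


class TestGenerateComplex:
    def test_counts_and_box(self):
        atoms, affinity = generate_complex(0, 50, 10)
        assert len(atoms) == 60
        for a in atoms:
            assert all(0 <= x <= 48 for x in a.position)
        assert 0.0 <= affinity <= 12.0

    def test_deterministic(self):
        a1, f1 = generate_complex(123, 30, 8)
        a2, f2 = generate_complex(123, 30, 8)
        assert f1 == f2
        assert all(x.position == y.position for x, y in zip(a1, a2))

    @pytest.mark.parametrize("n_prot,n_lig", [(0, 5), (5, 0)])
    def test_rejects_empty_molecule(self, n_prot, n_lig):
        with pytest.raises(ValueError):
            generate_complex(0, n_prot, n_lig)


class TestVoxelize:
    def test_single_atom_element_ball(self):
        # carbon centered exactly on a voxel center
        atom = _atom(position=(8.5, 8.5, 8.5), vdw=1.7)
        grid = voxelize([atom], box_size=16.0)
        carbon = grid.values[1]
        centers = np.arange(16) + 0.5
        d2 = ((centers - 8.5)[:, None, None]**2
              + (centers - 8.5)[None, :, None]**2
              + (centers - 8.5)[None, None, :]**2)
        inside = d2 <= 1.7**2
        assert np.array_equal(carbon > 0, inside)
        # every other element channel stays empty
        for ch in (0, 2, 3, 4, 5, 6, 7, 8):
            assert not grid.values[ch].any()

    def test_overlapping_atoms_add(self):
        atom = _atom()
        single = voxelize([atom], box_size=16.0).values
        double = voxelize([atom, atom], box_size=16.0).values
        np.testing.assert_allclose(double, 2 * single)

    def test_small_radius_single_voxel(self):
        # brute-force oracle over all voxel centers
        atom = _atom(position=(8.5, 8.5, 8.5), vdw=0.4)
        grid = voxelize([atom], box_size=16.0)
        centers = np.arange(16) + 0.5
        cnt = 0
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    d2 = ((centers[i] - 8.5)**2 + (centers[j] - 8.5)**2
                          + (centers[k] - 8.5)**2)
                    cnt += d2 <= 0.4**2
        assert cnt == 1
        assert np.count_nonzero(grid.values[1]) == 1

    def test_feature_vector_layout(self):
        atom = _atom(element="O", charge=-0.3, mol=-1)
        v = feature_vector(atom)
        assert v.shape == (N_FEATURES,)
        assert v[3] == 1.0 and v[9] == 3 and v[17] == -0.3 and v[18] == -1

    def test_permutation_invariance(self):
        atoms = [_atom(position=(5.2, 6.1, 7.3)), _atom("O", (9.9, 8.2, 6.6), 1.52),
                 _atom("N", (7.7, 7.7, 7.7), 1.55)]
        a = voxelize(atoms, box_size=16.0).values
        b = voxelize(atoms[::-1], box_size=16.0).values
        np.testing.assert_array_equal(a, b)

    def test_atom_outside_box_rejected(self):
        with pytest.raises(ValueError):
            voxelize([_atom(position=(20.0, 8.0, 8.0))], box_size=16.0)


class TestGaussianBlur:
    def test_zero_grid_stays_zero(self):
        g = FeatureGrid(np.zeros((19, 8, 8, 8), np.float32), 1.0, "z")
        assert not gaussian_blur(g).values.any()

    def test_impulse_mass_conserved(self):
        v = np.zeros((19, 32, 32, 32), np.float32)
        v[0, 16, 16, 16] = 1.0
        out = gaussian_blur(FeatureGrid(v, 2.0, "i"), sigma=1.0)
        assert abs(out.values[0].sum() - 1.0) < 1e-9
        assert out.affinity == 2.0

    def test_matches_dense_convolution_oracle(self):
        # naive triple-loop convolution with the separable truncated kernel
        rng = np.random.default_rng(0)
        v = np.zeros((19, 12, 12, 12), np.float32)
        v[0] = rng.random((12, 12, 12))
        out = gaussian_blur(FeatureGrid(v, 0.0, "r"), sigma=1.0).values[0]
        r = 4
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * x**2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        ref = np.zeros((12, 12, 12))
        src = v[0].astype(np.float64)
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dz in range(-r, r + 1):
                    w = kernel[dx + r, dy + r, dz + r]
                    shifted = np.zeros_like(ref)
                    xs = slice(max(0, -dx), min(12, 12 - dx))
                    ys = slice(max(0, -dy), min(12, 12 - dy))
                    zs = slice(max(0, -dz), min(12, 12 - dz))
                    xd = slice(max(0, dx), min(12, 12 + dx))
                    yd = slice(max(0, dy), min(12, 12 + dy))
                    zd = slice(max(0, dz), min(12, 12 + dz))
                    shifted[xd, yd, zd] = src[xs, ys, zs]
                    ref += w * shifted
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_invalid_sigma(self):
        g = FeatureGrid(np.zeros((19, 8, 8, 8), np.float32), 0.0, "x")
        with pytest.raises(ValueError):
            gaussian_blur(g, sigma=0.0)


class TestStratifiedSplit:
    @staticmethod
    def _grids(affinities):
        return [FeatureGrid(np.zeros((19, 4, 4, 4), np.float32), float(a),
                            f"s{i}") for i, a in enumerate(affinities)]

    def test_exact_arithmetic_100(self):
        grids = self._grids(range(100))
        split = stratified_split(grids, seed=0)
        assert len(split.validation_ids) == 10
        assert len(split.train_ids) == 90
        # two per quintile
        aff = {g.sample_id: g.affinity for g in grids}
        edges = np.percentile(list(aff.values()), [20, 40, 60, 80])
        bins = [int(np.searchsorted(edges, aff[i], side="left"))
                for i in split.validation_ids]
        assert sorted(bins) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_deterministic(self):
        grids = self._grids(np.linspace(0, 11, 37))
        assert stratified_split(grids, seed=5) == stratified_split(grids, seed=5)

    def test_small_set_one_per_quintile(self):
        # brute-force quintile membership for 10 distinct affinities
        grids = self._grids(range(10))
        split = stratified_split(grids, seed=1)
        assert len(split.validation_ids) == 5
        edges = np.percentile(range(10), [20, 40, 60, 80])
        bins = [int(np.searchsorted(edges, float(i[1:]), side="left"))
                for i in split.validation_ids]
        assert sorted(bins) == [0, 1, 2, 3, 4]

    def test_partition_property(self):
        grids = self._grids(np.linspace(0, 11, 23))
        split = stratified_split(grids, seed=9)
        ids = set(split.train_ids) | set(split.validation_ids)
        assert ids == {g.sample_id for g in grids}
        assert not set(split.train_ids) & set(split.validation_ids)

    def test_duplicate_ids_rejected(self):
        grids = self._grids(range(8))
        grids[1].sample_id = grids[0].sample_id
        with pytest.raises(ValueError):
            stratified_split(grids, seed=0)
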