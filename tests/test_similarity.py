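import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atlassel.similarity import (
    RegionMask,
    dice,
    entropy,
    normalized_mi,
    score_4l,
    score_lv,
)
from atlassel.volio import GridError, IntensityVolume, VolumeGrid

from conftest import label_volume

GRID = VolumeGrid((4, 4, 4))


def _mask_from_count(n, total=64, offset=0):
    flat = np.zeros(total, dtype=bool)
    flat[offset:offset + n] = True
    return flat.reshape(4, 4, 4)


def _random_volume(seed, shape=(5, 5, 5)):
    rng = np.random.default_rng(seed)
    return IntensityVolume(VolumeGrid(shape), rng.normal(size=shape))


class TestDice:
    def test_identity_is_one(self):
        m = _mask_from_count(10)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        assert dice(_mask_from_count(5), _mask_from_count(5, offset=10)) == 0.0

    def test_counting_example(self):
        # |a|=4, |b|=6, overlap 3 -> 2*3/(4+6)
        a = _mask_from_count(4)
        b = _mask_from_count(6, offset=1)  # shares voxels 1..3 with a
        assert dice(a, b) == pytest.approx(2 * 3 / (4 + 6))

    def test_empty_empty_convention(self, caplog):
        with caplog.at_level("WARNING"):
            assert dice(_mask_from_count(0), _mask_from_count(0)) == 1.0
        assert "empty" in caplog.text
        assert dice(_mask_from_count(0), _mask_from_count(3)) == 0.0

    def test_incompatible_grids_rejected(self):
        a = RegionMask(VolumeGrid((4, 4, 4)), _mask_from_count(3))
        b = RegionMask(VolumeGrid((4, 4, 4), (2, 2, 2)), _mask_from_count(3))
        with pytest.raises(GridError):
            dice(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((4, 4, 4)) < 0.4
        b = rng.random((4, 4, 4)) < 0.4
        d_ab, d_ba = dice(a, b), dice(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        if a.any():
            assert dice(a, a) == 1.0


class TestEntropy:
    def test_constant_region_zero_bits(self):
        img = IntensityVolume(GRID, np.full((4, 4, 4), 3.7))
        assert entropy(img) == 0.0

    def test_uniform_eight_bins_three_bits(self):
        # 64 voxels filling 8 bins equally -> log2(8) bits
        values = np.repeat(np.arange(8, dtype=float), 8).reshape(4, 4, 4)
        assert entropy(IntensityVolume(GRID, values), n_bins=8) == pytest.approx(3.0)

    def test_two_bin_example(self):
        # p = (0.25, 0.75): H = -(0.25 log2 0.25 + 0.75 log2 0.75) = 0.8113
        values = np.zeros(64)
        values[:48] = 1.0
        img = IntensityVolume(GRID, values.reshape(4, 4, 4))
        assert entropy(img, n_bins=2) == pytest.approx(0.811278, abs=1e-5)

    def test_invariant_under_bin_permutation(self):
        # Entropy depends only on the multiset of bin probabilities.
        v1 = np.repeat([0.0, 1.0, 2.0, 3.0], [32, 16, 8, 8]).reshape(4, 4, 4)
        v2 = np.repeat([0.0, 1.0, 2.0, 3.0], [8, 32, 8, 16]).reshape(4, 4, 4)
        h1 = entropy(IntensityVolume(GRID, v1), n_bins=4)
        h2 = entropy(IntensityVolume(GRID, v2), n_bins=4)
        assert h1 == pytest.approx(h2)

    def test_empty_mask_rejected(self):
        img = IntensityVolume(GRID, np.arange(64, dtype=float).reshape(4, 4, 4))
        with pytest.raises(ValueError, match="empty mask"):
            entropy(img, mask=np.zeros((4, 4, 4), dtype=bool))


class TestNormalizedMI:
    def test_self_similarity_is_two(self):
        a = _random_volume(1)
        assert normalized_mi(a, a) == pytest.approx(2.0)

    def test_independent_volumes_near_one(self):
        # Permuting voxels destroys spatial correspondence; identical
        # marginals, (near-)independent joint -> NMI -> 1.
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(12, 12, 12))
        perm = rng.permutation(vals.ravel()).reshape(vals.shape)
        grid = VolumeGrid((12, 12, 12))
        nmi = normalized_mi(
            IntensityVolume(grid, vals), IntensityVolume(grid, perm), n_bins=8
        )
        assert nmi == pytest.approx(1.0, abs=0.02)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_range(self, seed):
        a = _random_volume(seed)
        b = _random_volume(seed + 100_000)
        ab = normalized_mi(a, b)
        ba = normalized_mi(b, a)
        assert ab == pytest.approx(ba, rel=1e-12)
        assert 1.0 <= ab <= 2.0 + 1e-12

    def test_constant_volume_rejected(self):
        a = _random_volume(3, (4, 4, 4))
        const = IntensityVolume(GRID, np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="constant"):
            normalized_mi(a, const)


def _coarse_pair(target_ids, atlas_ids):
    return label_volume(np.array(target_ids)), label_volume(np.array(atlas_ids))


class TestCoarseScores:
    def test_4l_identity(self, clean_phantom):
        assert score_4l(clean_phantom.coarse, clean_phantom.coarse) == 1.0

    def test_4l_is_mean_of_per_label_dices(self, default_library8):
        lib, _ = default_library8
        a, b = lib[lib.ids[0]].coarse, lib[lib.ids[-1]].coarse
        per_label = [dice(a.mask(c), b.mask(c)) for c in (1, 2, 3, 4)]
        assert score_4l(a, b) == pytest.approx(np.mean(per_label))

    def test_4l_disjoint_labels_zero(self):
        t = np.zeros((4, 4, 4), dtype=np.int32)
        a = np.zeros((4, 4, 4), dtype=np.int32)
        t[0], a[1] = np.arange(1, 5)[:, None], np.arange(1, 5)[:, None]
        assert score_4l(label_volume(t), label_volume(a)) == 0.0

    def test_lv_counting_example(self):
        # 100 vs 140 ventricle voxels sharing 90 -> 180/240
        t = np.zeros((10, 10, 10), dtype=np.int32)
        a = np.zeros((10, 10, 10), dtype=np.int32)
        t.ravel()[:100] = 4
        a.ravel()[10:150] = 4
        got = score_lv(label_volume(t), label_volume(a))
        assert got == pytest.approx(180 / 240)

    def test_lv_empty_empty(self, caplog):
        t = np.zeros((3, 3, 3), dtype=np.int32)
        with caplog.at_level("WARNING"):
            assert score_lv(label_volume(t), label_volume(t.copy())) == 1.0

    def test_non_coarse_ids_rejected(self):
        bad = np.zeros((3, 3, 3), dtype=np.int32)
        bad[0, 0, 0] = 9
        with pytest.raises(ValueError, match="non-coarse"):
            score_4l(label_volume(bad), label_volume(np.zeros((3, 3, 3), dtype=np.int32)))
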