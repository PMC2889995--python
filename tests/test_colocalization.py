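import itertools

import numpy as np
import pytest

from granuloc import (
    Punctum,
    PunctaSet,
    Stack,
    VoxelGeometry,
    is_colocalized,
    line_intensity_profile,
    overlap_fraction,
    percent_colocalization,
    triple_colocalization,
)


def make_punctum(pid, channel, voxels):
    voxels = frozenset(voxels)
    arr = np.array(sorted(voxels))
    centroid = tuple(arr.mean(axis=0))
    return Punctum(id=pid, channel=channel, voxels=voxels, centroid=centroid, peak_intensity=1.0)


def make_set(channel, voxel_groups, shape=(4, 32, 32)):
    labels = np.zeros(shape, dtype=np.int32)
    puncta = []
    for i, vox in enumerate(voxel_groups, start=1):
        p = make_punctum(i, channel, vox)
        puncta.append(p)
        for v in vox:
            labels[v] = i
    return PunctaSet(puncta=puncta, channel=channel, shape=shape, labels=labels)


def random_sets(rng, n_per_channel, channels=("a", "b"), shape=(4, 32, 32)):
    """Random blobby puncta; overlap across channels arises by chance."""
    sets = []
    for ch in channels:
        groups = []
        for _ in range(n_per_channel):
            z = rng.integers(0, shape[0])
            y, x = rng.integers(2, shape[1] - 2), rng.integers(2, shape[2] - 2)
            size = rng.integers(1, 8)
            vox = {(z, y, x)}
            while len(vox) < size:
                dz, dy, dx = rng.integers(-1, 2, size=3)
                vz = min(max(z + dz, 0), shape[0] - 1)
                vox.add((vz, min(max(y + dy, 0), shape[1] - 1), min(max(x + dx, 0), shape[2] - 1)))
            groups.append(vox)
        # drop same-channel voxel collisions to keep sets disjoint
        used: set = set()
        clean = []
        for gconv in groups:
            g2 = {v for v in gconv if v not in used}
            if g2:
                used |= g2
                clean.append(g2)
        sets.append(make_set(ch, clean, shape))
    return sets


def brute_force_percent(ref, target, threshold):
    """O(n^2) all-pairs evaluation with set intersections."""
    events = 0
    for p in ref.puncta:
        for q in target.puncta:
            inter = len(p.voxels & q.voxels)
            if inter / min(p.size, q.size) > threshold:
                events += 1
                break
    return 100.0 * events / len(ref)


class TestOverlapFraction:
    def test_identical_sets(self):
        a = make_punctum(1, "a", [(0, 1, 1), (0, 1, 2)])
        b = make_punctum(1, "b", [(0, 1, 1), (0, 1, 2)])
        assert overlap_fraction(a, b) == 1.0
        assert overlap_fraction(b, a) == 1.0  # symmetric

    def test_disjoint_sets(self):
        a = make_punctum(1, "a", [(0, 1, 1)])
        b = make_punctum(1, "b", [(0, 5, 5)])
        assert overlap_fraction(a, b) == 0.0

    def test_fraction_of_smaller_object(self):
        a = make_punctum(1, "a", [(0, 0, x) for x in range(10)])
        b = make_punctum(1, "b", [(0, 0, x) for x in range(6, 16)])
        assert overlap_fraction(a, b) == pytest.approx(0.4)

    def test_same_channel_rejected(self):
        a = make_punctum(1, "a", [(0, 1, 1)])
        b = make_punctum(2, "a", [(0, 1, 1)])
        with pytest.raises(ValueError, match="same channel"):
            overlap_fraction(a, b)


class TestIsColocalized:
    def test_threshold_is_strict(self):
        # 31/100 voxels shared -> colocalized; exactly 30/100 -> not
        a31 = make_punctum(1, "a", [(0, 0, x) for x in range(100)])
        b31 = make_punctum(1, "b", [(0, 0, x) for x in range(69, 169)])
        assert overlap_fraction(a31, b31) == pytest.approx(0.31)
        assert is_colocalized(a31, b31)
        b30 = make_punctum(2, "b", [(0, 0, x) for x in range(70, 170)])
        assert overlap_fraction(a31, b30) == pytest.approx(0.30)
        assert not is_colocalized(a31, b30)

    def test_invalid_threshold_rejected(self):
        a = make_punctum(1, "a", [(0, 1, 1)])
        b = make_punctum(1, "b", [(0, 1, 1)])
        with pytest.raises(ValueError):
            is_colocalized(a, b, threshold=1.0)


class TestPercentColocalization:
    def test_three_of_ten(self):
        ref_groups = [[(0, y, 0), (0, y, 1)] for y in range(10)]
        tgt_groups = [[(0, y, 0), (0, y, 1)] for y in range(3)]
        ref = make_set("a", ref_groups)
        tgt = make_set("b", tgt_groups)
        res = percent_colocalization(ref, tgt)
        assert res.n_ref_events == 10 and res.n_coloc_events == 3
        assert res.percent == pytest.approx(30.0)

    def test_empty_target_gives_zero(self):
        ref = make_set("a", [[(0, 1, 1)]])
        tgt = make_set("b", [])
        res = percent_colocalization(ref, tgt)
        assert res.percent == 0.0

    def test_empty_ref_rejected(self):
        ref = make_set("a", [])
        tgt = make_set("b", [[(0, 1, 1)]])
        with pytest.raises(ValueError, match="empty"):
            percent_colocalization(ref, tgt)

    def test_one_ref_event_despite_two_partners(self):
        ref = make_set("a", [[(0, 5, x) for x in range(4)]])
        tgt = make_set("b", [[(0, 5, 0), (0, 5, 1)], [(0, 5, 2), (0, 5, 3)]])
        res = percent_colocalization(ref, tgt)
        assert res.n_coloc_events == 1
        assert len(res.pairs) == 2  # both partners recorded

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref, tgt = random_sets(rng, 40)
        for threshold in (0.0, 0.30, 0.5):
            res = percent_colocalization(ref, tgt, threshold)
            assert res.percent == pytest.approx(brute_force_percent(ref, tgt, threshold))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        ref, tgt = random_sets(rng, 50)
        percents = [
            percent_colocalization(ref, tgt, t).percent for t in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert percents == sorted(percents, reverse=True)

    def test_directional_pairs_are_transposes(self):
        rng = np.random.default_rng(5)
        ref, tgt = random_sets(rng, 40)
        fwd = percent_colocalization(ref, tgt, 0.3)
        rev = percent_colocalization(tgt, ref, 0.3)
        fwd_pairs = {(r, t) for r, t, _ in fwd.pairs}
        rev_pairs = {(t, r) for r, t, _ in rev.pairs}
        assert fwd_pairs == rev_pairs


class TestTripleColocalization:
    def test_three_identical_sets(self):
        groups = [[(0, y, 0), (0, y, 1)] for y in range(5)]
        a, b, c = (make_set(ch, groups) for ch in "abc")
        res = triple_colocalization(a, b, c)
        assert res.n_triple == 5

    def test_any_empty_set_gives_zero(self):
        a = make_set("a", [[(0, 1, 1)]])
        b = make_set("b", [])
        c = make_set("c", [[(0, 1, 1)]])
        assert triple_colocalization(a, b, c).n_triple == 0

    def test_distinct_channels_required(self):
        a = make_set("a", [[(0, 1, 1)]])
        b = make_set("a", [[(0, 1, 1)]])
        c = make_set("c", [[(0, 1, 1)]])
        with pytest.raises(ValueError, match="distinct"):
            triple_colocalization(a, b, c)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_matches_exhaustive_triple_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = random_sets(rng, 30, channels=("a", "b", "c"))
        res = triple_colocalization(a, b, c, 0.3)
        n_expected = 0
        for p in a.puncta:  # brute force over all (p, q, r) partner pairs
            hit_b = any(
                len(p.voxels & q.voxels) / min(p.size, q.size) > 0.3 for q in b.puncta
            )
            hit_c = any(
                len(p.voxels & r.voxels) / min(p.size, r.size) > 0.3 for r in c.puncta
            )
            n_expected += hit_b and hit_c
        assert res.n_triple == n_expected

    def test_triple_never_exceeds_pairwise(self):
        rng = np.random.default_rng(9)
        a, b, c = random_sets(rng, 30, channels=("a", "b", "c"))
        res = triple_colocalization(a, b, c, 0.3)
        for cres in res.pairwise.values():
            assert res.n_triple <= cres.n_ref_events
        ab = res.pairwise[("a", "b")]
        ac = res.pairwise[("a", "c")]
        assert res.n_triple <= min(ab.n_coloc_events, ac.n_coloc_events)


class TestLineIntensityProfile:
    def _stack(self, arr):
        geo = VoxelGeometry(pixel_size_xy=0.2)
        return Stack(channels={"ch": np.asarray(arr)}, geometry=geo)

    def test_constant_row(self):
        img = np.full((1, 8, 8), 7.0)
        prof = line_intensity_profile(self._stack(img), (3, 0), (3, 7))
        np.testing.assert_array_equal(prof["ch"], np.full(8, 7.0))

    def test_ramp_is_monotone(self):
        img = np.tile(np.arange(16.0), (16, 1))[None]
        prof = line_intensity_profile(self._stack(img), (2, 0), (13, 15))
        assert np.all(np.diff(prof["ch"]) >= 0)

    def test_diagonal_matches_bresenham_oracle(self):
        from skimage.draw import line

        rng = np.random.default_rng(12)
        img = rng.integers(0, 256, size=(2, 20, 20)).astype(np.uint8)
        prof = line_intensity_profile(self._stack(img), (1, 2), (17, 13), z=1)
        rr, cc = line(1, 2, 17, 13)
        expected = np.array([img[1, r, c] for r, c in zip(rr, cc)])
        np.testing.assert_array_equal(prof["ch"], expected)

    def test_out_of_bounds_endpoint_rejected(self):
        img = np.zeros((1, 8, 8))
        with pytest.raises(ValueError, match="outside"):
            line_intensity_profile(self._stack(img), (0, 0), (8, 3))
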