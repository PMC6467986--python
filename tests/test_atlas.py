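"""Atlas statistics, single-case t-maps, cluster filtering and the
leave-one-out outlier screen."""

import numpy as np
import pytest
from scipy import stats

import wbatlas as wb
from wbatlas.errors import DataError
from wbatlas.grids import ChannelKind, LabelMap, SubjectDataset, VolumeGrid


def _make_subject(rng, shape=(8, 8, 8), sid="s", jitter=True):
    fat = np.clip(np.full(shape, 0.3)
                  + (rng.normal(0, 0.05, shape) if jitter else 0.0), 0, 1)
    sub = SubjectDataset(
        sid,
        VolumeGrid(fat, (4, 4, 4), (0, 0, 0), ChannelKind.FRACTION),
        VolumeGrid(1 - fat, (4, 4, 4), (0, 0, 0), ChannelKind.FRACTION),
        VolumeGrid(rng.random(shape) + 1, (4, 4, 4), (0, 0, 0)),
        75, 150, space="reference")
    sub.normalized_fdg = VolumeGrid(rng.random(shape) + 0.5, (4, 4, 4), (0, 0, 0),
                                    ChannelKind.NORMALIZED)
    return sub


def _labels(shape=(8, 8, 8)):
    return LabelMap(np.ones(shape, np.int16), {1: "body"}, (4, 4, 4), (0, 0, 0))


def _zero_jacs(n, shape=(8, 8, 8)):
    zero = wb.DisplacementField(np.zeros(shape + (3,)), (4, 4, 4), (0, 0, 0))
    return [wb.jacobian(zero) for _ in range(n)]


class TestBuildAtlas:
    def test_matches_bruteforce_stack_statistics(self):
        rng = np.random.default_rng(0)
        subs = [_make_subject(rng, sid=f"s{i}") for i in range(6)]
        atlas = wb.build_atlas(subs, _zero_jacs(6), _labels())
        for ch, getter in [("fat_fraction", lambda s: s.fat.data),
                           ("water_fraction", lambda s: s.water.data),
                           ("normalized_fdg", lambda s: s.normalized_fdg.data)]:
            stack = np.stack([getter(s) for s in subs])
            np.testing.assert_allclose(atlas.means[ch].data, stack.mean(0),
                                       atol=1e-6)
            np.testing.assert_allclose(atlas.sds[ch].data, stack.std(0, ddof=1),
                                       atol=1e-6)

    def test_two_identical_subjects_give_zero_sd(self):
        rng = np.random.default_rng(1)
        a = _make_subject(rng, sid="a")
        b = _make_subject(np.random.default_rng(1), sid="b")
        atlas = wb.build_atlas([a, b], _zero_jacs(2), _labels())
        for ch in wb.atlas.ATLAS_CHANNELS:
            assert np.all(atlas.sds[ch].data == 0)
            np.testing.assert_allclose(atlas.means["fat_fraction"].data, a.fat.data)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        a = _make_subject(rng, sid="a")
        b = _make_subject(rng, shape=(9, 8, 8), sid="b")
        with pytest.raises(DataError):
            wb.build_atlas([a, b], _zero_jacs(2), _labels())

    def test_atlas_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        subs = [_make_subject(rng, sid=f"s{i}") for i in range(3)]
        atlas = wb.build_atlas(subs, _zero_jacs(3), _labels())
        atlas.save(tmp_path / "atlas")
        back = wb.Atlas.load(tmp_path / "atlas")
        assert back.n_subjects == 3 and back.contributor_ids == ["s0", "s1", "s2"]
        np.testing.assert_allclose(back.means["fat_fraction"].data,
                                   atlas.means["fat_fraction"].data.astype(np.float32))


class TestSingleCaseT:
    def _vols(self, x, mu, sd):
        g = lambda d: VolumeGrid(np.asarray(d, float), (4, 4, 4), (0, 0, 0))
        return g(x), g(mu), g(sd)

    def test_subject_at_group_mean(self):
        x, mu, sd = self._vols(np.full((3, 3, 3), 2.0), np.full((3, 3, 3), 2.0),
                               np.ones((3, 3, 3)))
        t, p = wb.single_case_tmap(x, mu, sd, 3)
        assert np.all(t.data == 0) and np.all(p.data == 1)

    def test_closed_form_value_for_small_group(self):
        # group {1,2,3}: mean 2, sd 1, n 3; x = 10
        # t = 8 / sqrt(1 + 1/3) = 6.928, df = 2
        x, mu, sd = self._vols([[[10.0]]], [[[2.0]]], [[[1.0]]])
        t, p = wb.single_case_tmap(x, mu, sd, 3)
        assert t.data[0, 0, 0] == pytest.approx(8 / np.sqrt(4 / 3), abs=1e-3)
        assert t.data[0, 0, 0] == pytest.approx(6.928, abs=1e-3)
        assert p.data[0, 0, 0] == pytest.approx(2 * stats.t.sf(6.9282, 2), rel=1e-6)

    def test_zero_sd_handling(self):
        x, mu, sd = self._vols([[[2.0, 5.0]]], [[[2.0, 2.0]]], [[[0.0, 0.0]]])
        t, p = wb.single_case_tmap(x, mu, sd, 4)
        assert p.data[0, 0, 0] == 1.0 and p.data[0, 0, 1] == 0.0
        assert t.n_zero_sd == 2

    def test_null_calibration_at_p001(self):
        rng = np.random.default_rng(11)
        shape = (40, 40, 40)
        group = rng.standard_normal((12,) + shape)
        x, mu, sd = self._vols(rng.standard_normal(shape), group.mean(0),
                               group.std(0, ddof=1))
        _, p = wb.single_case_tmap(x, mu, sd, 12)
        rate = float((p.data < 0.001).mean())
        n = np.prod(shape)
        ci = 2.576 * np.sqrt(0.001 * 0.999 / n)
        assert abs(rate - 0.001) < ci + 1e-12

    def test_loo_group_stats_match_direct_recomputation(self):
        rng = np.random.default_rng(7)
        stack = rng.random((9, 5, 5, 5))
        mean, sd = stack.mean(0), stack.std(0, ddof=1)
        lm, ls = wb.loo_group_stats(mean, sd, 9, stack[4])
        rest = np.delete(stack, 4, axis=0)
        np.testing.assert_allclose(lm, rest.mean(0), atol=1e-10)
        np.testing.assert_allclose(ls, rest.std(0, ddof=1), atol=1e-8)


def _flood_fill_26(mask):
    """Brute-force 26-connected components for the oracle."""
    comps = np.zeros(mask.shape, int)
    nxt = 0
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask & (comps == 0))):
        if comps[start]:
            continue
        nxt += 1
        stack = [start]
        comps[start] = nxt
        while stack:
            v = stack.pop()
            for o in offs:
                w = tuple(np.add(v, o))
                if all(0 <= w[a] < mask.shape[a] for a in range(3)) \
                        and mask[w] and not comps[w]:
                    comps[w] = nxt
                    stack.append(w)
    return comps, nxt


class TestClusterFilter:
    def _pmap(self, sig):
        return VolumeGrid(np.where(sig, 0.0, 1.0), (4, 4, 4), (0, 0, 0),
                          ChannelKind.PVALUE)

    @pytest.mark.parametrize("n_vox,kept", [(9, False), (10, True)])
    def test_minimum_cluster_extent(self, n_vox, kept):
        sig = np.zeros((8, 8, 12), bool)
        sig[1, 2, :n_vox] = True
        cmap, sizes = wb.cluster_filter(self._pmap(sig), 0.05, 10,
                                        np.ones((8, 8, 12), bool))
        assert bool(sizes) is kept
        if kept:
            assert sizes == {1: 10}

    def test_corner_contact_is_one_component(self):
        sig = np.zeros((6, 6, 6), bool)
        sig[0:2, 0:2, 0:2] = True
        sig[2:4, 2:4, 2:4] = True  # touches only at the corner voxel diagonal
        cmap, sizes = wb.cluster_filter(self._pmap(sig), 0.05, 1,
                                        np.ones((6, 6, 6), bool))
        assert len(sizes) == 1 and sizes[1] == 16

    def test_matches_bruteforce_flood_fill(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            sig = rng.random((5, 5, 5)) < 0.3
            cmap, sizes = wb.cluster_filter(self._pmap(sig), 0.05, 1,
                                            np.ones((5, 5, 5), bool))
            oracle, n = _flood_fill_26(sig)
            assert len(sizes) == n
            assert sorted(sizes.values()) == sorted(
                np.bincount(oracle.ravel())[1:].tolist())


class TestLooBias:
    def _cohort(self, seed=0, n=5, planted=None):
        rng = np.random.default_rng(seed)
        subs = []
        for i in range(n):
            s = _make_subject(rng, shape=(10, 10, 10), sid=f"s{i}", jitter=False)
            base = 1.0 + rng.normal(0, 0.05, (10, 10, 10))
            if planted is not None and i == planted:
                base[2:8, 2:8, 2:8] += 1.0
            s.normalized_fdg = VolumeGrid(base, (4, 4, 4), (0, 0, 0),
                                          ChannelKind.NORMALIZED)
            subs.append(s)
        return subs

    def test_counts_invariant_to_subject_order(self):
        subs = self._cohort(seed=1)
        body = np.ones((10, 10, 10), bool)
        cfg = wb.QCConfig(min_voxels=2, flag_abs_floor=10)
        r1 = wb.loo_bias_assessment(subs, body, cfg)
        r2 = wb.loo_bias_assessment(subs[::-1], body, cfg)
        assert r1.counts == r2.counts

    def test_counts_invariant_to_global_scale(self):
        subs = self._cohort(seed=2)
        body = np.ones((10, 10, 10), bool)
        cfg = wb.QCConfig(min_voxels=2, flag_abs_floor=10)
        r1 = wb.loo_bias_assessment(subs, body, cfg)
        for s in subs:
            s.normalized_fdg = s.normalized_fdg.with_data(s.normalized_fdg.data * 3.7)
        r2 = wb.loo_bias_assessment(subs, body, cfg)
        assert r1.counts == r2.counts

    def test_planted_hot_subject_flagged(self):
        subs = self._cohort(seed=3, planted=2)
        body = np.ones((10, 10, 10), bool)
        rep = wb.loo_bias_assessment(subs, body, wb.QCConfig(flag_abs_floor=20))
        assert rep.flagged == ["s2"]
        assert rep.sorted_counts()[0][0] == "s2"
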