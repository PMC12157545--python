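import itertools

import numpy as np
import pytest
from scipy import stats as sstats

import cstract as cs
from cstract.core import MaskVolume, VolumeGrid
from cstract.stats import (bonferroni, group_compare, mann_whitney, pair_similarity,
                           termination_maps, topography_order, twin_analysis)
from cstract.tracking import PathDistribution


def _pd(grid, values, n=1000):
    return PathDistribution(grid, np.asarray(values, float), n)


class TestPairSimilarity:
    def test_self_similarity_is_one(self):
        grid = VolumeGrid.isotropic((4, 3, 2), 1.0)
        rng = np.random.default_rng(0)
        maps = {"a": _pd(grid, rng.random(grid.shape) * 0.1),
                "b": _pd(grid, rng.random(grid.shape) * 0.1)}
        r, per = pair_similarity(maps, maps)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pearson_on_five_voxels(self):
        grid = VolumeGrid.isotropic((5, 1, 1), 1.0)
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5]).reshape(5, 1, 1)
        b = np.array([0.5, 0.1, 0.4, 0.2, 0.3]).reshape(5, 1, 1)
        r, per = pair_similarity({"t": _pd(grid, a)}, {"t": _pd(grid, b)},
                                 threshold=0.0)
        xs, ys = a.ravel(), b.ravel()
        hand = (np.mean(xs * ys) - xs.mean() * ys.mean()) / (xs.std() * ys.std())
        assert per["t"] == pytest.approx(hand, abs=1e-12)

    def test_disjoint_indicator_maps_anticorrelate(self):
        grid = VolumeGrid.isotropic((8, 1, 1), 1.0)
        a = np.zeros(grid.shape); a[:4] = 0.2
        b = np.zeros(grid.shape); b[4:] = 0.2
        r, _ = pair_similarity({"t": _pd(grid, a)}, {"t": _pd(grid, b)}, threshold=0.01)
        assert r <= 0

    def test_union_support_semantics(self):
        # voxels surviving in either map enter the correlation
        grid = VolumeGrid.isotropic((6, 1, 1), 1.0)
        a = np.array([0.3, 0.3, 0.3, 0.0, 0.0, 0.0]).reshape(6, 1, 1)
        b = np.array([0.3, 0.3, 0.0, 0.3, 0.0, 0.0]).reshape(6, 1, 1)
        _, per = pair_similarity({"t": _pd(grid, a)}, {"t": _pd(grid, b)}, threshold=0.1)
        xs = np.array([0.3, 0.3, 0.3, 0.0])
        ys = np.array([0.3, 0.3, 0.0, 0.3])
        hand = np.corrcoef(xs, ys)[0, 1]
        assert per["t"] == pytest.approx(hand, abs=1e-12)

    def test_no_common_tracts_rejected(self):
        grid = VolumeGrid.isotropic((2, 2, 2), 1.0)
        with pytest.raises(ValueError):
            pair_similarity({"a": _pd(grid, np.zeros(grid.shape))},
                            {"b": _pd(grid, np.zeros(grid.shape))})


def _exact_two_sided_p(x, y):
    """Brute-force two-sided Mann-Whitney p by full reassignment enumeration."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(sel):
        ranks = sstats.rankdata(pooled)
        # recompute U from scratch for the permuted assignment
        xs = pooled[list(sel)]
        ys = np.delete(pooled, list(sel))
        r = sstats.rankdata(np.concatenate([xs, ys]))
        return r[: len(xs)].sum() - len(xs) * (len(xs) + 1) / 2

    centre = n1 * (len(pooled) - n1) / 2
    obs = abs(u_of(range(n1)) - centre)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(comb) - centre) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_textbook_separated_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2,tie", [(3, 3, False), (4, 5, False),
                                           (5, 4, True), (6, 6, True), (8, 7, True)])
    def test_exact_path_matches_enumeration_oracle(self, n1, n2, tie):
        rng = np.random.default_rng(n1 * 10 + n2 + tie)
        x = rng.integers(0, 6 if tie else 1000, size=n1).astype(float)
        y = rng.integers(0, 6 if tie else 1000, size=n2).astype(float)
        u, p = mann_whitney(x, y)
        assert p == pytest.approx(_exact_two_sided_p(x, y), abs=1e-12)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        u, p = mann_whitney(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestGroupCompare:
    def test_bonferroni_monotone_and_capped(self):
        adj = bonferroni({"a": 0.02, "b": 0.5, "c": 0.9, "d": 0.001})
        assert adj["a"] == pytest.approx(0.08)
        assert adj["b"] == 1.0 and adj["c"] == 1.0
        assert adj["d"] < adj["a"]

    def test_identical_groups_not_significant(self):
        vals = {"g1": np.arange(10.0), "g2": np.arange(10.0)}
        out = group_compare(vals, [("g1", "g2")])
        assert out["g1-g2"]["p_adjusted"] > 0.9

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare({"a": np.array([1.0]), "b": np.arange(5.0)}, [("a", "b")])


class TestTwinAnalysis:
    def test_zero_perturbation_cohort_all_similarities_one(self, mini_base):
        from cstract.tracking import Constraints, TrackingParams, run_seed_region
        coh = cs.build_cohort(mini_base.field, {"MZ": 3, "UNREL": 3},
                              {"MZ": 0.9, "UNREL": 0.0}, rng_seed=0,
                              rot_scale_deg=0.0, frac_scale=0.0)
        params = TrackingParams(rng_seed=7, step_mm=0.5, seeds_per_voxel=10, max_steps=200)
        recon = {}
        for sid, fld in coh.subjects:
            pd, _ = run_seed_region(fld, mini_base.masks["west_l"],
                                    Constraints(waypoints=[mini_base.masks["east_l"]]),
                                    params, "assoc")
            recon[sid] = {"assoc": pd}
        rep = twin_analysis(coh, recon)
        assert all(v == pytest.approx(1.0) for v in rep["medians"].values())
        assert rep["tests"]["MZ-UNREL"]["p_adjusted"] > 0.9

    def test_missing_reconstruction_named(self, mini_base):
        coh = cs.build_cohort(mini_base.field, {"MZ": 2}, {"MZ": 1.0}, rng_seed=0)
        with pytest.raises(ValueError, match=coh.subjects[0][0]):
            twin_analysis(coh, {})


class TestTerminationMaps:
    def _nucleus(self):
        g = VolumeGrid.isotropic((6, 6, 6), 1.0)
        m = MaskVolume.empty(g, "nuc")
        m.membership[1:5, 1:5, 1:5] = True
        return m

    def test_single_voxel_group(self):
        nuc = self._nucleus()
        maps = termination_maps([("g", np.array([[2, 2, 2]] * 5))], nuc, smooth=False)
        pre = maps["g"].pre_smoothing.values
        assert pre[2, 2, 2] == 1.0 and pre.sum() == 1.0

    def test_counting_oracle_matches_empirical_frequencies(self):
        nuc = self._nucleus()
        rng = np.random.default_rng(0)
        vox = nuc.voxel_indices()
        draws = vox[rng.integers(0, len(vox), 200)]
        maps = termination_maps([("g", draws)], nuc, smooth=False)
        counts = np.zeros(nuc.grid.shape)
        for v in draws:
            counts[tuple(v)] += 1
        np.testing.assert_allclose(maps["g"].pre_smoothing.values, counts / 200,
                                   atol=1e-15)

    def test_disjoint_groups_disjoint_supports_and_unit_sums(self):
        nuc = self._nucleus()
        a = np.array([[1, 1, 1], [1, 2, 1]])
        b = np.array([[4, 4, 4], [4, 3, 4], [4, 4, 3]])
        maps = termination_maps([("A", a), ("B", b)], nuc)
        pa = maps["A"].pre_smoothing.values
        pb = maps["B"].pre_smoothing.values
        assert not ((pa > 0) & (pb > 0)).any()
        assert pa.sum() == pytest.approx(1.0, abs=1e-12)
        assert pb.sum() == pytest.approx(1.0, abs=1e-12)
        assert (maps["A"].probabilities.values >= 0).all()

    def test_terminations_outside_nucleus_excluded_group_warns(self):
        nuc = self._nucleus()
        with pytest.warns(UserWarning):
            maps = termination_maps([("out", np.array([[0, 0, 0]]))], nuc)
        assert "out" not in maps


class TestTopographyOrder:
    def _maps(self):
        g = VolumeGrid.isotropic((10, 4, 4), 1.0)
        out = {}
        for i, name in enumerate(["a", "b", "c"]):
            v = np.zeros(g.shape)
            v[2 + 3 * i, 1, 1] = 1.0
            out[name] = v
        return out

    def test_known_sectors_recover_ordering(self):
        rep = topography_order(self._maps(), np.array([1.0, 0, 0]),
                               ground_truth=["a", "b", "c"])
        assert rep["ordering"] == ["a", "b", "c"]
        assert rep["matches_ground_truth"]

    def test_axis_flip_reverses_ordering(self):
        fwd = topography_order(self._maps(), np.array([1.0, 0, 0]))
        rev = topography_order(self._maps(), np.array([-1.0, 0, 0]))
        assert rev["ordering"] == fwd["ordering"][::-1]

    def test_zero_mass_map_excluded_with_warning(self):
        maps = self._maps()
        maps["empty"] = np.zeros((10, 4, 4))
        with pytest.warns(UserWarning):
            rep = topography_order(maps, np.array([1.0, 0, 0]))
        assert "empty" not in rep["axis_coordinates"]
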