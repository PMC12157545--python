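import numpy as np
import pytest

import cstract as cs
from cstract.blueprints import (assemble, cortical_blueprint, gm_by_wm,
                                group_average_blueprints, subcortical_blueprint,
                                tract_specificity, wm_by_tracts)
from cstract.core import MaskVolume, VolumeGrid
from cstract.pipeline import blueprint_nuclei, build_species_blueprint
from cstract.tracking import PathDistribution, TrackingParams


@pytest.fixture(scope="module")
def human_blueprint(human_phantom, human_tracts):
    tracts, classes, params = human_tracts
    return build_species_blueprint(human_phantom, tracts, classes, params)


class TestGmByWm:
    def test_elements_off_any_bundle_give_zero_rows(self, human_phantom):
        fld = human_phantom.field
        # voxels with no fibre populations are lost immediately
        dead = np.argwhere((fld.fractions.sum(-1) == 0)
                           & human_phantom.masks["ribbon"].membership)[:5]
        params = TrackingParams(rng_seed=0, step_mm=0.5, seeds_per_voxel=10)
        gmwm = gm_by_wm(fld, dead, human_phantom.masks["wm"], params)
        assert gmwm.row_mass().sum() == 0

    def test_bundle_origin_rows_land_on_in_tube_wm(self, mini_base):
        ph = mini_base
        tube = ph.ground_truth["tube_masks"]["assoc"]
        seeds = np.argwhere(tube.membership & ph.masks["west_l"].membership)[:8]
        params = TrackingParams(rng_seed=1, step_mm=0.5, seeds_per_voxel=30, max_steps=200)
        wm = ph.masks["brain"]
        gmwm = gm_by_wm(ph.field, seeds, wm, params, downsample=1)
        coarse_tube = tube.membership.ravel()[gmwm.wm_columns]
        mass = np.asarray(gmwm.matrix.sum(axis=0)).ravel()
        in_tube = mass[coarse_tube].sum()
        assert in_tube / mass.sum() > 0.9

    def test_downsample_conserves_row_mass(self, mini_base):
        ph = mini_base
        seeds = np.argwhere(ph.ground_truth["tube_masks"]["assoc"].membership
                            & ph.masks["west_l"].membership)[:6]
        params = TrackingParams(rng_seed=2, step_mm=0.5, seeds_per_voxel=20, max_steps=200)
        g1 = gm_by_wm(ph.field, seeds, ph.masks["brain"], params, downsample=1)
        g2 = gm_by_wm(ph.field, seeds, ph.masks["brain"], params, downsample=2)
        # aggregation can only merge fine voxels: per-row coarse mass is
        # bounded by fine mass and at least the number of streamlines
        m1, m2 = g1.row_mass(), g2.row_mass()
        assert (m2 <= m1).all()
        assert (m2 > 0).sum() == (m1 > 0).sum()

    def test_empty_wm_mask_rejected(self, mini_base):
        params = TrackingParams(rng_seed=0, seeds_per_voxel=1)
        with pytest.raises(ValueError):
            gm_by_wm(mini_base.field, np.array([[2, 2, 2]]),
                     MaskVolume.empty(mini_base.field.grid), params)


class TestWmByTracts:
    def _toy(self):
        grid = VolumeGrid.isotropic((4, 2, 2), 1.0)
        return grid

    def test_threshold_hand_check(self):
        grid = self._toy()
        v = np.zeros(grid.shape)
        v[0, 0, 0] = 0.0005
        v[2, 0, 0] = 0.002
        pd = PathDistribution(grid, v, 1000)
        cols = np.arange(np.prod([2, 1, 1]))
        from cstract.core import downsample_grid
        cg = downsample_grid(grid, 2)
        mat, names = wm_by_tracts({"t": pd}, np.arange(int(np.prod(cg.shape))), cg,
                                  downsample=2, threshold=0.001)
        assert (mat > 0).sum() == 0  # block-mean dilutes both below threshold
        mat2, _ = wm_by_tracts({"t": pd}, np.arange(int(np.prod(grid.shape))), grid,
                               downsample=1, threshold=0.001)
        assert (mat2 > 0).sum() == 1

    def test_zero_distribution_gives_zero_column(self):
        grid = self._toy()
        pd = PathDistribution(grid, np.zeros(grid.shape), 10)
        mat, _ = wm_by_tracts({"z": pd}, np.arange(int(np.prod(grid.shape))), grid,
                              downsample=1)
        assert not mat.any()

    def test_disjoint_tracts_have_disjoint_rows(self):
        grid = self._toy()
        a = np.zeros(grid.shape); a[0] = 0.1
        b = np.zeros(grid.shape); b[3] = 0.1
        mat, names = wm_by_tracts({"a": PathDistribution(grid, a, 10),
                                   "b": PathDistribution(grid, b, 10)},
                                  np.arange(int(np.prod(grid.shape))), grid, downsample=1)
        assert not ((mat[:, 0] > 0) & (mat[:, 1] > 0)).any()


class TestCorticalBlueprint:
    def test_manual_matrix_product(self):
        from scipy import sparse
        from cstract.blueprints import GMxWMMatrix
        g = VolumeGrid.isotropic((2, 2, 1), 1.0)
        gm = sparse.csr_matrix(np.arange(12, dtype=float).reshape(3, 4))
        gmwm = GMxWMMatrix(element_ids=list(range(3)), coarse_grid=g,
                           wm_columns=np.arange(4), matrix=gm)
        wmt = np.arange(8, dtype=float).reshape(4, 2)
        out = cortical_blueprint(gmwm, wmt)
        np.testing.assert_allclose(out, gm.toarray() @ wmt)

    def test_consistent_wm_permutation_leaves_product_unchanged(self):
        from scipy import sparse
        from cstract.blueprints import GMxWMMatrix
        g = VolumeGrid.isotropic((2, 2, 1), 1.0)
        rng = np.random.default_rng(0)
        gm = rng.random((3, 5))
        wmt = rng.random((5, 2))
        perm = rng.permutation(5)
        a = cortical_blueprint(GMxWMMatrix([0, 1, 2], g, np.arange(5),
                                           sparse.csr_matrix(gm)), wmt)
        b = cortical_blueprint(GMxWMMatrix([0, 1, 2], g, np.arange(5),
                                           sparse.csr_matrix(gm[:, perm])), wmt[perm])
        np.testing.assert_allclose(a, b)

    def test_dimension_mismatch_rejected(self):
        from scipy import sparse
        from cstract.blueprints import GMxWMMatrix
        g = VolumeGrid.isotropic((2, 2, 1), 1.0)
        gmwm = GMxWMMatrix([0], g, np.arange(3), sparse.csr_matrix((1, 3)))
        with pytest.raises(ValueError):
            cortical_blueprint(gmwm, np.zeros((4, 2)))


class TestSubcorticalBlueprint:
    def test_direct_rows_depend_only_on_in_nucleus_values(self, human_phantom, human_tracts):
        tracts, _, _ = human_tracts
        nuclei = blueprint_nuclei(human_phantom)
        rows1, meta1, names = subcortical_blueprint(tracts, nuclei)
        # perturb one tract far outside every nucleus
        modified = dict(tracts)
        pd = tracts["UF_l"]
        v = pd.values.copy()
        v[0:4, 0:4, 0:4] = 0.9
        modified["UF_l"] = PathDistribution(pd.grid, v, pd.n_valid)
        rows2, meta2, _ = subcortical_blueprint(modified, nuclei)
        np.testing.assert_array_equal(rows1, rows2)

    def test_tract_absent_from_nuclei_gives_zero_column(self, human_phantom, human_tracts):
        tracts, _, _ = human_tracts
        rows, meta, names = subcortical_blueprint(tracts, blueprint_nuclei(human_phantom))
        j = names.index("SLF_l")   # dorsal association bundle touches no nucleus
        assert rows[:, j].sum() == 0

    def test_terminal_nucleus_receives_its_tract(self, human_phantom, human_tracts):
        tracts, _, _ = human_tracts
        rows, meta, names = subcortical_blueprint(tracts, blueprint_nuclei(human_phantom))
        kinds = np.array([m["kind"] for m in meta])
        j = names.index("StBf_l")
        assert rows[kinds == "putamen_l", j].sum() > 0
        assert rows[kinds == "caudate_l", j].sum() == 0

    def test_threshold_one_flags_all_rows(self, human_phantom, human_tracts):
        tracts, classes, params = human_tracts
        rows, meta, names = subcortical_blueprint(tracts, blueprint_nuclei(human_phantom),
                                                  threshold=1.0)
        assert rows.sum() == 0
        bp = assemble(np.zeros((0, len(names))), [], rows, meta, names, classes)
        assert bp.flagged.all()


class TestAssembleAndAverage:
    def _bp(self, values, names=("a", "b")):
        meta = [{"kind": "cortex", "hemisphere": "l", "voxel": (0, 0, i)}
                for i in range(len(values))]
        return assemble(np.asarray(values, float), meta,
                        np.zeros((0, len(names))), [], list(names),
                        {n: "cs" for n in names})

    def test_row_normalisation(self):
        bp = self._bp([[2.0, 2.0], [1.0, 3.0], [0.0, 0.0]])
        np.testing.assert_allclose(bp.values[0], [0.5, 0.5])
        np.testing.assert_allclose(bp.values[1], [0.25, 0.75])
        assert bp.flagged[2] and not bp.flagged[:2].any()

    def test_normalised_rows_are_idempotent(self):
        bp = self._bp([[0.3, 0.7]])
        np.testing.assert_allclose(bp.values[0], [0.3, 0.7], atol=1e-12)

    def test_random_matrix_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        bp = self._bp(rng.random((20, 2)))
        sums = bp.values[~bp.flagged].sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-9

    def test_group_average_single_input_identity(self, human_blueprint):
        out = group_average_blueprints([human_blueprint])
        np.testing.assert_allclose(out.values, human_blueprint.values, atol=1e-12)

    def test_group_average_two_one_hot_rows(self):
        a = self._bp([[1.0, 0.0]])
        b = self._bp([[0.0, 1.0]])
        out = group_average_blueprints([a, b])
        np.testing.assert_allclose(out.values[0], [0.5, 0.5])

    def test_group_average_matches_hand_computation(self, human_blueprint):
        rng = np.random.default_rng(1)
        others = []
        for _ in range(4):
            vals = human_blueprint.values * rng.uniform(0.5, 1.5, size=human_blueprint.values.shape)
            sums = vals.sum(axis=1)
            ok = sums > 0
            vals[ok] /= sums[ok, None]
            others.append(cs.ConnectivityBlueprint(
                values=vals, tract_names=human_blueprint.tract_names,
                tract_classes=human_blueprint.tract_classes,
                row_meta=human_blueprint.row_meta, normalised=True,
                flagged=~ok))
        group = group_average_blueprints([human_blueprint] + others)
        hand = np.mean([human_blueprint.values] + [o.values for o in others], axis=0)
        sums = hand.sum(axis=1)
        hand[sums > 0] /= sums[sums > 0, None]
        np.testing.assert_allclose(group.values, hand, atol=1e-9)

    def test_structure_mismatch_rejected(self, human_blueprint):
        other = self._bp([[1.0, 0.0]])
        with pytest.raises(ValueError):
            group_average_blueprints([human_blueprint, other])


class TestVariantComparison:
    def test_direct_variant_specificity_on_clean_tract(self, human_phantom, human_tracts):
        tracts, _, _ = human_tracts
        rows, meta, names = subcortical_blueprint(tracts, blueprint_nuclei(human_phantom))
        spec = tract_specificity(rows, meta, names,
                                 human_phantom.ground_truth["bundle_nucleus"])
        assert spec["ATR_l"] == pytest.approx(1.0)
        assert spec["MB_l"] == pytest.approx(1.0)

    def test_column_permutation_equivariance(self, human_blueprint):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(human_blueprint.tract_names))
        permuted = cs.ConnectivityBlueprint(
            values=human_blueprint.values[:, perm],
            tract_names=[human_blueprint.tract_names[i] for i in perm],
            tract_classes=human_blueprint.tract_classes,
            row_meta=human_blueprint.row_meta, normalised=True,
            flagged=human_blueprint.flagged)
        ref_rows = human_blueprint.rows_of("putamen_l")
        from cstract.divergence import DivergenceConfig, divergence_map
        d1 = divergence_map(human_blueprint, ref_rows, human_blueprint)
        d2 = divergence_map(permuted, ref_rows, permuted)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9, equal_nan=True)


class TestBlueprintIO:
    def test_tsv_round_trip(self, tmp_path, human_blueprint):
        human_blueprint.save(tmp_path / "bp")
        back = cs.ConnectivityBlueprint.load(tmp_path / "bp")
        np.testing.assert_allclose(back.values, human_blueprint.values, atol=1e-9)
        assert back.tract_names == human_blueprint.tract_names
        np.testing.assert_array_equal(back.flagged, human_blueprint.flagged)
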