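import numpy as np
import pandas as pd
import pytest
from scipy import stats

import restmem.groupglm as gg
from conftest import balanced_frame


def simple_spec(dependent="y", scalars=(), voxelwise=()):
    return gg.GroupModelSpec(
        dependent=dependent,
        scalar_covariates=list(scalars),
        voxelwise_covariates=list(voxelwise),
    )


def grid_for(n_vox):
    shape = (n_vox, 1, 1)
    return gg.VoxelGrid(np.ones(shape, bool), np.eye(4))


class TestInclusiveMask:
    def test_identical_full_masks(self, rng):
        stack = np.abs(rng.normal(1, 0.1, size=(5, 4, 4, 4))) + 0.1
        np.testing.assert_array_equal(gg.build_inclusive_mask(stack, stack),
                                      np.ones((4, 4, 4), bool))

    def test_single_zero_excludes_voxel(self, rng):
        stack = np.abs(rng.normal(1, 0.1, size=(5, 4, 4, 4))) + 0.1
        stack[2, 1, 2, 3] = 0.0
        mask = gg.build_inclusive_mask(stack)
        assert not mask[1, 2, 3]
        assert mask.sum() == 63

    def test_equals_bruteforce_intersection(self, rng):
        stacks = [rng.normal(size=(6, 3, 3, 3)) for _ in range(2)]
        for s in stacks:
            s[rng.random(s.shape) < 0.1] = 0.0
            s[rng.random(s.shape) < 0.05] = np.nan
        mask = gg.build_inclusive_mask(*stacks)
        brute = np.ones((3, 3, 3), bool)
        for s in stacks:
            for subj in s:
                brute &= np.isfinite(subj) & (subj != 0)
        np.testing.assert_array_equal(mask, brute)

    def test_empty_intersection_errors(self):
        stack = np.zeros((2, 2, 2, 2))
        with pytest.raises(ValueError, match="empty"):
            gg.build_inclusive_mask(stack)


class TestAssembleDesigns:
    def test_model1_regressor_names(self):
        frame = balanced_frame(8, 8)
        frame["hc_vol"] = 6000.0 + np.arange(16)
        frame["tiv"] = 1.4e6
        frame["wmlv"] = 500.0
        maps = {"gmv": np.random.default_rng(0).normal(600, 30, (16, 10))}
        design = gg.assemble_designs(gg.model1_spec(), frame, maps)
        assert design.names == [
            "young_Skyra", "young_Verio", "older_Skyra", "older_Verio",
            "HCvol_young", "HCvol_old", "TIV_young", "TIV_old",
            "WMLV_young", "WMLV_old", "age",
            "GMV_young_Skyra", "GMV_young_Verio", "GMV_old_Skyra", "GMV_old_Verio",
        ]

    def test_model3_regressor_names(self):
        frame = balanced_frame(6, 6)
        rng = np.random.default_rng(1)
        maps = {"gmv": rng.normal(600, 30, (12, 5)),
                "mperaf": rng.normal(1, 0.1, (12, 5)),
                "sme": rng.normal(0, 1, (12, 5))}
        design = gg.assemble_designs(gg.model3_spec(), frame, maps)
        assert design.names == [
            "young_Skyra", "young_Verio", "older_Skyra", "older_Verio", "age",
            "mPerAF_young_Skyra", "mPerAF_young_Verio", "mPerAF_old_Skyra",
            "mPerAF_old_Verio",
            "GMV_young_Skyra", "GMV_young_Verio", "GMV_old_Skyra", "GMV_old_Verio",
        ]

    def test_constant_voxelwise_covariate_degenerates_to_scalar(self):
        frame = balanced_frame(6, 6)
        vals = np.arange(12, dtype=float)
        maps = {"gmv": np.tile(vals[:, None], (1, 7))}  # constant across voxels
        spec = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        design = gg.assemble_designs(spec, frame, maps)
        x0 = design.matrix_at(0)
        for v in range(1, 7):
            np.testing.assert_array_equal(design.matrix_at(v), x0)
        # and the batch materialization agrees with the scalar one
        np.testing.assert_array_equal(design.matrices_at(np.arange(7))[3], x0)

    def test_groupwise_centering_sums_to_zero(self):
        frame = balanced_frame(7, 9)
        frame["hc_vol"] = np.random.default_rng(2).normal(6500, 400, 16)
        spec = simple_spec(scalars=[gg.ScalarCovariate("hc_vol", "HCvol")])
        design = gg.assemble_designs(spec, frame, {})
        young = frame["age_group"] == "young"
        col = design.base[:, design.names.index("HCvol_young")]
        assert col[young].sum() == pytest.approx(0.0, abs=1e-9)
        col_o = design.base[:, design.names.index("HCvol_old")]
        assert col_o[~young].sum() == pytest.approx(0.0, abs=1e-9)

    def test_missing_map_errors_with_subject(self):
        frame = balanced_frame(3, 3)
        maps = {"gmv": np.full((6, 4), 1.0)}
        maps["gmv"][4, 2] = np.nan
        spec = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        with pytest.raises(ValueError, match="o1"):
            gg.assemble_designs(spec, frame, maps)

    def test_missing_modality_errors(self):
        frame = balanced_frame(3, 3)
        spec = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        with pytest.raises(ValueError, match="gmv"):
            gg.assemble_designs(spec, frame, {})


class TestFitVoxelwise:
    def test_reduction_bit_identical_to_group_glm(self, rng):
        frame = balanced_frame(10, 10)
        frame["hc_vol"] = rng.normal(6500, 400, 20)
        spec = simple_spec(scalars=[gg.ScalarCovariate("hc_vol", "HCvol")])
        design = gg.assemble_designs(spec, frame, {})
        y = rng.normal(size=(20, 50))
        a = gg.fit_voxelwise(design, y)
        b = gg.fit_group_glm(design.base, y, design.names)
        assert np.array_equal(a.betas, b.betas)
        assert np.array_equal(a.sigma2, b.sigma2)
        assert np.array_equal(a.xtx_inv, b.xtx_inv)

    def test_matches_pervoxel_normal_equations_oracle(self, rng):
        frame = balanced_frame(12, 12)
        v = 100
        maps = {"gmv": rng.normal(600, 40, (24, v))}
        spec = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        design = gg.assemble_designs(spec, frame, maps)
        y = rng.normal(size=(24, v))
        fit = gg.fit_voxelwise(design, y, chunk=17)
        for vox in range(v):
            x = design.matrix_at(vox)
            beta = np.linalg.solve(x.T @ x, x.T @ y[:, vox])
            np.testing.assert_allclose(fit.betas[vox], beta, atol=1e-10)
            resid = y[:, vox] - x @ beta
            np.testing.assert_allclose(fit.sigma2[vox], resid @ resid / fit.df,
                                       atol=1e-10)

    def test_rank_deficient_voxels_masked_and_logged(self, rng):
        frame = balanced_frame(6, 6)
        v = 10
        maps = {"gmv": rng.normal(600, 40, (12, v))}
        maps["gmv"][:, 3] = 600.0  # constant within every cell at voxel 3
        spec = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        design = gg.assemble_designs(spec, frame, maps)
        fit = gg.fit_voxelwise(design, rng.normal(size=(12, v)))
        assert not fit.valid[3]
        assert fit.valid.sum() == v - 1

    def test_pervasive_deficiency_aborts(self, rng):
        frame = balanced_frame(6, 6)
        maps = {"gmv": np.full((12, 10), 600.0)}
        spec = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        design = gg.assemble_designs(spec, frame, maps)
        with pytest.raises(RuntimeError, match="rank-deficient"):
            gg.fit_voxelwise(design, rng.normal(size=(12, 10)))


class TestTContrast:
    def test_sign_flip_antisymmetry(self, rng, group_contrast_young_gt_old):
        frame = balanced_frame(8, 8)
        design = gg.assemble_designs(simple_spec(), frame, {})
        fit = gg.fit_voxelwise(design, rng.normal(size=(16, 30)))
        c = group_contrast_young_gt_old(design.names)
        tpos = gg.t_contrast(fit, c).t
        tneg = gg.t_contrast(fit, -c).t
        np.testing.assert_allclose(tpos, -tneg, atol=1e-12)

    def test_single_voxel_matches_textbook_formula(self, rng):
        x = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = (2.0 + 0.5 * x[:, 1] + rng.normal(0, 0.3, 15)).reshape(-1, 1)
        fit = gg.fit_group_glm(x, y, ["const", "slope"])
        c = np.array([0.0, 1.0])
        t = gg.t_contrast(fit, c).t[0]
        beta = np.linalg.solve(x.T @ x, x.T @ y[:, 0])
        resid = y[:, 0] - x @ beta
        s2 = resid @ resid / (15 - 2)
        expected = beta[1] / np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
        assert t == pytest.approx(expected, abs=1e-12)

    def test_null_t_follows_student_distribution(self, rng):
        frame = balanced_frame(12, 12)
        frame["hc_vol"] = rng.normal(6500, 400, 24)
        spec = simple_spec(scalars=[gg.ScalarCovariate("hc_vol", "HCvol")])
        design = gg.assemble_designs(spec, frame, {})
        y = rng.normal(size=(24, 5000))
        fit = gg.fit_voxelwise(design, y)
        c = gg.contrast_vector(design.names, {"HCvol_young": 1.0})
        tvals = gg.t_contrast(fit, c).t
        assert stats.kstest(tvals, "t", args=(fit.df,)).pvalue > 0.01

    def test_all_zero_contrast_errors(self, rng):
        frame = balanced_frame(5, 5)
        design = gg.assemble_designs(simple_spec(), frame, {})
        fit = gg.fit_voxelwise(design, rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="all-zero"):
            gg.t_contrast(fit, np.zeros(len(design.names)))


class TestFweThreshold:
    def setup_design(self, n_young=10, n_old=10):
        frame = balanced_frame(n_young, n_old)
        design = gg.assemble_designs(simple_spec(), frame, {})
        c = gg.contrast_vector(design.names, {"young_Skyra": 0.5, "young_Verio": 0.5,
                                              "older_Skyra": -0.5, "older_Verio": -0.5})
        return frame, design, c

    def test_all_zero_data_empty_table(self):
        frame, design, c = self.setup_design()
        y = np.zeros((20, 27))
        grid = gg.VoxelGrid(np.ones((3, 3, 3), bool), np.eye(4))
        res = gg.fwe_threshold(design, y, c, grid, n_perm=100, seed=0)
        assert len(res.clusters) == 0
        assert not res.sig.any()

    def test_small_blob_removed_by_extent(self, rng):
        frame, design, c = self.setup_design()
        grid = gg.VoxelGrid(np.ones((4, 4, 4), bool), np.eye(4))
        y = rng.normal(0, 0.5, size=(20, 64))
        blob = [0, 1, 2, 3, 4]  # 5 voxels, adjacent in flat order within (4,4,4)
        young = (frame["age_group"] == "young").to_numpy()
        y[np.ix_(young, blob)] += 10.0
        res = gg.fwe_threshold(design, y, c, grid, n_perm=200, seed=1, cluster_k=10)
        assert (res.p_fwe[blob] <= 0.05).all()  # voxel-level detections...
        assert not res.sig.any()  # ...killed by the k=10 extent threshold
        res2 = gg.fwe_threshold(design, y, c, grid, n_perm=200, seed=1, cluster_k=2)
        assert res2.sig.sum() >= 5

    def test_permutation_deterministic_under_seed(self, rng):
        frame, design, c = self.setup_design()
        grid = grid_for(30)
        y = rng.normal(size=(20, 30))
        r1 = gg.fwe_threshold(design, y, c, grid, n_perm=150, seed=42)
        r2 = gg.fwe_threshold(design, y, c, grid, n_perm=150, seed=42)
        assert r1.threshold == r2.threshold
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)

    def test_bonferroni_threshold(self, rng):
        frame, design, c = self.setup_design()
        grid = grid_for(40)
        y = rng.normal(size=(20, 40))
        res = gg.fwe_threshold(design, y, c, grid, method="bonferroni")
        assert res.threshold == pytest.approx(stats.t.isf(0.05 / 40, res.df))

    def test_too_few_units_errors(self, rng):
        frame = balanced_frame(3, 3)
        design = gg.assemble_designs(simple_spec(), frame, {})
        c = gg.contrast_vector(design.names, {"young_Skyra": 1.0, "older_Skyra": -1.0})
        with pytest.raises(ValueError, match="permutable"):
            gg.fwe_threshold(design, rng.normal(size=(6, 5)), c, grid_for(5), n_perm=50)

    def test_fwer_calibrated_heavy_tails(self, rng):
        """FWER stays near alpha under t(3) noise (300 null datasets)."""
        frame, design, c = self.setup_design()
        grid = grid_for(32)
        fp = 0
        reps = 300
        for _ in range(reps):
            y = rng.standard_t(3, size=(20, 32))
            res = gg.fwe_threshold(design, y, c, grid, n_perm=200,
                                   seed=int(rng.integers(2**31)), cluster_k=1)
            fp += bool((res.p_fwe <= 0.05).any())
        # binomial 99% band around 0.05 for 300 reps is ~[0.019, 0.081]
        assert 0.015 <= fp / reps <= 0.085

    def test_stratified_permutations_stay_within_strata(self, rng):
        frame, design, c = self.setup_design()
        strata = frame["scanner"].to_numpy()
        perms = gg._permutation_indices(20, 50, rng, strata)
        for p in perms:
            assert (strata[p] == strata).all()

    def test_voxelwise_and_shared_paths_agree_under_null(self, rng):
        """A constant voxelwise covariate makes both permutation paths
        statistically identical; with the same seed, identical perms."""
        frame = balanced_frame(8, 8)
        v = 12
        maps = {"gmv": np.tile(rng.normal(600, 40, 16)[:, None], (1, v))}
        spec_vox = simple_spec(voxelwise=[gg.VoxelwiseCovariate("gmv", "GMV")])
        d_vox = gg.assemble_designs(spec_vox, frame, maps)
        y = rng.normal(size=(16, v))
        c = gg.contrast_vector(d_vox.names, {"young_Skyra": 0.5, "young_Verio": 0.5,
                                             "older_Skyra": -0.5, "older_Verio": -0.5})
        res_vox = gg.fwe_threshold(d_vox, y, c, grid_for(v), n_perm=64, seed=9)
        # equivalent shared design: materialize the (voxel-constant) matrix
        d_shared = gg.GroupDesign(base=d_vox.matrix_at(0), names=d_vox.names,
                                  fillers=[], maps={}, cohort=frame)
        res_shared = gg.fwe_threshold(d_shared, y, c, grid_for(v), n_perm=64, seed=9)
        np.testing.assert_allclose(res_vox.maxt_null, res_shared.maxt_null, atol=1e-8)
        # p-values are permutation counts; fp jitter can flip a tied comparison
        np.testing.assert_allclose(res_vox.p_fwe, res_shared.p_fwe, atol=2 / 64)


class TestClusterAndOverlap:
    def test_cluster_table_peaks_inside_cluster(self, rng):
        t3 = rng.normal(size=(6, 6, 6))
        sig = np.zeros((6, 6, 6), bool)
        sig[1:3, 1:3, 1:3] = True
        t3[2, 2, 2] = 10.0
        table, keep = gg.cluster_table(sig, t3, np.eye(4), k=2)
        assert len(table) == 1
        assert table.loc[0, "size"] == 8
        assert (table.loc[0, ["x", "y", "z"]] == [2, 2, 2]).all()
        assert table.loc[0, "peak_t"] == pytest.approx(10.0)
        np.testing.assert_array_equal(keep, sig)

    def test_cluster_extent_threshold(self):
        sig = np.zeros((5, 5, 5), bool)
        sig[0, 0, :3] = True
        table, keep = gg.cluster_table(sig, np.ones((5, 5, 5)), np.eye(4), k=10)
        assert len(table) == 0 and not keep.any()

    def test_26_connectivity(self):
        sig = np.zeros((3, 3, 3), bool)
        sig[0, 0, 0] = sig[1, 1, 1] = True  # diagonal neighbors
        table, _ = gg.cluster_table(sig, np.ones((3, 3, 3)), np.eye(4), k=1)
        assert len(table) == 1 and table.loc[0, "size"] == 2

    def test_overlap_identity(self, rng):
        a = rng.random((4, 4, 4)) > 0.5
        inter, _ = gg.overlap_maps(a, a, np.eye(4))
        np.testing.assert_array_equal(inter, a)

    def test_overlap_disjoint_empty(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0], b[2] = True, True
        inter, table = gg.overlap_maps(a, b, np.eye(4))
        assert not inter.any() and len(table) == 0

    def test_overlap_equals_bruteforce(self, rng):
        a = rng.random((4, 4, 4)) > 0.6
        b = rng.random((4, 4, 4)) > 0.6
        inter, _ = gg.overlap_maps(a, b, np.eye(4))
        np.testing.assert_array_equal(inter, a & b)

    def test_overlap_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            gg.overlap_maps(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool), np.eye(4))


class TestGroundTruthRecovery:
    def test_group_difference_recovered(self, rng, group_contrast_young_gt_old):
        """Injected young > old mean difference is detected; a null covariate
        contrast is not."""
        frame = balanced_frame(20, 20)
        design = gg.assemble_designs(simple_spec(), frame, {})
        v = 125
        grid = gg.VoxelGrid(np.ones((5, 5, 5), bool), np.eye(4))
        y = rng.normal(size=(40, v))
        effect_vox = np.arange(30)
        young = (frame["age_group"] == "young").to_numpy()
        y[np.ix_(young, effect_vox)] += 1.8
        c = group_contrast_young_gt_old(design.names)
        res = gg.fwe_threshold(design, y, c, grid, n_perm=300, seed=5, cluster_k=1)
        sens = (res.p_fwe[effect_vox] <= 0.05).mean()
        assert sens >= 0.8
        # opposite direction finds nothing
        res_neg = gg.fwe_threshold(design, y, -c, grid, n_perm=300, seed=5, cluster_k=1)
        assert (res_neg.p_fwe <= 0.05).sum() == 0
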