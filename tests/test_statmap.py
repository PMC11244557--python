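"""Factorial voxelwise inference, ROI tests and permutation cluster FWER."""

import numpy as np
import pandas as pd
import pytest

from sexgeno.connectivity import ConnectivityMap
from sexgeno.statmap import (
    T_CLIP,
    cluster_fwer,
    factorial_anova,
    roi_ttest,
    voxelwise_glm,
)


def _maps_from_values(values, shape=None):
    """One map per subject from a (n_subj, n_voxels) array."""
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (values.shape[1], 1, 1)
    mask = np.ones(shape, dtype=bool)
    out = []
    for row in values:
        data = np.full(shape, np.nan)
        data[mask] = row
        out.append(ConnectivityMap(data, "global", mask))
    return out


def _design(n_per_cell):
    rows = []
    for sex in ("M", "F"):
        for geno in ("WT", "MUT"):
            for k in range(n_per_cell):
                rows.append({"subject": f"{sex}{geno}{k}", "sex": sex,
                             "genotype": geno})
    return pd.DataFrame(rows)


def anova_interaction_t(y, sex, geno):
    """Textbook cell-means interaction contrast t for a balanced 2x2."""
    cells = {}
    for s in (1, -1):
        for g in (1, -1):
            cells[(s, g)] = y[(sex == s) & (geno == g)]
    n = len(next(iter(cells.values())))
    means = {k: v.mean() for k, v in cells.items()}
    contrast = (means[(1, 1)] - means[(1, -1)] - means[(-1, 1)] + means[(-1, -1)]) / 4
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    mse = ss_within / (4 * n - 4)
    se = np.sqrt(mse * 4 / (16 * n))
    return contrast / se


class TestVoxelwiseGlm:
    def test_constant_maps_give_zero_t(self):
        design = _design(3)
        maps = _maps_from_values(np.ones((12, 40)))
        for sm in voxelwise_glm(maps, design):
            np.testing.assert_array_equal(sm.in_mask(), 0.0)

    def test_pure_interaction_pattern_clips_t(self):
        design = _design(3)
        vals = np.zeros((12, 10))
        mut_male = (design.sex == "M") & (design.genotype == "MUT")
        vals[mut_male.to_numpy()] = 2.0
        sex_m, geno_m, inter_m = voxelwise_glm(_maps_from_values(vals), design)
        assert np.all(np.abs(inter_m.in_mask()) == T_CLIP)
        # +d in the MUT-male cell only loads positively on the interaction
        assert np.all(inter_m.in_mask() > 0)

    def test_matches_textbook_anova_contrast(self, rng):
        design = _design(5)
        cell_means = {"M": {"WT": 0.0, "MUT": 0.5}, "F": {"WT": 0.2, "MUT": -0.4}}
        mu = np.array([cell_means[s][g] for s, g in
                       zip(design.sex, design.genotype)])
        vals = mu[:, None] + rng.standard_normal((20, 200))
        _, _, inter_map = voxelwise_glm(_maps_from_values(vals, (10, 10, 2)), design)
        sex = np.where(design.sex == "M", 1, -1)
        geno = np.where(design.genotype == "MUT", 1, -1)
        oracle = np.array([anova_interaction_t(vals[:, v], sex, geno)
                           for v in range(200)])
        np.testing.assert_allclose(inter_map.in_mask(), oracle, atol=1e-8)

    def test_glm_interaction_t_squared_equals_anova_f(self, rng):
        design = _design(4)
        vals = rng.standard_normal((16, 30))
        _, _, inter_map = voxelwise_glm(_maps_from_values(vals, (5, 3, 2)), design)
        for v in (0, 7, 29):
            res = factorial_anova(vals[:, v], design)
            assert inter_map.in_mask()[v] ** 2 == pytest.approx(
                res["F_interaction"], rel=1e-8)

    def test_nan_voxels_excluded(self, rng):
        design = _design(3)
        vals = rng.standard_normal((12, 20))
        vals[4, 3] = np.nan
        maps = _maps_from_values(vals)
        sm = voxelwise_glm(maps, design)[2]
        assert np.isnan(sm.in_mask()[3])
        assert np.isfinite(np.delete(sm.in_mask(), 3)).all()

    def test_empty_cell_rejected(self, rng):
        design = _design(3)
        design = design[~((design.sex == "F") & (design.genotype == "MUT"))]
        maps = _maps_from_values(rng.standard_normal((9, 10)))
        with pytest.raises(ValueError, match="interaction"):
            voxelwise_glm(maps, design)


class TestRoiTtest:
    def test_identical_groups(self):
        t, p = roi_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_pooled_t(self):
        t, p = roi_ttest([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(6), rng.standard_normal(8) + 1
        t1, p1 = roi_ttest(a, b)
        t2, p2 = roi_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            roi_ttest([1.0, 1.0], [2.0, 2.0])


class TestFactorialAnova:
    def test_additive_means_no_interaction(self):
        design = _design(2)
        sex_eff = np.where(design.sex == "M", 1.0, 0.0)
        geno_eff = np.where(design.genotype == "MUT", 2.0, 0.0)
        res = factorial_anova(sex_eff + geno_eff, design)
        assert res["F_interaction"] == 0.0
        assert res["p_interaction"] == 1.0

    def test_single_loaded_cell_matches_brute_force_ss(self):
        design = _design(2)
        y = np.where((design.sex == "F") & (design.genotype == "MUT"), 1.0, 0.0)
        res = factorial_anova(y, design)
        # brute force: grand mean 0.25; each effect SS = 8 * 0.25^2 = 0.5
        # within-cell SS = 0 -> F infinite for every effect
        assert res["F_sex"] == np.inf and res["F_interaction"] == np.inf

    def test_brute_force_decomposition_with_noise(self, rng):
        design = _design(3)
        y = rng.standard_normal(12)
        res = factorial_anova(y, design)
        sex = np.where(design.sex == "M", 1.0, -1.0)
        geno = np.where(design.genotype == "MUT", 1.0, -1.0)
        X = np.column_stack([np.ones(12), sex, geno, sex * geno])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        mse = (resid**2).sum() / 8
        # balanced orthogonal design: SS_effect = n * beta^2
        for j, name in ((1, "sex"), (2, "genotype"), (3, "interaction")):
            F = 12 * beta[j] ** 2 / mse
            assert res[f"F_{name}"] == pytest.approx(F, rel=1e-8)

    def test_scale_invariance_of_f(self, rng):
        design = _design(3)
        y = rng.standard_normal(12)
        r1 = factorial_anova(y, design)
        r2 = factorial_anova(2.0 * y, design)
        for key in ("F_sex", "F_genotype", "F_interaction"):
            assert r1[key] == pytest.approx(r2[key], rel=1e-10)

    def test_tukey_table_present(self, rng):
        design = _design(3)
        res = factorial_anova(rng.standard_normal(12), design, tukey=True)
        assert len(res["tukey"]) == 6  # all cell pairs

    def test_empty_cell_rejected(self, rng):
        design = _design(2)
        design = design[~((design.sex == "M") & (design.genotype == "WT"))]
        with pytest.raises(ValueError):
            factorial_anova(rng.standard_normal(len(design)), design)


class TestClusterFwer:
    def _setup(self, rng, effect=0.0, n_per_cell=4, shape=(6, 6, 4)):
        design = _design(n_per_cell)
        n = len(design)
        nvox = int(np.prod(shape))
        vals = rng.standard_normal((n, nvox))
        if effect:
            block = np.zeros(shape, dtype=bool)
            block[1:4, 1:4, 1:3] = True
            mut_male = ((design.sex == "M") & (design.genotype == "MUT")).to_numpy()
            vals[np.ix_(mut_male, block.ravel())] += effect
        maps = _maps_from_values(vals, shape)
        tmaps = voxelwise_glm(maps, design)
        return tmaps[2], maps, design

    def test_no_suprathreshold_voxels_empty_result(self, rng):
        tmap, maps, design = self._setup(rng)
        tmap.data[:] = 0.0
        res = cluster_fwer(tmap, maps, design, t_thresh=2.1, n_perm=100, seed=1)
        assert res.clusters == []

    def test_corrected_p_floor(self, rng):
        tmap, maps, design = self._setup(rng, effect=5.0)
        res = cluster_fwer(tmap, maps, design, t_thresh=2.1, n_perm=100, seed=1)
        assert res.clusters
        for c in res.clusters:
            assert c.corrected_p >= 1 / 101

    def test_planted_effect_detected(self, rng):
        tmap, maps, design = self._setup(rng, effect=4.0)
        res = cluster_fwer(tmap, maps, design, t_thresh=2.1, n_perm=200, seed=2)
        sig = res.significant(0.05)
        assert sig and sig[0].extent >= 9

    def test_p_monotone_in_extent(self, rng):
        tmap, maps, design = self._setup(rng, effect=2.0)
        res = cluster_fwer(tmap, maps, design, t_thresh=1.5, n_perm=150, seed=3)
        ordered = sorted(res.clusters, key=lambda c: c.extent)
        for a, b in zip(ordered, ordered[1:]):
            assert a.corrected_p >= b.corrected_p

    def test_deterministic_given_seed(self, rng):
        tmap, maps, design = self._setup(rng, effect=2.0)
        r1 = cluster_fwer(tmap, maps, design, t_thresh=2.0, n_perm=120, seed=9)
        r2 = cluster_fwer(tmap, maps, design, t_thresh=2.0, n_perm=120, seed=9)
        assert [c.corrected_p for c in r1.clusters] == [c.corrected_p for c in r2.clusters]
        np.testing.assert_array_equal(r1.null_max_extent, r2.null_max_extent)

    def test_bad_threshold_rejected(self, rng):
        tmap, maps, design = self._setup(rng)
        with pytest.raises(ValueError):
            cluster_fwer(tmap, maps, design, t_thresh=0.0, n_perm=100, seed=1)
        with pytest.raises(ValueError):
            cluster_fwer(tmap, maps, design, t_thresh=2.0, n_perm=50, seed=1)
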