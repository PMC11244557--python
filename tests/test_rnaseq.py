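"""Count filtering, TMM, log-CPM, voom weights, SVA and the factorial fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from sexgeno.rnaseq import (
    CountMatrix,
    classify_interaction,
    estimate_svs,
    filter_genes,
    fit_interaction,
    interaction_model_matrix,
    logcpm,
    precision_weights,
    tmm_factors,
)
from sexgeno.simulate import CountsSimSpec, PlantedSet, simulate_counts


def _cm(counts, samples=None):
    counts = np.atleast_2d(counts)
    if samples is None:
        samples = [f"s{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"g{i:03d}" for i in range(counts.shape[0])])
    return CountMatrix(df)


def brute_force_tmm(counts, ref_j, trim_m=0.3, trim_a=0.05):
    """Independent straight-line TMM: explicit loops, no shared code."""
    X = np.asarray(counts, dtype=float)
    lib = X.sum(axis=0)
    factors = []
    for j in range(X.shape[1]):
        if j == ref_j:
            factors.append(1.0)
            continue
        M, A, w = [], [], []
        for g in range(X.shape[0]):
            o, r = X[g, j], X[g, ref_j]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref_j]
                M.append(np.log2(po / pr))
                A.append(0.5 * np.log2(po * pr))
                w.append((lib[j] - o) / (lib[j] * o)
                         + (lib[ref_j] - r) / (lib[ref_j] * r))
        M, A, w = map(np.array, (M, A, w))
        if len(M) == 0 or np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = rankdata(M), rankdata(A)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilterGenes:
    def test_low_read_gene_dropped(self):
        cm = _cm([[1000] * 4, [0, 0, 0, 0], [1000, 1000, 50, 50]])
        out = filter_genes(cm, min_reads=100, min_samples=2, var_quantile=0.0)
        assert list(out.counts.index) == ["g000"]

    def test_variance_quantile_with_tie_break(self):
        # identical rows -> all variances tie; the tie-break decides
        cm_eq = _cm(np.tile([500, 600, 700, 800], (100, 1)))
        out = filter_genes(cm_eq, min_reads=100, min_samples=2,
                           var_quantile=0.15)
        assert len(out.counts) == 85
        # ties keep the lowest gene IDs
        assert list(out.counts.index) == [f"g{i:03d}" for i in range(85)]

    def test_all_filtered_rejected(self):
        cm = _cm([[1, 1, 1], [2, 2, 2]])
        with pytest.raises(ValueError):
            filter_genes(cm, min_reads=100, min_samples=2, var_quantile=0.0)

    def test_brute_force_variance_ranking(self, rng):
        counts = rng.integers(200, 5000, size=(40, 6))
        cm = _cm(counts)
        out = filter_genes(cm, min_reads=0, min_samples=99, var_quantile=0.25)
        lib = counts.sum(axis=0)
        lc = np.log2((counts + 0.5) / (lib + 1.0) * 1e6)
        v = lc.var(axis=1, ddof=1)
        expected_drop = set(np.argsort(v, kind="stable")[:10])
        kept = {int(g[1:]) for g in out.counts.index}
        assert kept == set(range(40)) - expected_drop


class TestTmm:
    def test_identical_samples_factor_one(self):
        cm = _cm(np.tile([[100], [300], [800], [50], [1200]], (1, 4)))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0)

    def test_pure_depth_difference_absorbed(self, rng):
        base = rng.integers(100, 5000, 200)
        cm = _cm(np.column_stack([base, base * 2, base]))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0, atol=1e-12)

    def test_small_matrix_matches_brute_force(self):
        counts = np.array([
            [100, 220, 90],
            [5000, 4200, 5100],
            [40, 90, 35],
            [800, 1700, 750],
            [300, 290, 310],
        ])
        cm = _cm(counts)
        lib = counts.sum(axis=0)
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(3)])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
        expected = brute_force_tmm(counts, ref_j)
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), expected,
                                   atol=1e-6)

    def test_larger_matrix_matches_brute_force(self, rng):
        counts = rng.negative_binomial(5, 0.01, size=(150, 5))
        cm = _cm(counts)
        lib = counts.sum(axis=0)
        uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(5)])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(),
                                   brute_force_tmm(counts, ref_j), atol=1e-6)

    def test_geometric_mean_one(self, rng):
        counts = rng.integers(0, 3000, size=(80, 6))
        f = tmm_factors(_cm(counts)).to_numpy()
        assert np.prod(f) == pytest.approx(1.0, abs=1e-10)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(_cm([[10], [20]]))


class TestLogCpm:
    def test_closed_form_zero_count(self):
        counts = np.zeros((1, 1), dtype=int)
        df = pd.DataFrame(counts, index=["g0"], columns=["s0"])
        # force libsize by adding a filler gene
        df.loc["g1"] = [1_000_000]
        out = logcpm(df, pd.Series([1.0], index=["s0"]))
        assert out.loc["g0", "s0"] == pytest.approx(
            np.log2(0.5 / 1_000_001 * 1e6), abs=1e-9)
        assert out.loc["g0", "s0"] == pytest.approx(-1.0000014, abs=1e-6)

    def test_depth_invariance_of_cpm(self, rng):
        base = rng.integers(10, 1000, 50)
        df1 = pd.DataFrame({"a": base})
        df2 = pd.DataFrame({"a": base * 2})
        lc1 = logcpm(df1).to_numpy().ravel()
        lc2 = logcpm(df2).to_numpy().ravel()
        np.testing.assert_allclose(lc1, lc2, atol=0.01)

    def test_equal_counts_equal_libs_constant_rows(self):
        df = pd.DataFrame(np.tile([[100], [900]], (1, 3)),
                          columns=list("abc"))
        out = logcpm(df).to_numpy()
        assert np.ptp(out, axis=1).max() < 1e-12


class TestPrecisionWeights:
    def _design(self, n_per_cell=4):
        rows = []
        for sex in ("M", "F"):
            for geno in ("WT", "MUT"):
                for k in range(n_per_cell):
                    rows.append({"sample": f"{sex}{geno}{k}", "sex": sex,
                                 "genotype": geno, "rin": 8.0 + 0.1 * k})
        return pd.DataFrame(rows)

    def test_weights_positive(self, rng):
        design = self._design()
        X, _ = interaction_model_matrix(design)
        lc = pd.DataFrame(rng.standard_normal((50, 16)) + 5)
        w = precision_weights(lc, X, np.full(16, 1e6))
        assert (w.to_numpy() > 0).all()

    def test_homoskedastic_weights_nearly_flat(self, rng):
        design = self._design()
        X, _ = interaction_model_matrix(design)
        lc = pd.DataFrame(rng.standard_normal((400, 16)) * 0.3
                          + rng.uniform(2, 10, 400)[:, None])
        w = precision_weights(lc, X, np.full(16, 1e6))
        cv = w.to_numpy().std() / w.to_numpy().mean()
        assert cv < 0.2

    def test_planted_trend_recovered(self, rng):
        design = self._design()
        X, _ = interaction_model_matrix(design)
        mu = rng.uniform(0, 10, 500)
        sd = 1.0 / (1.0 + 0.4 * mu)  # decreasing mean-variance trend
        lc = pd.DataFrame(mu[:, None] + sd[:, None]
                          * rng.standard_normal((500, 16)))
        w = precision_weights(lc, X, np.full(16, 1e6))
        rho = spearmanr(w.to_numpy().mean(axis=1), 1.0 / sd**2).statistic
        assert rho > 0.8

    def test_too_few_genes_rejected(self, rng):
        design = self._design()
        X, _ = interaction_model_matrix(design)
        lc = pd.DataFrame(rng.standard_normal((5, 16)))
        with pytest.raises(ValueError):
            precision_weights(lc, X, np.full(16, 1e6))


class TestEstimateSvs:
    def test_orthonormal(self, rng):
        cm, design, _ = simulate_counts(CountsSimSpec(n_genes=300, seed=11))
        lc = logcpm(cm.counts)
        svs = estimate_svs(lc, design, n_sv=2)
        np.testing.assert_allclose(svs.T @ svs, np.eye(2), atol=1e-10)

    def test_recovers_planted_artifact(self):
        for seed in (1, 2, 3):
            spec = CountsSimSpec(n_genes=1000, n_per_cell=6, seed=seed,
                                 artifact_strength=1.0)
            cm, design, truth = simulate_counts(spec)
            lc = logcpm(cm.counts, tmm_factors(cm))
            svs = estimate_svs(lc, design, n_sv=2)
            r = np.corrcoef(svs[:, 0], truth.artifact.to_numpy())[0, 1]
            assert abs(r) > 0.9

    def test_too_many_svs_rejected(self, rng):
        cm, design, _ = simulate_counts(CountsSimSpec(n_genes=50, n_per_cell=2,
                                                      seed=1))
        with pytest.raises(ValueError):
            estimate_svs(logcpm(cm.counts), design, n_sv=5)


class TestFitAndClassify:
    def _toy(self, rng, n_per_cell=4, n_genes=30):
        rows = []
        for sex in ("M", "F"):
            for geno in ("WT", "MUT"):
                for k in range(n_per_cell):
                    rows.append({"sample": f"{sex}{geno}{k}", "sex": sex,
                                 "genotype": geno, "rin": 8.0 + 0.05 * k})
        design = pd.DataFrame(rows)
        lc = pd.DataFrame(rng.standard_normal((n_genes, len(design))) + 5,
                          columns=design["sample"],
                          index=[f"g{i}" for i in range(n_genes)])
        return lc, design

    def test_pure_interaction_pattern(self, rng):
        lc, design = self._toy(rng)
        d = 1.0
        mut_m = ((design.sex == "M") & (design.genotype == "MUT")).to_numpy()
        mut_f = ((design.sex == "F") & (design.genotype == "MUT")).to_numpy()
        lc.iloc[0] = 5.0
        lc.iloc[0, np.flatnonzero(mut_m)] = 5.0 + d
        lc.iloc[0, np.flatnonzero(mut_f)] = 5.0 - d
        res = fit_interaction(lc, None, design, covariates=(), moderate=False)
        row = res.table.iloc[0]
        assert row.male_est == pytest.approx(d, abs=1e-10)
        assert row.female_est == pytest.approx(-d, abs=1e-10)
        # zero residual noise on this gene: unmoderated t hits the clip
        assert abs(row.interaction_t) == 1e6
        # the moderated fit borrows variance from the other genes
        mod = fit_interaction(lc, None, design, covariates=()).table.iloc[0]
        assert np.isfinite(mod.interaction_t)
        assert mod.male_est == pytest.approx(d, abs=1e-10)

    def test_equal_weights_reduce_to_ols(self, rng):
        lc, design = self._toy(rng)
        w = pd.DataFrame(np.full(lc.shape, 3.7), index=lc.index,
                         columns=lc.columns)
        r1 = fit_interaction(lc, None, design)
        r2 = fit_interaction(lc, w, design)
        for col in ("interaction_est", "interaction_t", "male_est", "female_est"):
            np.testing.assert_allclose(r1.table[col], r2.table[col], atol=1e-10)

    def test_sample_permutation_invariance(self, rng):
        lc, design = self._toy(rng)
        perm = rng.permutation(len(design))
        r1 = fit_interaction(lc, None, design)
        r2 = fit_interaction(lc.iloc[:, perm],
                             None, design.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(r1.table["interaction_t"],
                                   r2.table["interaction_t"], atol=1e-10)

    def test_variance_squeezing_pulls_toward_prior(self, rng):
        from sexgeno.rnaseq import squeeze_variances

        df = 12
        true = 0.5
        s2 = true * rng.chisquare(df, 3000) / df
        post, d0, s0 = squeeze_variances(s2, df)
        assert d0 > 0
        assert s0 == pytest.approx(true, rel=0.15)
        # posterior lies between the observation and the prior
        between = ((post - s2) * (s0 - s2) >= 0)
        assert between.mean() > 0.99
        spread = np.log(post).std() / np.log(s2).std()
        assert spread < 1.0

    def test_classification_policies(self):
        table = pd.DataFrame({
            "male_est": [-1.0, 1.0, 0.5, -1.0, 0.5],
            "female_est": [1.0, -1.0, 0.1, 1.0, -0.5],
            "interaction_q": [0.001, 0.01, 0.01, 0.2, 0.04],
        }, index=list("abcde"))
        from sexgeno.rnaseq import DEResult

        res = classify_interaction(DEResult(table, df_resid=10), q_thresh=0.05)
        assert list(res.table["gene_class"]) == [
            "M-F+", "M+F-", "concordant", "NS", "M+F-"]

    def test_rank_deficient_design_rejected(self, rng):
        lc, design = self._toy(rng)
        design = design.copy()
        design["rin"] = 1.0  # centered -> zero column... absorbed; duplicate sex
        design["dup"] = design["rin"]
        with pytest.raises(ValueError, match="rank"):
            interaction_model_matrix(design, covariates=("rin",))


class TestEndToEndRecovery:
    def test_planted_classes_recovered(self):
        sens = []
        confusions = []
        for seed in (1, 2, 3):
            planted = [PlantedSet("mf", tuple(range(0, 30)), 1.5, -1.5),
                       PlantedSet("fm", tuple(range(30, 60)), -1.5, 1.5)]
            spec = CountsSimSpec(n_genes=1200, n_per_cell=5, seed=seed,
                                 planted=planted)
            cm, design, truth = simulate_counts(spec)
            from sexgeno.rnaseq import run_de_pipeline

            res, filtered = run_de_pipeline(cm, design)
            kept = res.table.index
            for label in ("M+F-", "M-F+"):
                true_genes = truth.gene_class.index[truth.gene_class == label]
                true_kept = [g for g in true_genes if g in kept]
                if not true_kept:
                    continue
                called = res.table.loc[true_kept, "gene_class"]
                sens.append((called == label).mean())
                other = "M-F+" if label == "M+F-" else "M+F-"
                confusions.append((called == other).mean())
        assert np.mean(sens) >= 0.8
        assert np.mean(confusions) <= 0.02
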