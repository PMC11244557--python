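"""Factorial differential expression for 2x2 bulk RNA-seq designs.

Stages (in pipeline order):

1. :func:`filter_genes` — drop low-read genes (< ``min_reads`` in
   ``min_samples`` or more samples) and the bottom variance quantile on
   log-CPM.
2. :func:`tmm_factors` — trimmed-mean-of-M-values between-sample
   normalization (doubly trimmed, precision-weighted mean of log ratios
   against a reference sample).
3. :func:`logcpm` — log2 counts per million with the voom offsets
   (count + 0.5, effective library size + 1).
4. :func:`precision_weights` — voom-style observation weights from a
   lowess mean-variance trend.
5. :func:`estimate_svs` — surrogate variables as principal sample-side
   singular vectors of the residual after removing the known design.
6. :func:`fit_interaction` — per-gene weighted least squares for
   ``logcpm ~ genotype*sex + RIN + sv1 + sv2`` with +/-1 effect coding;
   reports the interaction coefficient and the within-sex simple effects
   (MUT - WT in males, and in females), with BH q over interaction p's.
7. :func:`classify_interaction` — M+F- / M-F+ / concordant labels from
   the simple-effect signs of interaction-significant genes.

Variance moderation (empirical-Bayes squeezing of residual variances) is
deliberately not applied; t statistics use the ordinary WLS residual df,
which is conservative at small n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

log = logging.getLogger(__name__)

CLASS_LABELS = ("M+F-", "M-F+", "concordant", "NS")


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with gene and sample metadata."""

    counts: pd.DataFrame  # genes x samples
    gene_meta: pd.DataFrame = None  # index: gene IDs; chromosome, human_homolog
    design: pd.DataFrame = None  # sample, sex, genotype, rin ...

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.design is not None:
            missing = set(self.counts.columns) - set(self.design["sample"])
            extra = set(self.design["sample"]) - set(self.counts.columns)
            if missing or extra:
                raise ValueError(
                    f"design/sample mismatch: missing={sorted(missing)}, "
                    f"extra={sorted(extra)}"
                )
        if self.gene_meta is not None:
            if not self.counts.index.isin(self.gene_meta.index).all():
                raise ValueError("gene_meta lacks rows for some genes")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).to_numpy(dtype=float)

    def subset_genes(self, keep: pd.Index) -> "CountMatrix":
        meta = self.gene_meta.loc[keep] if self.gene_meta is not None else None
        return CountMatrix(self.counts.loc[keep], meta, self.design)


def _raw_logcpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def filter_genes(
    c: CountMatrix,
    min_reads: int = 100,
    min_samples: int = 2,
    var_quantile: float = 0.15,
) -> CountMatrix:
    """Low-read filter then bottom-variance-quantile filter.

    A gene is dropped when it has fewer than ``min_reads`` reads in
    ``min_samples`` or more samples; of the remainder, the
    ``var_quantile`` fraction with lowest log-CPM variance is dropped
    (floor(q*n) genes; ties broken by keeping lower gene IDs).
    """
    if min_reads < 0 or min_samples < 0 or not (0 <= var_quantile < 1):
        raise ValueError("invalid filter thresholds")
    low = (c.counts < min_reads).sum(axis=1) >= min_samples
    kept = c.counts.index[~low]
    if len(kept) == 0:
        raise ValueError("read filter removed every gene")
    sub = c.counts.loc[kept]
    variances = _raw_logcpm(sub).var(axis=1, ddof=1).to_numpy()
    n_drop = int(np.floor(var_quantile * len(kept)))
    if n_drop:
        id_rank = rankdata(kept.to_numpy(), method="ordinal")
        order = np.lexsort((-id_rank, variances))  # asc var; ties: high ID first
        drop = set(order[:n_drop])
        kept = pd.Index([g for i, g in enumerate(kept) if i not in drop])
    if len(kept) == 0:
        raise ValueError("variance filter removed every gene")
    log.info("filter_genes: retained %d of %d genes", len(kept), len(c.counts))
    return c.subset_genes(kept)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2^f)."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("sample shares no expressed gene with the reference")
    o, r = obs[ok], ref[ok]
    po, pr = o / n_obs, r / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(M) & np.isfinite(A) & np.isfinite(w)
    M, A, w = M[fin], A[fin], w[fin]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = (w[keep] * M[keep]).sum() / w[keep].sum()
    return float(2.0**f)


def tmm_factors(
    c: CountMatrix | pd.DataFrame,
    ref: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample defaults to the one whose upper-quartile count
    fraction is closest to the mean upper quartile.  For each sample, M
    (log ratio) and A (log abundance) values against the reference are
    doubly trimmed (``trim_m`` of M, ``trim_a`` of A, each side) and the
    remaining M values averaged with inverse-delta-method weights.
    """
    counts = c.counts if isinstance(c, CountMatrix) else c
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad} has zero total count")
    if ref is None:
        uq = np.array([np.quantile(X[:, j] / lib[j], 0.75)
                       for j in range(X.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = counts.columns.get_loc(ref)
    factors = np.array([
        1.0 if j == ref_j else
        _tmm_pair(X[:, j], X[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
        for j in range(X.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def logcpm(c: CountMatrix | pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2 CPM with voom offsets: log2((k+0.5)/(lib*f+1) * 1e6)."""
    counts = c.counts if isinstance(c, CountMatrix) else c
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    f = np.ones(counts.shape[1]) if factors is None else factors.reindex(counts.columns).to_numpy()
    eff = lib * f
    return np.log2((counts + 0.5) / (eff + 1.0) * 1e6)


def interaction_model_matrix(
    design: pd.DataFrame, svs: np.ndarray | None = None,
    covariates: tuple[str, ...] = ("rin",),
) -> tuple[np.ndarray, list[str]]:
    """Model matrix [1, genotype, sex, genotype*sex, covars..., svs...].

    Genotype and sex are +/-1 effect-coded (MUT=+1, M=+1); numeric
    covariates are mean-centered.
    """
    from .statmap import effect_codes

    s, g = effect_codes(design)
    cols = [np.ones(len(design)), g, s, g * s]
    names = ["intercept", "genotype", "sex", "genotype:sex"]
    for cov in covariates:
        if cov in design.columns:
            v = design[cov].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(cov)
    if svs is not None:
        svs = np.atleast_2d(np.asarray(svs, dtype=float))
        if svs.shape[0] != len(design):
            svs = svs.T
        for k in range(svs.shape[1]):
            cols.append(svs[:, k])
            names.append(f"sv{k + 1}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"model matrix is rank deficient (columns: {names})")
    return X, names


def precision_weights(
    log_cpm: pd.DataFrame,
    design_matrix: np.ndarray,
    lib_sizes: np.ndarray,
    lowess_frac: float = 0.5,
) -> pd.DataFrame:
    """Voom-style precision weights from the mean-variance trend.

    Per-gene linear fits give residual standard deviations; a lowess
    trend of sqrt(sd) against average log2 count is evaluated at each
    observation's fitted log2 count, and the weight is trend**-4 (the
    inverse predicted variance).  Weights are strictly positive and
    nonincreasing in the predicted variance by construction.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    Y = log_cpm.to_numpy(dtype=float)
    if Y.shape[0] < 10:
        raise ValueError("need at least 10 genes to estimate the trend")
    X = np.asarray(design_matrix, dtype=float)
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # (genes, p)
    fitted = beta @ X.T  # (genes, n)
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    sqrt_sd = np.sqrt(sigma)

    log2lib = np.log2(lib_sizes + 1.0)
    sx = Y.mean(axis=1) + log2lib.mean() - np.log2(1e6)  # avg log2 count
    ok = sigma > 0
    trend = lowess(sqrt_sd[ok], sx[ok], frac=lowess_frac, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)

    fitted_count = fitted + log2lib[None, :] - np.log2(1e6)
    pred = np.interp(fitted_count, tx, ty)  # clamped extrapolation
    w = pred**-4.0
    return pd.DataFrame(w, index=log_cpm.index, columns=log_cpm.columns)


def estimate_svs(
    log_cpm: pd.DataFrame, design: pd.DataFrame, n_sv: int = 2,
    covariates: tuple[str, ...] = ("rin",),
) -> np.ndarray:
    """Surrogate variables: top sample-side singular vectors of the residual.

    The known model (genotype, sex, interaction, covariates) is projected
    out of the expression matrix; the surrogate variables are the leading
    ``n_sv`` right singular vectors (sample side) of the residual, an
    orthonormal (n_samples, n_sv) basis for the dominant structured
    artifact directions.
    """
    X, _ = interaction_model_matrix(design, svs=None, covariates=covariates)
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    if not (0 < n_sv < n - rank):
        raise ValueError(
            f"n_sv={n_sv} must satisfy 0 < n_sv < n_samples - rank(design) = {n - rank}"
        )
    Y = log_cpm.to_numpy(dtype=float)
    hat = X @ np.linalg.pinv(X)  # (n, n) projection onto the known design
    resid = Y - Y @ hat.T
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    svs = vt[:n_sv].T  # (n_samples, n_sv), orthonormal
    # deterministic sign: largest-magnitude element positive
    for k in range(svs.shape[1]):
        j = np.argmax(np.abs(svs[:, k]))
        if svs[j, k] < 0:
            svs[:, k] = -svs[:, k]
    return svs


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def squeeze_variances(sigma2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene-wise residual variances.

    Fits a scaled F prior to the observed variances by the method of
    moments on log variances and returns the posterior variances
    (d0*s0^2 + df*s2) / (d0 + df) together with the prior df d0 and
    prior variance s0^2.  Moderated t statistics then use df + d0
    degrees of freedom, which calibrates the extreme tail of the null
    p distribution at small n.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0, float("nan")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1))
    t2 = evar - float(polygamma(1, df / 2.0))
    if t2 > 0:
        d0 = 2.0 * _trigamma_inverse(t2)
        s0 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0 = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0)
    return post, d0, s0


@dataclass
class DEResult:
    """Per-gene factorial DE estimates plus interaction class labels."""

    table: pd.DataFrame
    df_resid: int
    model_columns: list[str] = field(default_factory=list)

    def genes_in_class(self, label: str) -> pd.Index:
        return self.table.index[self.table["gene_class"] == label]


def fit_interaction(
    log_cpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: pd.DataFrame,
    svs: np.ndarray | None = None,
    covariates: tuple[str, ...] = ("rin",),
    moderate: bool = True,
) -> DEResult:
    """Per-gene weighted least squares for the factorial interaction model.

    Reports, per gene: the interaction coefficient (t, p, BH q) and the
    within-sex simple effects MUT - WT estimated as 2*(b_g + b_gs) in
    males and 2*(b_g - b_gs) in females.  With all weights equal the fit
    reduces to OLS.  By default residual variances are empirical-Bayes
    moderated across genes (``moderate=False`` gives plain WLS t with
    the ordinary residual df).
    """
    X, names = interaction_model_matrix(design, svs=svs, covariates=covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} samples cannot identify {p} coefficients")
    Y = log_cpm.to_numpy(dtype=float)
    W = None if weights is None else weights.to_numpy(dtype=float)
    df = n - p
    g = Y.shape[0]

    c_int = np.zeros(p); c_int[names.index("genotype:sex")] = 1.0
    c_male = np.zeros(p)
    c_male[names.index("genotype")] = 2.0
    c_male[names.index("genotype:sex")] = 2.0
    c_fem = np.zeros(p)
    c_fem[names.index("genotype")] = 2.0
    c_fem[names.index("genotype:sex")] = -2.0
    contrasts = {"interaction": c_int, "male": c_male, "female": c_fem}

    ests = {k: np.empty(g) for k in contrasts}
    unscaled_var = {k: np.empty(g) for k in contrasts}  # c' (X'WX)^-1 c
    sigma2 = np.empty(g)
    for i in range(g):
        if W is None:
            Xw, yw = X, Y[i]
        else:
            sw = np.sqrt(W[i])
            Xw, yw = X * sw[:, None], Y[i] * sw
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        beta = xtx_inv @ (Xw.T @ yw)
        sigma2[i] = float(((yw - Xw @ beta) ** 2).sum()) / df
        for key, cvec in contrasts.items():
            ests[key][i] = float(cvec @ beta)
            unscaled_var[key][i] = float(cvec @ xtx_inv @ cvec)

    if moderate:
        post_var, d0, _s0 = squeeze_variances(sigma2, df)
        df_total = df + d0
    else:
        post_var, df_total = sigma2, df

    out = {}
    for key in contrasts:
        var = unscaled_var[key] * post_var
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ests[key] / np.sqrt(var)
        t = np.where(var > 0, t,
                     np.where(ests[key] == 0, 0.0, np.sign(ests[key]) * 1e6))
        t = np.clip(t, -1e6, 1e6)
        if np.isfinite(df_total):
            pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(t))
        pvals = np.where(var > 0, pvals, np.where(ests[key] == 0, 1.0, 0.0))
        out[f"{key}_est"] = ests[key]
        out[f"{key}_t"] = t
        out[f"{key}_p"] = pvals

    from .enrich import bh_fdr

    table = pd.DataFrame(out, index=log_cpm.index)
    table.insert(0, "mean_logcpm", Y.mean(axis=1))
    table["interaction_q"] = bh_fdr(table["interaction_p"].to_numpy())
    table["gene_class"] = "NS"
    return DEResult(table, int(df), names)


def classify_interaction(d: DEResult, q_thresh: float = 0.05) -> DEResult:
    """Label interaction-significant genes by their simple-effect signs.

    q < ``q_thresh`` and male effect < 0 < female effect -> "M-F+";
    female < 0 < male -> "M+F-"; both same (nonzero) sign -> "concordant";
    everything else "NS".
    """
    t = d.table
    sig = t["interaction_q"] < q_thresh
    male, fem = t["male_est"], t["female_est"]
    cls = np.full(len(t), "NS", dtype=object)
    cls[sig & (male > 0) & (fem < 0)] = "M+F-"
    cls[sig & (male < 0) & (fem > 0)] = "M-F+"
    cls[sig & (male * fem > 0)] = "concordant"
    t = t.copy()
    t["gene_class"] = cls
    return DEResult(t, d.df_resid, d.model_columns)


def run_de_pipeline(
    cm: CountMatrix,
    design: pd.DataFrame,
    n_sv: int = 2,
    q_thresh: float = 0.05,
    min_reads: int = 100,
    min_samples: int = 2,
    var_quantile: float = 0.15,
) -> tuple[DEResult, CountMatrix]:
    """Filter -> TMM -> log-CPM -> weights -> SVs -> fit -> classify.

    Returns the classified DE result and the filtered count matrix (whose
    gene index is the enrichment background universe).
    """
    filtered = filter_genes(cm, min_reads, min_samples, var_quantile)
    factors = tmm_factors(filtered)
    lc = logcpm(filtered, factors)
    X0, _ = interaction_model_matrix(design)
    w = precision_weights(lc, X0, filtered.lib_sizes)
    svs = estimate_svs(lc, design, n_sv=n_sv) if n_sv else None
    res = fit_interaction(lc, w, design, svs=svs)
    return classify_interaction(res, q_thresh), filtered
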