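"""Voxelwise 2x2 factorial inference with permutation cluster-extent FWER.

The factorial model is fit per voxel by OLS on [intercept, sex, genotype,
sex*genotype] with +/-1 effect coding (sex: M=+1, F=-1; genotype: MUT=+1,
WT=-1), so the interaction coefficient is symmetric in the two factors and,
for balanced designs, its squared t equals the two-way-ANOVA interaction F.

Cluster correction is nonparametric: clusters are formed at |t| > t_thresh
(positive and negative tails separately), and the familywise null is the
distribution of the maximum cluster extent over label permutations that
respect exchangeability — the permuted factor is shuffled within strata of
the other factor (restricted permutation), which is the appropriate scheme
for the interaction contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import ConnectivityMap

#: reported in place of an infinite t (zero residual variance)
T_CLIP = 1e6

SEX_LEVELS = ("M", "F")
GENO_LEVELS = ("WT", "MUT")
CONTRASTS = ("sex", "genotype", "interaction")


@dataclass
class StatMap:
    """3D t map for one contrast of the factorial model."""

    data: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) integer coordinates
    extent: int
    peak_t: float
    sign: int
    corrected_p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_thresh: float
    n_perm: int
    seed: int
    contrast: str
    null_max_extent: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.corrected_p < alpha]


def effect_codes(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return +/-1 codes for sex (M=+1) and genotype (MUT=+1)."""
    for col, levels in (("sex", SEX_LEVELS), ("genotype", GENO_LEVELS)):
        if col not in design.columns:
            raise ValueError(f"design lacks required column '{col}'")
        bad = set(design[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels {sorted(bad)}; expected {levels}")
    s = np.where(design["sex"].to_numpy() == "M", 1.0, -1.0)
    g = np.where(design["genotype"].to_numpy() == "MUT", 1.0, -1.0)
    return s, g


def _check_cells(design: pd.DataFrame, min_n: int) -> None:
    counts = design.groupby(["sex", "genotype"], observed=True).size()
    for sex in SEX_LEVELS:
        for gen in GENO_LEVELS:
            n = int(counts.get((sex, gen), 0))
            if n < min_n:
                raise ValueError(
                    f"design cell sex={sex}, genotype={gen} has {n} subjects; "
                    f"the interaction needs at least {min_n} per cell"
                )


def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    s, g = effect_codes(design)
    return np.column_stack([np.ones(len(s)), s, g, s * g])


def _stack_maps(maps: list[ConnectivityMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack subject maps to (n_subj, n_voxels) over commonly finite voxels."""
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all maps must share one mask")
    Y = np.stack([m.in_mask() for m in maps])
    good = np.isfinite(Y).all(axis=0)
    return Y[:, good], good, mask


def _fit_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-voxel OLS t statistics for every coefficient.

    X is (n, p), Y is (n, v); returns (p, v) t array and residual df.
    Infinite t (zero residual variance) is clipped to +/-T_CLIP.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no effect, no noise
    return np.clip(t, -T_CLIP, T_CLIP), df


def voxelwise_glm(maps: list[ConnectivityMap], design: pd.DataFrame) -> list[StatMap]:
    """Fit the sex + genotype + sex*genotype model at every voxel.

    Returns t maps for the three contrasts (coefficient t statistics with
    n - 4 residual df).  Voxels NaN in any subject are excluded (NaN in the
    output maps).
    """
    if len(maps) != len(design):
        raise ValueError(f"{len(maps)} maps but {len(design)} design rows")
    _check_cells(design, min_n=2)
    X = _design_matrix(design)
    Y, good, mask = _stack_maps(maps)
    t, df = _fit_t(X, Y)
    out = []
    for j, name in enumerate(CONTRASTS, start=1):
        flat = np.full(good.shape, np.nan)
        flat[good] = t[j]
        vol = np.full(mask.shape, np.nan)
        vol[mask] = flat
        out.append(StatMap(vol, df, name, mask))
    return out


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _clusters_from_t(tvol: np.ndarray, t_thresh: float, struct: np.ndarray):
    """Maximal connected components above +t_thresh and below -t_thresh."""
    found = []
    for sign in (1, -1):
        above = np.nan_to_num(sign * tvol, nan=-np.inf) > t_thresh
        labels, n = ndimage.label(above, structure=struct)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            ts = tvol[labels == lab]
            found.append((vox, int(len(vox)), float(ts[np.abs(ts).argmax()]), sign))
    return found


def _max_extent(t_flat: np.ndarray, good: np.ndarray, mask: np.ndarray,
                t_thresh: float, struct: np.ndarray) -> int:
    vol = np.zeros(mask.shape)
    flat = np.zeros(good.shape)
    flat[good] = t_flat
    vol[mask] = flat
    best = 0
    for sign in (1, -1):
        labels, n = ndimage.label(sign * vol > t_thresh, structure=struct)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def _permuted_designs(design: pd.DataFrame, contrast: str, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Permutation index matrix (n_perm, n) applied to the permuted factor.

    For the interaction and the genotype contrast, genotype labels are
    shuffled within sex strata; for the sex contrast, sex labels are
    shuffled within genotype strata.
    """
    strata_col = "genotype" if contrast == "sex" else "sex"
    n = len(design)
    strata = [np.flatnonzero(design[strata_col].to_numpy() == lev)
              for lev in np.unique(design[strata_col])]
    perms = np.empty((n_perm, n), dtype=int)
    for i in range(n_perm):
        idx = np.arange(n)
        for s in strata:
            idx[s] = s[rng.permutation(len(s))]
        perms[i] = idx
    return perms


def cluster_fwer(
    t: StatMap,
    maps: list[ConnectivityMap],
    design: pd.DataFrame,
    t_thresh: float = 2.1,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
) -> ClusterResult:
    """Cluster-extent FWER correction by restricted label permutation.

    Corrected p for a cluster of extent k is (1 + #{perm max extent >= k})
    / (1 + n_perm), using the maximum suprathreshold cluster extent (over
    both tails) of the permuted-design t map as the familywise null.
    """
    if t_thresh <= 0:
        raise ValueError("t_thresh must be positive")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if t.contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {t.contrast!r}")
    struct = _structure(connectivity)
    ci = CONTRASTS.index(t.contrast) + 1

    observed = _clusters_from_t(t.data, t_thresh, struct)

    Y, good, mask = _stack_maps(maps)
    rng = np.random.default_rng(seed)
    perms = _permuted_designs(design, t.contrast, n_perm, rng)
    s, g = effect_codes(design)
    null_max = np.empty(n_perm, dtype=int)
    ones = np.ones(len(design))
    for i in range(n_perm):
        if t.contrast == "sex":
            sp, gp = s[perms[i]], g
        else:
            sp, gp = s, g[perms[i]]
        Xp = np.column_stack([ones, sp, gp, sp * gp])
        tp, _ = _fit_t(Xp, Y)
        null_max[i] = _max_extent(tp[ci], good, mask, t_thresh, struct)

    clusters = []
    for vox, extent, peak, sign in observed:
        p = (1 + int((null_max >= extent).sum())) / (1 + n_perm)
        clusters.append(Cluster(vox, extent, peak, sign, p))
    clusters.sort(key=lambda c: (c.corrected_p, -c.extent))
    return ClusterResult(clusters, t_thresh, n_perm, seed, t.contrast, null_max)


def roi_ttest(scores_g1, scores_g2) -> tuple[float, float]:
    """Two-sided unpaired pooled-variance t test on ROI summary scores."""
    a = np.asarray(scores_g1, dtype=float)
    b = np.asarray(scores_g2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def factorial_anova(
    values, design: pd.DataFrame, tukey: bool = False
) -> dict:
    """Two-way ANOVA (Type II SS) for value ~ sex * genotype.

    For balanced designs this equals the Type I/III decomposition.  Returns
    a dict with F and p per effect, residual df, and (optionally) Tukey HSD
    pairwise comparisons across the four cells.  Effects with zero sum of
    squares report F = 0, p = 1 even when the residual variance vanishes.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = np.asarray(values, dtype=float)
    if len(y) != len(design):
        raise ValueError("values and design lengths differ")
    counts = design.groupby(["sex", "genotype"], observed=True).size()
    if len(counts) < 4 or (counts < 1).any():
        raise ValueError("all four sex x genotype cells must be nonempty")
    df = design.copy()
    df["value"] = y
    fit = ols("value ~ C(sex) * C(genotype)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    df_resid = float(tab.loc["Residual", "df"])
    tol = 1e-12 * max(float((y - y.mean()) @ (y - y.mean())), 1.0)
    out: dict = {"df_resid": df_resid}
    rows = {"sex": "C(sex)", "genotype": "C(genotype)",
            "interaction": "C(sex):C(genotype)"}
    for name, row in rows.items():
        ss = float(tab.loc[row, "sum_sq"])
        dfe = float(tab.loc[row, "df"])
        if ss <= tol:
            F, p = 0.0, 1.0
        elif ss_resid <= tol:
            F, p = np.inf, 0.0
        else:
            F = (ss / dfe) / (ss_resid / df_resid)
            p = float(stats.f.sf(F, dfe, df_resid))
        out[f"F_{name}"] = float(F)
        out[f"p_{name}"] = float(p)
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        cells = (df["sex"].astype(str) + ":" + df["genotype"].astype(str)).to_numpy()
        res = pairwise_tukeyhsd(y, cells)
        out["tukey"] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return out
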