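"""Synthetic data with planted ground truth for both pipelines.

Two generators:

* :func:`simulate_bold` — multi-subject 4D BOLD-like series over a small
  grid.  Connectivity is planted through latent network signals shared by
  the voxels of each network mask; the latent amplitude in each design cell
  is chosen so the expected within-mask pairwise correlation sits at a
  target Fisher z (baseline z plus cell-specific deltas), so effect sizes
  are specified directly in z units.  Noise is AR(1); six synthetic motion
  traces and one ventricular trace are linearly mixed into the data.

* :func:`simulate_counts` — gene-by-sample negative-binomial counts for a
  2x2 sex-by-genotype design with gene-wise dispersions, library-size
  variation, planted per-sex log2 fold changes (opposite-signed within-sex
  effects give the M+F- / M-F+ phenomenology), a structured artifact factor
  recoverable as a surrogate variable, and an RIN-like covariate effect.

Both are deterministic given their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preproc import BoldSeries, NuisanceSet

CELLS = [("M", "WT"), ("M", "MUT"), ("F", "WT"), ("F", "MUT")]


# ---------------------------------------------------------------------------
# fMRI simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskEffect:
    """Connectivity deltas (Fisher-z units) planted on one network mask.

    ``base_z`` is the within-mask z in the reference cell (female WT);
    ``sex`` adds for males, ``genotype`` adds for mutants, ``interaction``
    adds for mutant males only.
    """

    base_z: float = 0.3
    sex: float = 0.0
    genotype: float = 0.0
    interaction: float = 0.0

    def target_z(self, sex: str, genotype: str) -> float:
        z = self.base_z
        if sex == "M":
            z += self.sex
        if genotype == "MUT":
            z += self.genotype
        if sex == "M" and genotype == "MUT":
            z += self.interaction
        return z

    @property
    def effect_class(self) -> str:
        if self.interaction != 0:
            return "interaction"
        if self.genotype != 0:
            return "genotype"
        if self.sex != 0:
            return "sex"
        return "network"


@dataclass
class FmriSimSpec:
    """Study-condition description for the BOLD generator.

    Defaults mirror the 2x2 imaging cohort geometry used throughout the
    package's calibration experiments: a 16x16x8 grid, 120 retained frames
    at TR = 1 s, 5 subjects per cell, moderate temporal autocorrelation.
    """

    dims: tuple[int, int, int] = (16, 16, 8)
    n_timepoints: int = 120
    tr_s: float = 1.0
    voxel_size_mm: tuple[float, float, float] = (0.23, 0.23, 0.6)
    n_per_cell: int = 5
    ar1: float = 0.4
    masks: list[np.ndarray] = field(default_factory=list)  # 3D boolean each
    effects: list[MaskEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    nuisance_strength: float = 0.3
    network_band_hz: tuple[float, float] = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims) or self.n_timepoints < 2:
            raise ValueError("dims and n_timepoints must be positive")
        if not abs(self.ar1) < 1:
            raise ValueError("|AR(1) coefficient| must be < 1")
        if self.n_per_cell < 2:
            raise ValueError("need n_per_cell >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.masks) != len(self.effects):
            raise ValueError("one MaskEffect per mask required")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        for m in self.masks:
            if m.shape != tuple(self.dims):
                raise ValueError("mask shape must equal grid dims")
        for i, (mi, ei) in enumerate(zip(self.masks, self.effects)):
            for j in range(i + 1, len(self.masks)):
                if (mi & self.masks[j]).any() and ei != self.effects[j]:
                    raise ValueError(
                        f"masks {i} and {j} overlap with contradictory effects"
                    )


@dataclass
class FmriGroundTruth:
    """Per-voxel planted effect class plus the subject design table."""

    voxel_class: np.ndarray  # 3D array of strings
    design: pd.DataFrame
    target_z: dict  # (mask_index, sex, genotype) -> planted within-mask z


def _ar1(rng: np.random.Generator, shape: tuple[int, int], rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) rows, shape (n_series, t)."""
    e = rng.standard_normal(shape)
    if rho == 0:
        return e
    scale = np.sqrt(1 - rho**2)
    # start the recursion at the stationary marginal: x_0 = e_0
    e = e.copy()
    e[:, 0] /= scale
    return lfilter([scale], [1.0, -rho], e, axis=1)


def _bandlimited(rng: np.random.Generator, n: int, t: int, tr_s: float,
                 band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian signals with power confined to ``band`` (Hz).

    Emulates slow hemodynamic network fluctuations: white noise is
    restricted to the band in the frequency domain and rescaled to unit
    variance, so the analysis band-pass retains the network signal fully.
    """
    e = rng.standard_normal((n, t))
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate band: fall back to white signals
        return e
    spec = np.fft.rfft(e, axis=1)
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=t, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _smooth_traces(rng: np.random.Generator, n: int, t: int) -> np.ndarray:
    """Slow random traces (cumulative sums, detrended, unit variance)."""
    steps = rng.standard_normal((n, t))
    walk = np.cumsum(steps, axis=1)
    walk -= walk.mean(axis=1, keepdims=True)
    sd = walk.std(axis=1)
    sd[sd == 0] = 1.0
    return walk / sd[:, None]


def _amplitude(z: float, noise_sd: float) -> float:
    """Latent weight giving expected pairwise correlation tanh(z).

    Two voxels w*s + noise share corr r = w^2 / (w^2 + sd^2), so
    w = sd * sqrt(r / (1 - r)).
    """
    r = np.tanh(z)
    if r <= 0:
        return 0.0
    return float(noise_sd * np.sqrt(r / (1.0 - r)))


def simulate_bold(
    spec: FmriSimSpec,
) -> tuple[list[BoldSeries], list[NuisanceSet], FmriGroundTruth]:
    """Generate one subject cohort; see the module docstring for the model."""
    rng = np.random.default_rng(spec.seed)
    dims, t = tuple(spec.dims), spec.n_timepoints
    n_vox = int(np.prod(dims))
    mask = np.ones(dims, dtype=bool)

    voxel_class = np.full(dims, "null", dtype=object)
    for m, e in zip(spec.masks, spec.effects):
        voxel_class[m] = e.effect_class

    rows = []
    for sex, geno in CELLS:
        for k in range(spec.n_per_cell):
            rows.append({"subject": f"{sex}_{geno}_{k:02d}", "sex": sex,
                         "genotype": geno})
    design = pd.DataFrame(rows)

    target_z = {}
    series, nuisances = [], []
    for _, row in design.iterrows():
        noise = spec.noise_sd * _ar1(rng, (n_vox, t), spec.ar1)
        data = noise.reshape(*dims, t)
        latents = _bandlimited(rng, max(len(spec.masks), 1), t, spec.tr_s,
                               spec.network_band_hz)
        for mi, (m, eff) in enumerate(zip(spec.masks, spec.effects)):
            z = eff.target_z(row.sex, row.genotype)
            target_z[(mi, row.sex, row.genotype)] = z
            w = _amplitude(z, spec.noise_sd)
            data[m] += w * latents[mi]

        motion = _smooth_traces(rng, 6, t).T  # (t, 6)
        vent = _smooth_traces(rng, 1, t)[0]
        nu = NuisanceSet(motion, vent)
        if spec.nuisance_strength > 0:
            loads = spec.nuisance_strength * rng.standard_normal((n_vox, 7))
            traces = np.vstack([motion.T, vent[None, :]])  # (7, t)
            data += (loads @ traces).reshape(*dims, t)

        series.append(
            BoldSeries(data, mask, spec.voxel_size_mm, spec.tr_s, row.subject)
        )
        nuisances.append(nu)

    truth = FmriGroundTruth(voxel_class, design, target_z)
    return series, nuisances, truth


def box_mask(dims: tuple[int, int, int], lo: tuple[int, int, int],
             hi: tuple[int, int, int]) -> np.ndarray:
    """Convenience rectangular mask with half-open bounds [lo, hi)."""
    m = np.zeros(dims, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


# ---------------------------------------------------------------------------
# RNA-seq counts simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSet:
    """A disjoint block of genes carrying per-sex log2 fold changes."""

    name: str
    genes: tuple[int, ...]  # gene indices
    male_log2fc: float
    female_log2fc: float

    @property
    def true_class(self) -> str:
        m, f = self.male_log2fc, self.female_log2fc
        if m > 0 and f < 0:
            return "M+F-"
        if m < 0 and f > 0:
            return "M-F+"
        if m != 0 and f != 0:
            return "concordant"
        return "null"


@dataclass
class CountsSimSpec:
    """Study-condition description for the NB count generator.

    The default geometry matches a small bulk RNA-seq cohort: 2000 genes,
    a 2x2 design with ~5 samples per cell, lognormal baseline expression,
    gene-wise NB dispersions with variance mu + phi*mu^2, moderate
    library-size spread, a binary structured artifact over ~30% of genes,
    and a weak RIN-like covariate effect.
    """

    n_genes: int = 2000
    n_per_cell: int | dict = 5
    baseline_mean_log2cpm: float = 4.0
    baseline_sd_log2cpm: float = 1.5
    dispersion_median: float = 0.05
    dispersion_log_sd: float = 0.5
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    planted: list[PlantedSet] = field(default_factory=list)
    artifact_gene_frac: float = 0.3
    artifact_strength: float = 1.0
    artifact_sample_frac: float = 0.5
    rin_gene_frac: float = 0.2
    rin_strength: float = 0.1
    x_chrom_frac: float = 0.05
    homolog_frac: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.dispersion_median <= 0:
            raise ValueError("dispersions must be positive")
        seen: set[int] = set()
        for ps in self.planted:
            idx = set(ps.genes)
            if idx & seen:
                raise ValueError(f"planted set {ps.name} overlaps another set")
            if max(idx, default=-1) >= self.n_genes or min(idx, default=0) < 0:
                raise ValueError(f"planted set {ps.name} has out-of-range genes")
            seen |= idx

    def cell_n(self, sex: str, geno: str) -> int:
        if isinstance(self.n_per_cell, dict):
            return int(self.n_per_cell[(sex, geno)])
        return int(self.n_per_cell)


@dataclass
class CountsGroundTruth:
    """Per-gene planted class and true within-sex log2 fold changes."""

    gene_class: pd.Series  # index: gene IDs
    male_log2fc: pd.Series
    female_log2fc: pd.Series
    artifact: pd.Series  # per-sample artifact scores (binary)
    design: pd.DataFrame


def simulate_counts(spec: CountsSimSpec):
    """Generate (CountMatrix, design table, ground truth) for a 2x2 design."""
    from .rnaseq import CountMatrix

    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    gene_ids = np.array([f"gene{i:05d}" for i in range(g)])

    base_log2cpm = rng.normal(spec.baseline_mean_log2cpm,
                              spec.baseline_sd_log2cpm, g)
    if not np.all(np.isfinite(base_log2cpm)):
        raise ValueError("non-finite baseline expression")
    for ps in spec.planted:
        if np.any(2.0 ** base_log2cpm[list(ps.genes)] == 0):
            raise ValueError(f"planted set {ps.name} hits a zero-baseline gene")

    disp = np.exp(rng.normal(np.log(spec.dispersion_median),
                             spec.dispersion_log_sd, g))

    rows = []
    for sex, geno in CELLS:
        for k in range(spec.cell_n(sex, geno)):
            rows.append({"sample": f"{sex}_{geno}_{k:02d}", "sex": sex,
                         "genotype": geno})
    design = pd.DataFrame(rows)
    n = len(design)
    design["rin"] = rng.uniform(7.5, 9.5, n)

    male_fc = np.zeros(g)
    female_fc = np.zeros(g)
    gene_class = np.full(g, "null", dtype=object)
    for ps in spec.planted:
        idx = list(ps.genes)
        male_fc[idx] = ps.male_log2fc
        female_fc[idx] = ps.female_log2fc
        gene_class[idx] = ps.true_class

    art_genes = rng.random(g) < spec.artifact_gene_frac
    art_load = np.where(art_genes, rng.standard_normal(g), 0.0)
    # balanced binary artifact across cells -> near-orthogonal to the design
    art_sample = np.zeros(n)
    for sex, geno in CELLS:
        cell_idx = np.flatnonzero((design.sex == sex) & (design.genotype == geno))
        k = int(round(spec.artifact_sample_frac * len(cell_idx)))
        art_sample[rng.choice(cell_idx, size=k, replace=False)] = 1.0

    rin_genes = rng.random(g) < spec.rin_gene_frac
    rin_slope = np.where(rin_genes, rng.normal(0, spec.rin_strength, g), 0.0)
    rin_c = design["rin"].to_numpy() - design["rin"].mean()

    libsizes = rng.uniform(*spec.libsize_range, n)

    # per-sample expected log2 relative expression
    log2rel = np.tile(base_log2cpm[:, None], (1, n))
    is_mut = (design.genotype == "MUT").to_numpy()
    is_male = (design.sex == "M").to_numpy()
    log2rel[:, is_mut & is_male] += male_fc[:, None]
    log2rel[:, is_mut & ~is_male] += female_fc[:, None]
    log2rel += spec.artifact_strength * np.outer(art_load, art_sample)
    log2rel += np.outer(rin_slope, rin_c)

    rel = 2.0 ** log2rel
    rel /= rel.sum(axis=0, keepdims=True)
    mu = rel * libsizes[None, :]
    # NB with variance mu + phi mu^2: shape r = 1/phi, p = r/(r+mu)
    r_shape = 1.0 / disp[:, None]
    p = r_shape / (r_shape + mu)
    counts = rng.negative_binomial(r_shape, p)

    chroms = rng.choice(
        [str(c) for c in range(1, 20)] + ["X"],
        size=g,
        p=[(1 - spec.x_chrom_frac) / 19] * 19 + [spec.x_chrom_frac],
    )
    homolog = np.where(rng.random(g) < spec.homolog_frac,
                       np.char.upper(gene_ids), "")
    gene_meta = pd.DataFrame(
        {"chromosome": chroms, "human_homolog": homolog}, index=gene_ids
    )
    counts_df = pd.DataFrame(counts, index=gene_ids,
                             columns=design["sample"].to_numpy())

    cm = CountMatrix(counts_df, gene_meta, design)
    truth = CountsGroundTruth(
        gene_class=pd.Series(gene_class, index=gene_ids),
        male_log2fc=pd.Series(male_fc, index=gene_ids),
        female_log2fc=pd.Series(female_fc, index=gene_ids),
        artifact=pd.Series(art_sample, index=design["sample"].to_numpy()),
        design=design,
    )
    return cm, design, truth
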