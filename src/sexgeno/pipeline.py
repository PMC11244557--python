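"""Configuration-driven orchestration of the two analysis pipelines.

A :class:`RunConfig` (usually loaded from YAML) names one pipeline —

* ``imaging``: simulate (or read) BOLD series -> trim -> nuisance
  regression -> smoothing -> band-pass -> connectivity maps -> factorial
  t maps -> permutation cluster-extent FWER;
* ``omics``: simulate (or read) counts -> filter -> TMM -> log-CPM ->
  precision weights -> surrogate variables -> weighted factorial fit ->
  M+F-/M-F+ classification -> hypergeometric enrichment;

and every artifact written carries a provenance manifest with the config
hash, so re-running an identical config reproduces identical outputs.
Unknown configuration keys are rejected before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .connectivity import SeedSpec, global_connectivity, local_connectivity, seed_connectivity
from .enrich import GeneSet, enrich_many, chromosome_enrich, map_homologs
from .preproc import preprocess
from .rnaseq import run_de_pipeline
from .simulate import CountsSimSpec, FmriSimSpec, MaskEffect, PlantedSet, simulate_bold, simulate_counts
from .statmap import cluster_fwer, voxelwise_glm

_ALLOWED = {
    "top": {"pipeline", "seed", "out_dir", "imaging", "omics"},
    "imaging": {"sim", "preproc", "connectivity", "stats"},
    "imaging.sim": {"dims", "n_timepoints", "tr_s", "voxel_size_mm",
                    "n_per_cell", "ar1", "noise_sd", "nuisance_strength",
                    "masks", "effects"},
    "imaging.preproc": {"n_drop", "fwhm_mm", "band"},
    "imaging.connectivity": {"kind", "radius_vox", "seed_center", "seed_extent",
                             "average_domain"},
    "imaging.stats": {"contrast", "t_thresh", "n_perm", "connectivity"},
    "omics": {"sim", "counts", "design", "gene_meta", "de", "enrichment"},
    "omics.sim": {"n_genes", "n_per_cell", "planted", "artifact_strength",
                  "artifact_gene_frac", "artifact_sample_frac",
                  "dispersion_median", "libsize_range", "x_chrom_frac"},
    "omics.de": {"n_sv", "q_thresh", "min_reads", "min_samples", "var_quantile"},
    "omics.enrichment": {"gmt", "homolog_map", "chromosomes"},
}


def _check_keys(d: dict, scope: str) -> None:
    extra = set(d) - _ALLOWED[scope]
    if extra:
        raise ValueError(f"unknown config key(s) {sorted(extra)} under {scope!r}")


@dataclass
class RunConfig:
    """Validated pipeline configuration with a stable content hash."""

    pipeline: str
    seed: int = 0
    out_dir: str = "results/run"
    imaging: dict = field(default_factory=dict)
    omics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pipeline not in ("imaging", "omics"):
            raise ValueError("pipeline must be 'imaging' or 'omics'")
        _check_keys(self.imaging, "imaging")
        _check_keys(self.omics, "omics")
        for section, sub in (("imaging", self.imaging), ("omics", self.omics)):
            for key, val in sub.items():
                scope = f"{section}.{key}"
                if scope in _ALLOWED and isinstance(val, dict):
                    _check_keys(val, scope)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        _check_keys(raw, "top")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths like out_dir excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _fmri_spec(cfg: RunConfig) -> FmriSimSpec:
    sim = dict(cfg.imaging.get("sim", {}))
    masks_cfg = sim.pop("masks", [])
    effects_cfg = sim.pop("effects", [])
    dims = tuple(sim.get("dims", (16, 16, 8)))
    masks, effects = [], []
    for mc, ec in zip(masks_cfg, effects_cfg):
        m = np.zeros(dims, dtype=bool)
        lo, hi = mc["lo"], mc["hi"]
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        masks.append(m)
        effects.append(MaskEffect(**ec))
    for key in ("dims", "voxel_size_mm"):
        if key in sim:
            sim[key] = tuple(sim[key])
    return FmriSimSpec(seed=cfg.seed, masks=masks, effects=effects, **sim)


def run_imaging(cfg: RunConfig, out: Path) -> dict:
    spec = _fmri_spec(cfg)
    series, nuisances, truth = simulate_bold(spec)
    pp = cfg.imaging.get("preproc", {})
    band = tuple(pp.get("band", (0.01, 0.1)))
    conn_cfg = cfg.imaging.get("connectivity", {})
    kind = conn_cfg.get("kind", "global")
    maps = []
    for b, nu in zip(series, nuisances):
        clean = preprocess(b, nu, n_drop=int(pp.get("n_drop", 0)),
                           fwhm_mm=float(pp.get("fwhm_mm", 0.6)), band=band)
        if kind == "global":
            m = global_connectivity(clean, conn_cfg.get("average_domain", "z"))
        elif kind == "local":
            m = local_connectivity(clean, int(conn_cfg.get("radius_vox", 6)),
                                   conn_cfg.get("average_domain", "z"))
        elif kind == "seed":
            m = seed_connectivity(clean, SeedSpec(
                tuple(conn_cfg["seed_center"]),
                tuple(conn_cfg.get("seed_extent", (3, 3, 1)))))
        else:
            raise ValueError(f"unknown connectivity kind {kind!r}")
        maps.append(m)

    stats_cfg = cfg.imaging.get("stats", {})
    tmaps = voxelwise_glm(maps, truth.design)
    contrast = stats_cfg.get("contrast", "interaction")
    tmap = next(t for t in tmaps if t.contrast == contrast)
    res = cluster_fwer(
        tmap, maps, truth.design,
        t_thresh=float(stats_cfg.get("t_thresh", 2.1)),
        n_perm=int(stats_cfg.get("n_perm", 500)),
        seed=cfg.seed,
        connectivity=int(stats_cfg.get("connectivity", 6)),
    )
    for t in tmaps:
        io.write_map_like(t, out / f"tmap_{t.contrast}.nii")
    rows = [{"extent": c.extent, "peak_t": c.peak_t, "sign": c.sign,
             "corrected_p": c.corrected_p} for c in res.clusters]
    pd.DataFrame(rows, columns=["extent", "peak_t", "sign", "corrected_p"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False, float_format="%.6g")
    io.write_design(truth.design, out / "design.tsv")
    return {"n_subjects": len(series), "n_clusters": len(res.clusters),
            "contrast": contrast,
            "n_significant": len(res.significant())}


def _counts_spec(cfg: RunConfig) -> CountsSimSpec:
    sim = dict(cfg.omics.get("sim", {}))
    planted = [PlantedSet(p["name"], tuple(p["genes"]),
                          p["male_log2fc"], p["female_log2fc"])
               for p in sim.pop("planted", [])]
    if "libsize_range" in sim:
        sim["libsize_range"] = tuple(sim["libsize_range"])
    if isinstance(sim.get("n_per_cell"), dict):
        sim["n_per_cell"] = {tuple(k.split("_")): v
                             for k, v in sim["n_per_cell"].items()}
    return CountsSimSpec(seed=cfg.seed, planted=planted, **sim)


def run_omics(cfg: RunConfig, out: Path) -> dict:
    if "sim" in cfg.omics:
        cm, design, _truth = simulate_counts(_counts_spec(cfg))
    else:
        design = io.read_design(cfg.omics["design"])
        meta = (io.read_gene_meta(cfg.omics["gene_meta"])
                if "gene_meta" in cfg.omics else None)
        cm = io.read_counts(cfg.omics["counts"], gene_meta=meta, design=design)
    de_cfg = cfg.omics.get("de", {})
    res, filtered = run_de_pipeline(
        cm, design,
        n_sv=int(de_cfg.get("n_sv", 2)),
        q_thresh=float(de_cfg.get("q_thresh", 0.05)),
        min_reads=int(de_cfg.get("min_reads", 100)),
        min_samples=int(de_cfg.get("min_samples", 2)),
        var_quantile=float(de_cfg.get("var_quantile", 0.15)),
    )
    res.table.rename_axis("gene_id").to_csv(out / "de_results.tsv", sep="\t",
                                            float_format="%.6g")
    summary: dict = {
        "n_genes_input": len(cm.counts),
        "n_genes_analyzed": len(filtered.counts),
        "n_interaction_de": int((res.table["gene_class"] != "NS").sum()),
        "n_MplusFminus": int((res.table["gene_class"] == "M+F-").sum()),
        "n_MminusFplus": int((res.table["gene_class"] == "M-F+").sum()),
    }
    enr_cfg = cfg.omics.get("enrichment", {})
    background = GeneSet("background", frozenset(filtered.counts.index))
    queries = []
    for label in ("M+F-", "M-F+"):
        genes = res.genes_in_class(label)
        if len(genes):
            queries.append(GeneSet(label, frozenset(genes)))
    if "gmt" in enr_cfg and queries:
        lists = io.read_gmt(enr_cfg["gmt"])
        if "homolog_map" in enr_cfg:
            table = io.read_homolog_table(enr_cfg["homolog_map"])
            queries = [map_homologs(q, table) for q in queries]
            background = map_homologs(background, table)
        enr = enrich_many(queries, lists, background)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        summary["n_enrichment_tests"] = len(enr)
    if enr_cfg.get("chromosomes") and queries and filtered.gene_meta is not None:
        for q in queries:
            if q.namespace != "mouse":
                continue
            tab = chromosome_enrich(q, filtered.gene_meta["chromosome"], background)
            tag = q.name.replace("+", "p").replace("-", "m")
            tab.to_csv(out / f"chromosome_{tag}.tsv", sep="\t", index=False,
                       float_format="%.6g")
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured pipeline and write a provenance manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = run_imaging(cfg, out) if cfg.pipeline == "imaging" else run_omics(cfg, out)
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "summary": summary,
    }
    (out / "provenance.json").write_text(json.dumps(manifest, indent=2,
                                                    sort_keys=True, default=str))
    return summary
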