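#!/usr/bin/env python
"""Simulate the transcriptomic cohort: NB counts for a 2x2 design.

Generates 2000 genes for 4 WT + 5 MUT samples per sex (the bulk RNA-seq
cohort geometry), with 40 planted M+F- genes (log2FC +1.5 in males,
-1.5 in females), 40 planted M-F+ genes (the reverse), a structured
artifact factor over ~30% of genes, and an RIN-like covariate effect.
Writes counts, design, gene metadata and ground truth under
results/rnaseq_cohort/.
"""

import json
from pathlib import Path

from sexgeno import io
from sexgeno.simulate import CountsSimSpec, PlantedSet, simulate_counts

OUT = Path(__file__).resolve().parents[1] / "results" / "rnaseq_cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CountsSimSpec(
        n_genes=2000,
        n_per_cell={("M", "WT"): 4, ("M", "MUT"): 5,
                    ("F", "WT"): 4, ("F", "MUT"): 5},
        planted=[PlantedSet("M+F-", tuple(range(0, 40)), 1.5, -1.5),
                 PlantedSet("M-F+", tuple(range(40, 80)), -1.5, 1.5)],
        seed=20240902,
    )
    cm, design, truth = simulate_counts(spec)
    io.write_counts(cm, OUT / "counts.tsv")
    io.write_design(design, OUT / "design.tsv")
    io.write_gene_meta(cm.gene_meta, OUT / "gene_meta.tsv")
    truth.gene_class.rename("true_class").rename_axis("gene_id").to_csv(
        OUT / "true_classes.tsv", sep="\t")
    (OUT / "ground_truth.json").write_text(json.dumps({
        "n_genes": spec.n_genes,
        "planted": {ps.name: len(ps.genes) for ps in spec.planted},
        "artifact_samples": truth.artifact[truth.artifact > 0].index.tolist(),
    }, indent=2))
    print(f"wrote {spec.n_genes} genes x {len(design)} samples to {OUT}")
    print(truth.gene_class.value_counts().to_string())


if __name__ == "__main__":
    main()
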