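#!/usr/bin/env python
"""Hypergeometric odds-ratio enrichment of the DE classes.

Builds a small synthetic gene-set collection (the planted gene list plus
decoy lists drawn from the analyzed universe), converts everything
through a synthetic mouse-to-human homolog table, runs the enrichment
tests with the post-filter universe as background, and tests each class
for chromosome disproportionality.  Requires 05_differential_expression.py
output.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sexgeno import io
from sexgeno.enrich import GeneSet, chromosome_enrich, enrich_many, map_homologs

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(20240903)
    de = pd.read_csv(ROOT / "de" / "de_results.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(ROOT / "rnaseq_cohort" / "true_classes.tsv",
                        sep="\t", index_col=0, keep_default_na=False)
    meta = io.read_gene_meta(ROOT / "rnaseq_cohort" / "gene_meta.tsv")
    universe = list(de.index)

    # synthetic candidate lists: the planted genes (with decoys) and pure noise
    planted = [g for g in truth.index[truth["true_class"] != "null"]
               if g in de.index]
    decoys = rng.choice([g for g in universe if g not in set(planted)], 120,
                        replace=False).tolist()
    lists = [GeneSet("planted_plus_decoys", frozenset(planted + decoys[:60])),
             GeneSet("random_list_1", frozenset(decoys[:80])),
             GeneSet("random_list_2",
                     frozenset(rng.choice(universe, 100, replace=False)))]
    io.write_gmt(lists, OUT / "lists.gmt")

    background = GeneSet("background", frozenset(universe))
    queries = [GeneSet(lbl, frozenset(de.index[de["gene_class"] == lbl]))
               for lbl in ("M+F-", "M-F+")
               if (de["gene_class"] == lbl).any()]

    # synthetic homolog table: ~85% of genes map to an uppercase human symbol
    homolog = meta.loc[meta["human_homolog"] != "", "human_homolog"]
    table = homolog.rename("human_id").rename_axis("mouse_id").reset_index()
    table.to_csv(OUT / "homolog_map.tsv", sep="\t", index=False)
    h_queries = [map_homologs(q, table) for q in queries]
    h_background = map_homologs(background, table)
    h_lists = [map_homologs(l, table) for l in lists]

    enr = enrich_many(h_queries, h_lists, h_background)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(enr[["query", "list", "a", "odds_ratio", "p_value", "q_value"]]
          .to_string(index=False))

    for q in queries:
        tab = chromosome_enrich(q, meta["chromosome"], background)
        tag = q.name.replace("+", "p").replace("-", "m")
        tab.to_csv(OUT / f"chromosome_{tag}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        top = tab.iloc[0]
        print(f"{q.name}: most disproportionate chromosome {top.chromosome} "
              f"(OR {top.odds_ratio:.2f}, q {top.q_value:.3f})")


if __name__ == "__main__":
    main()
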