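"""Hypergeometric odds-ratio gene-set enrichment.

Enrichment of a query gene set (e.g. an interaction DE class) against a
candidate list within a background universe (the post-filter gene set of
the DE analysis).  The p value is the upper tail P[X >= a] of the
hypergeometric distribution (one-sided: "enrichment"; depletion shows as
OR < 1 without a second test), and the odds ratio comes from the 2x2
overlap table with a Haldane–Anscombe +0.5 continuity correction applied
to all cells iff any cell is zero.  BH-FDR is computed across all lists
tested in one invocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene IDs with a namespace tag (``mouse`` or ``human``)."""

    name: str
    genes: frozenset[str]
    namespace: str = "mouse"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def map_homologs(genes: GeneSet, table: pd.DataFrame) -> GeneSet:
    """Translate gene IDs through a two-column homolog table.

    ``table`` columns: source ID, target ID (e.g. mouse_id, human_id).
    Unmapped genes are dropped with a logged count; many-to-one
    collisions are deduplicated.
    """
    if len(table) == 0:
        raise ValueError("empty homolog mapping table")
    src, dst = table.columns[:2]
    mapping = dict(zip(table[src].astype(str), table[dst].astype(str)))
    mapped = {mapping[g] for g in genes.genes if g in mapping and mapping[g]}
    n_drop = len(genes) - sum(1 for g in genes.genes if g in mapping and mapping[g])
    if n_drop:
        log.info("map_homologs(%s): %d of %d genes unmapped, dropped",
                 genes.name, n_drop, len(genes))
    if not mapped:
        raise ValueError(f"no gene of {genes.name!r} could be mapped")
    ns = "human" if genes.namespace == "mouse" else genes.namespace
    return GeneSet(genes.name, frozenset(mapped), ns)


@dataclass
class EnrichmentRow:
    """One (query, list) enrichment: overlap table, OR, p, overlap IDs."""

    query_name: str
    list_name: str
    a: int  # query & list
    b: int  # query only
    c: int  # list only
    d: int  # neither
    odds_ratio: float
    p_value: float
    overlap: frozenset[str]
    q_value: float = np.nan

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


def _odds_ratio(a: int, b: int, c: int, d: int,
                continuity: bool = True) -> float:
    if continuity and min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    if b * c == 0:
        return np.inf
    return (a * d) / (b * c)


def hypergeom_enrich(
    query: GeneSet, gene_list: GeneSet, background: GeneSet,
    continuity: bool = True,
) -> EnrichmentRow:
    """Upper-tail hypergeometric enrichment of ``query`` for ``gene_list``.

    The query must be a subset of the background; the candidate list is
    intersected with the background before testing.  With N = |background|,
    K = |list ∩ background|, n = |query| and a = |query ∩ list|,
    p = P[X >= a] for X ~ Hypergeom(N, K, n).
    """
    bg = background.genes
    stray = query.genes - bg
    if stray:
        raise ValueError(
            f"query {query.name!r} not within background; offenders include "
            f"{sorted(stray)[:5]}"
        )
    lst = gene_list.genes & bg
    overlap = query.genes & lst
    N, K, n, a = len(bg), len(lst), len(query.genes), len(overlap)
    b = n - a
    c = K - a
    d = N - K - b
    p = float(hypergeom.sf(a - 1, N, K, n))
    orr = _odds_ratio(a, b, c, d, continuity)
    return EnrichmentRow(query.name, gene_list.name, a, b, c, d, orr,
                         min(p, 1.0), frozenset(overlap))


def enrich_many(
    queries: list[GeneSet], lists: list[GeneSet], background: GeneSet,
    continuity: bool = True,
) -> pd.DataFrame:
    """All (query, list) tests with one BH-FDR family across them."""
    rows = [hypergeom_enrich(q, l, background, continuity)
            for q in queries for l in lists]
    qvals = bh_fdr(np.array([r.p_value for r in rows]))
    recs = []
    for r, qv in zip(rows, qvals):
        r.q_value = float(qv)
        recs.append({
            "query": r.query_name, "list": r.list_name, "a": r.a, "b": r.b,
            "c": r.c, "d": r.d, "odds_ratio": r.odds_ratio,
            "p_value": r.p_value, "q_value": r.q_value,
            "overlap_genes": ",".join(sorted(r.overlap)),
        })
    return pd.DataFrame(recs)


def chromosome_enrich(
    class_genes: GeneSet, gene_chroms: pd.Series, background: GeneSet,
) -> pd.DataFrame:
    """Per-chromosome disproportionality of a DE class.

    For each chromosome, the candidate list is that chromosome's
    background genes; the percentage of chromosome genes falling in the
    class is reported alongside OR, p, and BH q across chromosomes.
    """
    bg = background.genes
    missing = [g for g in bg if g not in gene_chroms.index]
    if missing:
        raise ValueError(
            f"chromosome label missing for background genes, e.g. {missing[:5]}"
        )
    rows = []
    for chrom, genes in gene_chroms.loc[list(bg)].groupby(gene_chroms.loc[list(bg)]):
        members = frozenset(genes.index)
        if not members:
            log.warning("chromosome %s has no background genes; skipped", chrom)
            continue
        r = hypergeom_enrich(class_genes,
                             GeneSet(f"chr{chrom}", members), background)
        pct = 100.0 * r.a / len(members)
        rows.append({"chromosome": str(chrom), "n_chrom_genes": len(members),
                     "n_in_class": r.a, "percent_in_class": pct,
                     "odds_ratio": r.odds_ratio, "p_value": r.p_value})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("p_value").reset_index(drop=True)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q values (order-preserving, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
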