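"""Ranked TF-motif enrichment of a gene set against the genome background.

For each TF model group the statistic is a one-sided hypergeometric upper
tail on gene counts: of N genome genes, K carry at least one site of the
group fully inside their promoter; drawing the n genes of the query set,
the p-value is P(X >= k) for the k set genes with a site.  Rows are ranked
by p ascending.  No multiple-testing correction is applied by default (the
ranking is on raw p-values); Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .errors import ValidationError
from .intervals import ChromSizes, GenomeInterval
from .io.aliases import AliasTable
from .io.annotation import GeneModel
from .pwm import SiteHit, WeightMatrix


def resolve_gene(alias: str, table: AliasTable) -> str:
    """Canonical gene id for any supported nomenclature (case-insensitive)."""
    return table.resolve(alias)


def promoter_region(gene: GeneModel, window: int,
                    sizes: ChromSizes) -> GenomeInterval:
    """The ``window`` bases immediately upstream of the TSS, strand-aware.

    Clipped to chromosome bounds; a TSS flush against the chromosome edge
    (no upstream space at all) is an error.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    size = sizes.get(gene.chrom)
    if gene.strand == "+":
        start, end = gene.tss - window, gene.tss
    else:
        start, end = gene.tss + 1, gene.tss + 1 + window
    start = max(start, 0)
    if size is not None:
        end = min(end, size)
    if start >= end:
        raise ValidationError(
            f"gene {gene.gene_id}: degenerate promoter at chromosome edge")
    return GenomeInterval(gene.chrom, start, end, strand=gene.strand,
                          name=gene.gene_id)


def genes_with_site(hits: Iterable[SiteHit],
                    promoters: Mapping[str, GenomeInterval],
                    matrix_group: Sequence[WeightMatrix]) -> set[str]:
    """Genes whose promoter fully contains >= 1 hit of any group matrix."""
    ids = {m.id for m in matrix_group}
    out: set[str] = set()
    for gene_id, prom in promoters.items():
        for h in hits:
            if (h.matrix_id in ids and h.region.chrom == prom.chrom
                    and h.region.start >= prom.start
                    and h.region.end <= prom.end):
                out.add(gene_id)
                break
    return out


@dataclass(frozen=True)
class EnrichmentRow:
    rank: int
    model: str
    source: str
    k: int  # set genes with a site
    n: int  # set size
    K: int  # genome genes with a site
    N: int  # genome gene count
    p_value: float


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k} N={N} K={K} n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrichment_table(gene_set: Sequence[str], all_genes: Sequence[str],
                     hits: Sequence[SiteHit],
                     promoters: Mapping[str, GenomeInterval],
                     catalog_groups: Mapping[str, Sequence[WeightMatrix]],
                     correct: bool = False) -> list[EnrichmentRow]:
    """One ranked row per TF model group.

    ``gene_set`` must already be resolved to canonical ids and be a subset
    of ``all_genes``; duplicates are removed.  With ``correct=True``
    p-values are Benjamini-Hochberg adjusted before ranking.
    """
    gene_set_u = sorted(set(gene_set))
    all_u = sorted(set(all_genes))
    if not gene_set_u:
        raise ValidationError("empty gene set")
    missing = set(gene_set_u) - set(all_u)
    if missing:
        raise ValidationError(f"gene set not within background: {sorted(missing)}")
    N, n = len(all_u), len(gene_set_u)
    rows = []
    for name in sorted(catalog_groups):
        group = catalog_groups[name]
        with_site = genes_with_site(hits, promoters, group)
        K = len(with_site & set(all_u))
        k = len(with_site & set(gene_set_u))
        p = hypergeom_upper_tail(k, N, K, n)
        source = group[0].source if group else "user"
        rows.append((name, source, k, K, p))
    if correct:
        adj = false_discovery_control([r[4] for r in rows], method="bh")
        rows = [(m, s, k, K, float(q)) for (m, s, k, K, _), q in zip(rows, adj)]
    rows.sort(key=lambda r: (r[4], -r[2], r[0]))
    return [EnrichmentRow(rank=i + 1, model=m, source=s, k=k, n=n, K=K, N=N,
                          p_value=p)
            for i, (m, s, k, K, p) in enumerate(rows)]


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view with the classic report columns."""
    return pd.DataFrame([{
        "Rank": r.rank, "Model": r.model, "Source": r.source,
        "Genes": r.k, "Genome": r.K, "P Value": r.p_value,
    } for r in rows])
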