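"""Cis-proximity linkage between fixed variants and differentially
expressed genes.

A variant is "adjacent" to a gene when it falls within the gene span
extended by a flanking window (3 kb by default) on both sides; interior
variants count with distance 0, flanking ones with the gap to the nearest
gene edge.  The adjacency summary reports the distinct fractions of linked
variants and linked DEGs, the quantities used to judge how much expression
divergence is plausibly cis-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = ["GeneInterval", "CisLink", "link_variants_to_genes", "adjacency_summary"]

DEFAULT_WINDOW = 3000


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class CisLink:
    gene_id: str
    variant_keys: list[tuple] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)

    @property
    def min_distance(self) -> int:
        return min(self.distances)


def _distance(pos: int, gene: GeneInterval) -> int:
    if gene.start <= pos <= gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - gene.end


def link_variants_to_genes(
    variant_keys: Sequence[tuple],
    genes: Sequence[GeneInterval],
    window: int = DEFAULT_WINDOW,
    include_gene_body: bool = True,
) -> list[CisLink]:
    """Link each variant to every gene within ``window`` bp of the gene span.

    ``variant_keys`` are (contig, pos, ref, alt) tuples.  A variant may link
    to multiple genes.  With ``include_gene_body=False`` variants inside the
    gene span are excluded (flanks only).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    links: dict[str, CisLink] = {}
    for gene in genes:
        for key in variant_keys:
            contig, pos = key[0], key[1]
            if contig != gene.contig_id:
                continue
            if not (gene.start - window <= pos <= gene.end + window):
                continue
            d = _distance(pos, gene)
            if d == 0 and not include_gene_body:
                continue
            link = links.setdefault(gene.gene_id, CisLink(gene_id=gene.gene_id))
            link.variant_keys.append(tuple(key))
            link.distances.append(d)
    return [links[g.gene_id] for g in genes if g.gene_id in links]


def adjacency_summary(
    links: Sequence[CisLink], n_variants_total: int, n_degs_total: int
) -> tuple[float, float]:
    """Percent of variants linked to a DEG and percent of DEGs with a linked
    variant, each rounded to one decimal."""
    if n_variants_total <= 0 or n_degs_total <= 0:
        raise ValueError("totals must be positive")
    linked_variants = {k for link in links for k in link.variant_keys}
    linked_genes = {link.gene_id for link in links}
    if len(linked_variants) > n_variants_total or len(linked_genes) > n_degs_total:
        raise ValueError("linked counts exceed the stated totals")
    pct_variants = round(100.0 * len(linked_variants) / n_variants_total, 1)
    pct_degs = round(100.0 * len(linked_genes) / n_degs_total, 1)
    return pct_variants, pct_degs
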