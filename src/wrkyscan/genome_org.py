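"""Chromosomal organization: ordinal renaming and 200-kb gene clusters."""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io_formats import GeneModel, UNPLACED

CLUSTER_WINDOW_BP = 200_000


@dataclass
class GeneCluster:
    cluster_id: str
    chromosome: str
    member_gene_ids: list[str]
    span_bp: int


def _chrom_key(chrom: str) -> tuple:
    """Natural sort key: Chr2 < Chr10; unplaced genes sort last."""
    if chrom == UNPLACED:
        return (1, 0, "")
    m = re.search(r"(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), chrom)
    return (0, 10**9, chrom)


def rename_by_position(genes: list[GeneModel], prefix: str) -> dict[str, str]:
    """Ordinal family names along the genome.

    Genes are sorted by (chromosome in natural numeric order, start); unplaced
    genes receive the final ordinals.  Returns gene_id -> new name.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in input")
    ordered = sorted(genes, key=lambda g: (_chrom_key(g.chromosome), g.start, g.gene_id))
    return {g.gene_id: f"{prefix}{i}" for i, g in enumerate(ordered, 1)}


def find_clusters(
    genes: list[GeneModel], window_bp: int = CLUSTER_WINDOW_BP
) -> list[GeneCluster]:
    """Maximal chains of >=2 family genes with consecutive start-to-start
    gaps <= window on one chromosome (the 200-kb cluster rule, transitive)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.placed:
            by_chrom.setdefault(g.chromosome, []).append(g)
    clusters: list[GeneCluster] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        members = sorted(by_chrom[chrom], key=lambda g: g.start)
        chain: list[GeneModel] = [members[0]]
        for g in members[1:]:
            if g.start - chain[-1].start <= window_bp:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chrom, chain, len(clusters)))
                chain = [g]
        if len(chain) >= 2:
            clusters.append(_make_cluster(chrom, chain, len(clusters)))
    return clusters


def _make_cluster(chrom: str, chain: list[GeneModel], idx: int) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"cluster{idx + 1}",
        chromosome=chrom,
        member_gene_ids=[g.gene_id for g in chain],
        span_bp=max(g.end for g in chain) - min(g.start for g in chain),
    )
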