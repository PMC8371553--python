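"""Genic-feature and CpG-island-zone annotation of tested sites.

Features follow the precedence promoter > exon > intron > intergenic, with
the promoter spanning a strand-oriented window around the TSS; intergenic
sites are assigned the gene with the nearest TSS (ties to the smaller TSS
coordinate). Island zoning is distance-based: inside an island, within the
shore width of an edge, within the shelf width beyond that, else open sea;
overlapping flanks resolve to the nearer island automatically.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneModel

logger = logging.getLogger(__name__)

FEATURES = ("promoter", "exon", "intron", "intergenic")
ISLAND_ZONES = ("island", "shore", "shelf", "open_sea")


@dataclass
class AnnotationConfig:
    promoter_upstream: int = 1000
    promoter_downstream: int = 1000
    shore_width: int = 2000
    shelf_width: int = 2000

    def validate(self) -> None:
        for name in ("promoter_upstream", "promoter_downstream", "shore_width", "shelf_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def promoter_interval(gene: GeneModel, config: AnnotationConfig) -> tuple[int, int]:
    """Genomic half-open promoter window, oriented by strand."""
    if gene.strand == "+":
        return gene.tss - config.promoter_upstream, gene.tss + config.promoter_downstream + 1
    return gene.tss - config.promoter_downstream, gene.tss + config.promoter_upstream + 1


class _ChromGeneIndex:
    """Per-chromosome lookup tables for feature annotation."""

    def __init__(self, genes: Sequence[GeneModel], config: AnnotationConfig):
        genes = sorted(genes, key=lambda g: (g.start, g.end))
        self.genes = genes
        self.starts = [g.start for g in genes]
        self.promoters = [promoter_interval(g, config) for g in genes]
        self.tss_sorted = sorted((g.tss, g.gene_id) for g in genes)
        self.tss_pos = [t for t, _ in self.tss_sorted]
        self.max_reach = max(
            [max(g.end - g.start, p[1] - p[0]) for g, p in zip(genes, self.promoters)],
            default=0,
        )

    def candidates(self, pos: int) -> list[int]:
        """Indices of genes whose span or promoter could contain ``pos``."""
        hi = bisect_right(self.starts, pos)
        lo = bisect_right(self.starts, pos - self.max_reach)
        return list(range(max(lo - 1, 0), min(hi + 1, len(self.genes))))

    def nearest_tss_gene(self, pos: int) -> str:
        i = bisect_right(self.tss_pos, pos)
        best: tuple[int, int, str] | None = None
        for j in (i - 1, i):
            if 0 <= j < len(self.tss_sorted):
                t, gid = self.tss_sorted[j]
                cand = (abs(pos - t), t, gid)
                if best is None or cand < best:
                    best = cand
        return best[2] if best else ""


def annotate_feature(
    site_chrom: str,
    site_pos: int,
    index_by_chrom: dict,
) -> tuple[str, str]:
    """(feature, gene_id) for one site; unknown chromosomes are intergenic
    with an empty gene_id."""
    index = index_by_chrom.get(site_chrom)
    if index is None or not index.genes:
        return "intergenic", ""
    promoter_hits = []
    exon_hit = None
    intron_hit = None
    for gi in index.candidates(site_pos):
        gene = index.genes[gi]
        lo, hi = index.promoters[gi]
        if lo <= site_pos < hi:
            promoter_hits.append((gene.tss, gene.gene_id))
        if gene.start <= site_pos < gene.end:
            exons = gene.exons or [(gene.start, gene.end)]
            if any(s <= site_pos < e for s, e in exons):
                if exon_hit is None or gene.tss < exon_hit[0]:
                    exon_hit = (gene.tss, gene.gene_id)
            else:
                if intron_hit is None or gene.tss < intron_hit[0]:
                    intron_hit = (gene.tss, gene.gene_id)
    if promoter_hits:
        return "promoter", min(promoter_hits)[1]
    if exon_hit:
        return "exon", exon_hit[1]
    if intron_hit:
        return "intron", intron_hit[1]
    return "intergenic", index.nearest_tss_gene(site_pos)


def annotate_island_zone(
    site_chrom: str,
    site_pos: int,
    islands_by_chrom: dict,
    config: AnnotationConfig,
) -> str:
    intervals = islands_by_chrom.get(site_chrom)
    if not intervals:
        return "open_sea"
    starts, ends = intervals
    i = bisect_right(starts, site_pos) - 1
    if i >= 0 and site_pos < ends[i]:
        return "island"
    dist = None
    if i >= 0:
        dist = site_pos - ends[i]
    if i + 1 < len(starts):
        d2 = starts[i + 1] - site_pos
        dist = d2 if dist is None else min(dist, d2)
    if dist is None:
        return "open_sea"
    if dist <= config.shore_width:
        return "shore"
    if dist <= config.shore_width + config.shelf_width:
        return "shelf"
    return "open_sea"


def annotate_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    islands: Sequence[tuple[str, int, int]],
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Add feature, gene_id, and island_zone columns to a site table."""
    cfg = config or AnnotationConfig()
    cfg.validate()
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    index_by_chrom = {c: _ChromGeneIndex(gs, cfg) for c, gs in genes_by_chrom.items()}
    islands_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, start, end in sorted(islands):
        islands_by_chrom.setdefault(chrom, ([], []))
        islands_by_chrom[chrom][0].append(start)
        islands_by_chrom[chrom][1].append(end)

    unknown = set(sites["chrom"]) - set(index_by_chrom)
    if unknown:
        logger.warning("annotate_sites: unknown chromosomes %s -> intergenic", sorted(unknown))

    features = []
    gene_ids = []
    zones = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        feat, gid = annotate_feature(chrom, int(pos), index_by_chrom)
        features.append(feat)
        gene_ids.append(gid)
        zones.append(annotate_island_zone(chrom, int(pos), islands_by_chrom, cfg))
    out = sites.copy()
    out["feature"] = features
    out["gene_id"] = gene_ids
    out["island_zone"] = zones
    return out


def summarize_contrast(annotated: pd.DataFrame) -> dict:
    """Hyper/hypo tallies of significant sites by chromosome, feature
    (promoter / gene_body / intergenic), and island zone.

    ``annotated`` must carry direction, feature, and island_zone columns.
    """
    sig = annotated[annotated["direction"].isin(["hyper", "hypo"])].copy()
    sig["feature_group"] = sig["feature"].map(
        {"promoter": "promoter", "exon": "gene_body", "intron": "gene_body",
         "intergenic": "intergenic"}
    )

    def tally(key: str, levels: Sequence[str]) -> dict:
        out = {
            lev: {"hyper": 0, "hypo": 0} for lev in levels
        } if levels else {}
        for val, grp in sig.groupby(key, observed=True):
            out.setdefault(str(val), {"hyper": 0, "hypo": 0})
            out[str(val)]["hyper"] = int((grp["direction"] == "hyper").sum())
            out[str(val)]["hypo"] = int((grp["direction"] == "hypo").sum())
        return out

    return {
        "n_hyper": int((sig["direction"] == "hyper").sum()),
        "n_hypo": int((sig["direction"] == "hypo").sum()),
        "by_chromosome": tally("chrom", []),
        "by_feature": tally("feature_group", ["promoter", "gene_body", "intergenic"]),
        "by_island_zone": tally("island_zone", list(ISLAND_ZONES)),
    }
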