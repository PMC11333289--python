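"""Genomic-feature and CpG-context classification of regions.

Each region receives exactly one feature class — promoter, 5'/3' UTR, exon,
intron or intergenic — decided at its midpoint with the precedence
promoter > utr5 > utr3 > exon > intron > intergenic, and one CpG context —
island, shore (within 2 kb of an island), shelf (the next 2 kb) or open
sea.  Midpoint classification guarantees a unique label per region, which
is what fraction summaries split by methylation direction require.

Promoters default to [TSS - 2000, TSS + 500) strand-aware.  UTRs are derived
from CDS versus transcript bounds: a midpoint inside an exon but outside the
CDS is 5' or 3' UTR depending on which side of the CDS it falls and the
gene's strand; genes without an annotated CDS contribute exon/intron only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "classify_feature",
    "classify_cpg_context",
    "annotate_dmrs",
    "annotation_summary",
    "FEATURE_CLASSES",
    "CPG_CONTEXTS",
]

FEATURE_CLASSES = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")
CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")

_PRECEDENCE = {c: i for i, c in enumerate(FEATURE_CLASSES)}


@dataclass(frozen=True)
class Gene:
    """A gene model (longest-transcript style): half-open 0-based intervals."""

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.tx_end <= self.tx_start:
            raise ValueError("tx_end must exceed tx_start")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError("exon outside transcript bounds")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class GenomeAnnotation:
    genes: list[Gene]
    islands: pd.DataFrame  # chrom, start, end
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        from .enrichment import merge_intervals

        if len(self.islands):
            self.islands = merge_intervals(self.islands)
        else:
            self.islands = pd.DataFrame(columns=["chrom", "start", "end"])
        for g in self.genes:
            L = self.chrom_lengths.get(g.chrom)
            if L is not None and g.tx_end > L:
                raise ValueError(f"gene {g.gene_id} exceeds chromosome length")


# ---------------------------------------------------------------------------
# feature classification
# ---------------------------------------------------------------------------

def _gene_class_at(gene: Gene, mid: int, promoter_up: int, promoter_down: int) -> str | None:
    """This gene's best label for a midpoint, or None if unrelated."""
    if gene.strand == "+":
        prom = (gene.tss - promoter_up, gene.tss + promoter_down)
    else:
        prom = (gene.tss - promoter_down, gene.tss + promoter_up)
    labels = []
    if prom[0] <= mid < prom[1]:
        labels.append("promoter")
    if gene.tx_start <= mid < gene.tx_end:
        in_exon = any(s <= mid < e for s, e in gene.exons)
        if in_exon:
            if gene.cds_start is not None and gene.cds_end is not None:
                if mid < gene.cds_start:
                    labels.append("utr5" if gene.strand == "+" else "utr3")
                elif mid >= gene.cds_end:
                    labels.append("utr3" if gene.strand == "+" else "utr5")
                else:
                    labels.append("exon")
            else:
                labels.append("exon")
        else:
            labels.append("intron")
    if not labels:
        return None
    return min(labels, key=_PRECEDENCE.get)


def classify_feature(
    region: tuple[str, int, int],
    ann: GenomeAnnotation,
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> tuple[str, str | None, int | None]:
    """Classify one region by its midpoint.

    Returns (feature_class, gene_id, signed distance to the assigned gene's
    TSS; positive = downstream in the gene's direction).  Intergenic regions
    are assigned the gene with the nearest TSS on the same chromosome (None
    if the chromosome has no genes).
    """
    chrom, start, end = region
    if ann.chrom_lengths and chrom not in ann.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    mid = (start + end) // 2
    best: tuple[int, int, str, Gene] | None = None
    for g in ann.genes:
        if g.chrom != chrom:
            continue
        lab = _gene_class_at(g, mid, promoter_up, promoter_down)
        if lab is None:
            continue
        key = (_PRECEDENCE[lab], abs(mid - g.tss))
        if best is None or key < (best[0], best[1]):
            best = (*key, lab, g)
    if best is not None:
        _, _, lab, g = best
        return lab, g.gene_id, _signed_tss_dist(g, mid)
    near = None
    for g in ann.genes:
        if g.chrom != chrom:
            continue
        if near is None or abs(mid - g.tss) < abs(mid - near.tss):
            near = g
    if near is None:
        return "intergenic", None, None
    return "intergenic", near.gene_id, _signed_tss_dist(near, mid)


def _signed_tss_dist(gene: Gene, mid: int) -> int:
    d = mid - gene.tss
    return d if gene.strand == "+" else -d


# ---------------------------------------------------------------------------
# CpG context
# ---------------------------------------------------------------------------

def classify_cpg_context(
    region: tuple[str, int, int],
    islands: pd.DataFrame,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> str:
    """island / shore / shelf / open_sea by midpoint distance to merged islands.

    A midpoint immediately adjacent to an island edge is 1 bp away; shores
    cover distances < shore_bp, shelves the next shelf_bp.
    """
    chrom, start, end = region
    mid = (start + end) // 2
    sub = islands[islands["chrom"] == chrom]
    if len(sub) == 0:
        return "open_sea"
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    inside = (starts <= mid) & (mid < ends)
    if inside.any():
        return "island"
    left = np.where(mid < starts, starts - mid, np.inf)  # island to the right
    right = np.where(mid >= ends, mid - ends + 1, np.inf)  # island to the left
    d = min(left.min(), right.min())
    if d < shore_bp:
        return "shore"
    if d < shore_bp + shelf_bp:
        return "shelf"
    return "open_sea"


# ---------------------------------------------------------------------------
# DMR annotation and summaries
# ---------------------------------------------------------------------------

def annotate_dmrs(
    dmrs: Sequence,
    ann: GenomeAnnotation,
    promoter_up: int = 2000,
    promoter_down: int = 500,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> pd.DataFrame:
    """Annotate DMRs (objects with chrom/start/end/direction, and optionally
    area_stat) with feature class, CpG context, gene and TSS distance.

    Also writes the gene label back onto each DMR object so downstream
    gene-level metrics can use it.
    """
    rows = []
    for d in dmrs:
        region = (d.chrom, d.start, d.end)
        feat, gene, dist = classify_feature(region, ann, promoter_up, promoter_down)
        ctx = classify_cpg_context(region, ann.islands, shore_bp, shelf_bp)
        if hasattr(d, "gene"):
            d.gene = gene
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "direction": getattr(d, "direction", "."),
                "feature": feat,
                "cpg_context": ctx,
                "gene": gene,
                "tss_distance": dist,
            }
        )
    return pd.DataFrame(rows)


def annotation_summary(annotated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Fraction tables per direction for each classification axis.

    Returns {"feature": ..., "cpg_context": ...}; rows are directions,
    columns the classes, each row summing to 1.
    """
    if len(annotated) == 0:
        raise ValueError("nothing to summarize")
    out = {}
    for axis, classes in (("feature", FEATURE_CLASSES), ("cpg_context", CPG_CONTEXTS)):
        tab = pd.crosstab(annotated["direction"], annotated[axis], normalize="index")
        tab = tab.reindex(columns=classes, fill_value=0.0)
        out[axis] = tab
    return out
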