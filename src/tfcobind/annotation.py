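"""Peak-to-gene annotation and condition comparison.

Peaks are classified by where their *summit* falls relative to gene structure
(5' UTR, CDS, intron, 3' UTR), or to an upstream/downstream window of
configurable size (default 50 kb) when the summit overlaps no gene body.
Peak-to-gene assignment uses the same window rule: a peak is assigned to every
gene whose body or upstream window contains the summit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .genomic_io import GeneModel, GenomicInterval, Peak

__all__ = [
    "AnnotationParams",
    "PeakAnnotation",
    "ConditionComparison",
    "GeneIndex",
    "classify_peak",
    "classify_peaks",
    "feature_distribution",
    "assign_peaks_to_genes",
    "compare_conditions",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("upstream", "five_utr", "cds", "intron", "three_utr", "downstream", "intergenic")

DEFAULT_PRIORITY = ("five_utr", "cds", "three_utr", "intron", "upstream", "downstream", "intergenic")


@dataclass(frozen=True)
class AnnotationParams:
    """Parameters of the annotation rule.

    upstream_pad is the padding distance upstream of the TSS (and, for the
    'downstream' category, past the gene 3' end) within which a peak is still
    linked to a gene. downstream_as_intergenic merges the downstream category
    into intergenic for reporting.
    """

    upstream_pad: int = 50_000
    feature_priority: tuple[str, ...] = DEFAULT_PRIORITY
    downstream_as_intergenic: bool = False
    nearest_gene_only: bool = False

    def __post_init__(self) -> None:
        if self.upstream_pad <= 0:
            raise ValueError("upstream_pad must be > 0")
        unknown = set(self.feature_priority) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in priority: {sorted(unknown)}")


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    category: str
    genes: tuple[str, ...]
    tss_distance: Optional[int]  # signed; negative = upstream of nearest gene's TSS


@dataclass
class ConditionComparison:
    n_condition_a: int
    n_condition_b: int
    fold_change: Optional[float]  # None when |a| == 0
    gained: list[Peak]
    lost: list[Peak]
    persistent: list[tuple[Peak, Peak]]


class GeneIndex:
    """Per-chromosome interval index of gene windows (body + pads)."""

    def __init__(self, genes: Sequence[GeneModel], params: AnnotationParams):
        self.params = params
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            pad = params.upstream_pad
            lo = max(0, g.interval.start - pad)
            hi = g.interval.end + pad
            self.trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)

    def candidates(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def _categorize_for_gene(gene: GeneModel, pos: int, pad: int) -> Optional[str]:
    """Category of position `pos` relative to one gene, or None if outside all windows."""
    iv = gene.interval
    if iv.start <= pos < iv.end:
        if gene.utr3 is not None and gene.utr3.start <= pos < gene.utr3.end:
            return "three_utr"
        in_exon = any(s <= pos < e for s, e in gene.exons)
        if not in_exon:
            return "intron"
        if gene.cds is None:
            return "cds"
        cs, ce = gene.cds
        if cs <= pos < ce:
            return "cds"
        # exonic, outside CDS: 5' or 3' side depends on strand
        if iv.strand == "+":
            return "five_utr" if pos < cs else "three_utr"
        return "five_utr" if pos >= ce else "three_utr"
    # outside the body: upstream or downstream window, strand-aware
    if iv.strand == "+":
        if iv.start - pad <= pos < iv.start:
            return "upstream"
        if iv.end <= pos < iv.end + pad:
            return "downstream"
    else:
        if iv.end <= pos < iv.end + pad:
            return "upstream"
        if iv.start - pad <= pos < iv.start:
            return "downstream"
    return None


def _tss_distance(gene: GeneModel, pos: int) -> int:
    """Signed distance to the TSS; negative means upstream of the TSS."""
    d = pos - gene.tss
    return d if gene.strand == "+" else -d


def classify_peak(
    peak: Peak,
    genes: Sequence[GeneModel] | GeneIndex,
    params: AnnotationParams | None = None,
) -> PeakAnnotation:
    """Classify one peak. For batch use, pass a prebuilt :class:`GeneIndex`."""
    params = params or AnnotationParams()
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, params)
    return _classify(peak, index)


def classify_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: AnnotationParams | None = None,
) -> list[PeakAnnotation]:
    params = params or AnnotationParams()
    index = GeneIndex(genes, params)
    if peaks and index.trees and all(p.chrom not in index.trees for p in peaks):
        logger.warning("no peak chromosome matches any gene chromosome; all intergenic")
    return [_classify(p, index) for p in peaks]


def _classify(peak: Peak, index: GeneIndex) -> PeakAnnotation:
    params = index.params
    pos = peak.summit
    hits: list[tuple[str, GeneModel]] = []
    for gene in index.candidates(peak.chrom, pos):
        cat = _categorize_for_gene(gene, pos, params.upstream_pad)
        if cat is not None:
            hits.append((cat, gene))
    if not hits:
        return PeakAnnotation(peak=peak, category="intergenic", genes=(), tss_distance=None)
    rank = {c: i for i, c in enumerate(params.feature_priority)}
    best_cat = min((c for c, _g in hits), key=lambda c: rank.get(c, len(rank)))
    if params.nearest_gene_only:
        nearest = min(hits, key=lambda cg: abs(pos - cg[1].tss))
        hits = [nearest]
        best_cat = nearest[0]
    gene_ids = tuple(sorted({g.gene_id for _c, g in hits}))
    nearest_gene = min((g for _c, g in hits), key=lambda g: abs(pos - g.tss))
    category = best_cat
    if category == "downstream" and params.downstream_as_intergenic:
        category = "intergenic"
    return PeakAnnotation(
        peak=peak,
        category=category,
        genes=gene_ids,
        tss_distance=_tss_distance(nearest_gene, pos),
    )


def feature_distribution(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Percentage of peaks per category; percentages sum to 100."""
    if not annotations:
        raise ValueError("empty annotation list")
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
    n = len(annotations)
    return {c: 100.0 * counts[c] / n for c in CATEGORIES if c in counts}


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: AnnotationParams | None = None,
) -> dict[str, list[Peak]]:
    """Map gene_id -> peaks whose summit lies in the gene body or upstream window.

    Genes without any peak are absent from the map. The downstream window is
    used for categorization only, not for assignment.
    """
    params = params or AnnotationParams()
    index = GeneIndex(genes, params)
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        for gene in index.candidates(p.chrom, p.summit):
            cat = _categorize_for_gene(gene, p.summit, params.upstream_pad)
            if cat is None or cat == "downstream":
                continue
            out.setdefault(gene.gene_id, []).append(p)
    return out


def _overlap_tree(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.interval.start, p.interval.end, p)
    return trees


def compare_conditions(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    min_overlap: int = 1,
) -> ConditionComparison:
    """Compare one factor's peak sets between two conditions (a = reference).

    `persistent` holds every (a, b) pair overlapping by >= min_overlap bp;
    `gained` are b-peaks with no a-overlap, `lost` a-peaks with no b-overlap.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees_a = _overlap_tree(peaks_a)
    trees_b = _overlap_tree(peaks_b)
    persistent: list[tuple[Peak, Peak]] = []
    lost: list[Peak] = []
    for pa in peaks_a:
        tree = trees_b.get(pa.chrom)
        partners = []
        if tree is not None:
            for iv in tree.overlap(pa.interval.start, pa.interval.end):
                if pa.interval.overlap(iv.data.interval) >= min_overlap:
                    partners.append(iv.data)
        if partners:
            persistent.extend((pa, pb) for pb in partners)
        else:
            lost.append(pa)
    gained: list[Peak] = []
    for pb in peaks_b:
        tree = trees_a.get(pb.chrom)
        hit = False
        if tree is not None:
            for iv in tree.overlap(pb.interval.start, pb.interval.end):
                if pb.interval.overlap(iv.data.interval) >= min_overlap:
                    hit = True
                    break
        if not hit:
            gained.append(pb)
    n_a, n_b = len(peaks_a), len(peaks_b)
    fold = (n_b / n_a) if n_a > 0 else None
    return ConditionComparison(
        n_condition_a=n_a,
        n_condition_b=n_b,
        fold_change=fold,
        gained=gained,
        lost=lost,
        persistent=persistent,
    )
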