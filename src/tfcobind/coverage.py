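"""Anchor-centered coverage profiles and normalized per-peak read counts.

Reads are supplied as genomic intervals (BED-style); values are scaled to
reads per million by the library size. TSS profiles are strand-aware: rows of
minus-strand anchors are flipped so bins always run 5' to 3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, Peak

__all__ = [
    "ProfileMatrix",
    "tss_profile",
    "peak_read_counts",
    "boxplot_summary",
    "group_welch_tests",
]


@dataclass
class ProfileMatrix:
    anchor_ids: list[str]
    window: int
    bin_width: int
    values: np.ndarray  # anchors x bins, reads per million

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        lo = -self.window
        cols = [lo + i * self.bin_width for i in range(self.n_bins)]
        return pd.DataFrame(self.values, index=self.anchor_ids, columns=cols)


def _reads_by_chrom(read_intervals: Sequence[GenomicInterval]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in read_intervals:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out = {}
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _e in items])
        ends = np.array([e for _s, e in items])
        max_len = int((ends - starts).max()) if len(items) else 0
        out[chrom] = (starts, ends, max_len)
    return out


def tss_profile(
    read_intervals: Sequence[GenomicInterval],
    anchors: Sequence[tuple[str, int, str]],
    window: int = 2000,
    bin_width: int = 50,
    library_size: int = 1,
    anchor_ids: Optional[Sequence[str]] = None,
) -> ProfileMatrix:
    """Binned read density around anchors, in reads per million.

    Each read adds 1 to every bin its interval overlaps within the +/- window
    around the anchor position. anchors are (chrom, position, strand) tuples;
    minus-strand rows are reversed.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if (2 * window) % bin_width != 0:
        raise ValueError("bin_width must divide 2 * window")
    n_bins = (2 * window) // bin_width
    index = _reads_by_chrom(read_intervals)
    values = np.zeros((len(anchors), n_bins))
    for i, (chrom, pos, strand) in enumerate(anchors):
        entry = index.get(chrom)
        if entry is None:
            continue
        starts, ends, max_len = entry
        lo, hi = pos - window, pos + window
        # reads starting in [lo - max_len, hi) are the only overlap candidates
        j0 = int(np.searchsorted(starts, lo - max_len))
        j1 = int(np.searchsorted(starts, hi))
        for j in range(j0, j1):
            s, e = int(starts[j]), int(ends[j])
            a, b = max(s, lo), min(e, hi)
            if a >= b:
                continue
            first = (a - lo) // bin_width
            last = (b - 1 - lo) // bin_width
            values[i, first : last + 1] += 1.0
        if strand == "-":
            values[i] = values[i][::-1]
    values *= 1e6 / library_size
    ids = list(anchor_ids) if anchor_ids is not None else [f"anchor{i}" for i in range(len(anchors))]
    return ProfileMatrix(anchor_ids=ids, window=window, bin_width=bin_width, values=values)


def peak_read_counts(
    read_intervals: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    library_size: int,
) -> np.ndarray:
    """Reads overlapping each peak interval, scaled to reads per million."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    index = _reads_by_chrom(read_intervals)
    out = np.zeros(len(peaks))
    for i, p in enumerate(peaks):
        entry = index.get(p.chrom)
        if entry is None:
            continue
        starts, ends, max_len = entry
        j0 = int(np.searchsorted(starts, p.interval.start - max_len))
        j1 = int(np.searchsorted(starts, p.interval.end))
        n = 0
        for j in range(j0, j1):
            if int(ends[j]) > p.interval.start and int(starts[j]) < p.interval.end:
                n += 1
        out[i] = n
    return out * (1e6 / library_size)


def boxplot_summary(values: Sequence[float]) -> dict:
    """Tukey box-plot summary with type-7 (linear interpolation) quartiles.

    Whiskers extend to the most extreme data points within 1.5 IQR of the
    quartiles; points beyond are outliers.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]),
    }


def group_welch_tests(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups of per-peak normalized counts,
    with Benjamini-Hochberg adjustment across all pairs."""
    from .diffexpr import bh_adjust

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_adjust(df["p"].tolist())
    return df
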