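"""Core genomic domain types and file I/O.

All coordinates are 0-based, half-open (BED convention). Formats that use
1-based inclusive coordinates (GTF) are converted at parse time so every
downstream module sees a single convention. Chromosome names are compared as
exact strings; :func:`normalize_chrom` can strip or add a ``chr`` prefix when
two inputs disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "SampleMeta",
    "CountMatrix",
    "ParseError",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_count_matrix",
    "write_count_matrix",
    "read_fasta",
    "write_fasta",
    "normalize_chrom",
]

GENOTYPES = ("control", "soxc_ko")
TREATMENTS = ("tnf", "untreated")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping base pairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called binding interval with an absolute summit coordinate."""

    interval: GenomicInterval
    summit: int
    factor: str = ""
    condition: str = ""
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS, exon structure and optional 3' UTR."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[int, int]] = None
    utr3: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand required for TSS")
        prev_end = None
        for (s, e) in self.exons:
            if not (self.interval.start <= s < e <= self.interval.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if self.utr3 is not None and (
            self.utr3.chrom != self.interval.chrom
            or self.utr3.start < self.interval.start
            or self.utr3.end > self.interval.end
        ):
            raise ValueError(f"gene {self.gene_id}: utr3 outside gene body")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based position)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")


@dataclass
class CountMatrix:
    """Raw RNA-seq counts, genes x samples."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("counts shape does not match gene_ids x samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        keys = [(s.genotype, s.treatment, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (genotype, treatment, replicate) in samples")

    def select(self, genotype: Optional[str] = None, treatment: Optional[str] = None) -> list[int]:
        """Column indices of samples matching the given metadata filters."""
        idx = []
        for j, s in enumerate(self.samples):
            if genotype is not None and s.genotype != genotype:
                continue
            if treatment is not None and s.treatment != treatment:
                continue
            idx.append(j)
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=[s.sample_id for s in self.samples]
        )


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize chromosome naming. ``style='chr'`` adds the prefix, ``'plain'`` strips it."""
    if style == "chr":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if style == "plain":
        return chrom[3:] if chrom.startswith("chr") else chrom
    raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# peaks


def _parse_int(text: str, lineno: int, path: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {text!r}") from None


def read_peaks(
    path: str | Path,
    format: str = "narrowPeak",
    factor: str = "",
    condition: str = "",
) -> list[Peak]:
    """Read peaks from narrowPeak (ENCODE 10-column) or BED6.

    A narrowPeak summit offset of -1 (and every BED6 peak) falls back to the
    interval midpoint, floored for even lengths. ``factor`` and ``condition``
    labels are attached to every record.
    """
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format {format!r}")
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            ncol = 10 if format == "narrowPeak" else 6
            if len(fields) < ncol:
                raise ParseError(f"{path}:{lineno}: expected {ncol} columns, got {len(fields)}")
            chrom = fields[0]
            start = _parse_int(fields[1], lineno, str(path), "start")
            end = _parse_int(fields[2], lineno, str(path), "end")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3]
            try:
                score = float(fields[4])
            except ValueError:
                score = 0.0
            strand = fields[5] if fields[5] in ("+", "-", ".") else "."
            if format == "narrowPeak":
                offset = _parse_int(fields[9], lineno, str(path), "summit offset")
                summit = start + offset if offset >= 0 else (start + end) // 2
            else:
                summit = (start + end) // 2
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit=summit,
                    factor=factor,
                    condition=condition,
                    score=score,
                    name=name,
                )
            )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    """Write peaks; the narrowPeak summit column round-trips exactly."""
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak{i + 1}"
            base = [
                p.interval.chrom,
                str(p.interval.start),
                str(p.interval.end),
                name,
                f"{p.score:g}",
                p.interval.strand,
            ]
            if format == "narrowPeak":
                base += ["0", "-1", "-1", str(p.summit - p.interval.start)]
            fh.write("\t".join(base) + "\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    if format == "bed12":
        return _read_bed12(Path(path))
    if format == "gtf_lite":
        return _read_gtf_lite(Path(path))
    raise ValueError(f"unknown gene model format {format!r}")


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom = f[0]
            start = _parse_int(f[1], lineno, str(path), "start")
            end = _parse_int(f[2], lineno, str(path), "end")
            name = f[3]
            strand = f[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand required for gene models")
            thick_start = _parse_int(f[6], lineno, str(path), "thickStart")
            thick_end = _parse_int(f[7], lineno, str(path), "thickEnd")
            n_blocks = _parse_int(f[9], lineno, str(path), "blockCount")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            cds = (thick_start, thick_end) if thick_start < thick_end else None
            utr3 = _utr3_from_cds(chrom, start, end, strand, cds)
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    cds=cds,
                    utr3=utr3,
                )
            )
    return genes


def _utr3_from_cds(
    chrom: str, start: int, end: int, strand: str, cds: Optional[tuple[int, int]]
) -> Optional[GenomicInterval]:
    # 3' UTR reported as the genomic span between the CDS 3' end and the
    # transcript end (unspliced span; downstream modules only test overlap).
    if cds is None:
        return None
    if strand == "+" and cds[1] < end:
        return GenomicInterval(chrom, cds[1], end, strand)
    if strand == "-" and start < cds[0]:
        return GenomicInterval(chrom, start, cds[0], strand)
    return None


def _read_gtf_lite(path: Path) -> list[GeneModel]:
    """Parse a GTF subset with gene / exon / three_prime_utr features.

    GTF is 1-based inclusive; converted to 0-based half-open here.
    """
    gene_span: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    utr3s: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            if feature not in ("gene", "exon", "three_prime_utr"):
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand required for gene models")
            start = _parse_int(start1, lineno, str(path), "start") - 1
            end = _parse_int(end1, lineno, str(path), "end")
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                gene_span[gid] = (chrom, start, end, strand)
                order.append(gid)
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
            else:
                utr3s[gid] = (start, end)
    genes = []
    for gid in order:
        chrom, start, end, strand = gene_span[gid]
        ex = tuple(sorted(exons.get(gid, [(start, end)])))
        for (a, _b), (_c, d) in zip(ex[1:], ex[:-1]):
            if a < d:
                raise ParseError(f"gene {gid}: overlapping exon blocks")
        utr = utr3s.get(gid)
        utr3 = GenomicInterval(chrom, utr[0], utr[1], strand) if utr else None
        genes.append(
            GeneModel(
                gene_id=gid,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=ex,
                utr3=utr3,
            )
        )
    return genes


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            val = part[len(key):].strip()
            return val.strip('"')
    return None


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (CDS span in thickStart/thickEnd)."""
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.interval.start, g.interval.end
            cds = g.cds if g.cds is not None else (start, start)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, _e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start),
                        str(end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(cds[0]),
                        str(cds[1]),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# counts


def read_count_matrix(path: str | Path, metadata: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV and join a sample sheet by sample_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "genotype", "treatment", "replicate"}
    if not required.issubset(meta.columns):
        raise ParseError(f"{metadata}: sample sheet needs columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    samples = []
    for sid in df.columns:
        if sid not in meta.index:
            raise ParseError(f"sample {sid!r} in count header missing from {metadata}")
        row = meta.loc[sid]
        samples.append(
            SampleMeta(
                sample_id=str(sid),
                genotype=str(row["genotype"]),
                treatment=str(row["treatment"]),
                replicate=int(row["replicate"]),
            )
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric counts")
    if np.any(values < 0):
        raise ParseError(f"{path}: negative count")
    if np.any(values != np.floor(values)):
        raise ParseError(f"{path}: non-integer count")
    return CountMatrix(
        gene_ids=[str(g) for g in df.index], samples=samples, counts=values.astype(np.int64)
    )


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.to_frame().to_csv(counts_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cm.samples],
            "genotype": [s.genotype for s in cm.samples],
            "treatment": [s.treatment for s in cm.samples],
            "replicate": [s.replicate for s in cm.samples],
        }
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
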