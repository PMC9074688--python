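"""Synthetic data generator with planted ground truth.

Emulates the structure of a two-factor (SOX4, RELA) x two-condition
(untreated, TNF) ChIP-seq experiment integrated with a two-genotype
(control, SoxC knockout) x two-treatment RNA-seq experiment:

* non-overlapping gene models on a small genome, each with an exclusive
  annotation territory so peak-to-gene assignment is unambiguous;
* stimulated peak sets with a planted co-bound fraction (partner summits
  within the co-binding distance) and a planted induced/basal peak-count
  fold;
* regulatory-switch loci in the 3' UTRs of designated autoregulated genes
  (factor-A binding at baseline replaced by factor-B binding on stimulation);
* negative-binomial counts with planted stimulus fold changes whose knockout
  behaviour (nulled or reversed) encodes dependence, laid out so each
  dependent gene carries the binding evidence of its planted regulatory
  class;
* random peak sequences with planted motif instances in co-bound peaks.

Every planted fact is recorded in a :class:`TruthManifest`; recovery tests
read expected values from the manifest only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genomic_io import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    SampleMeta,
    write_count_matrix,
    write_fasta,
    write_gene_models,
    write_peaks,
)
from .motifs import IUPAC

__all__ = [
    "CountsConfig",
    "MotifConfig",
    "SyntheticConfig",
    "TruthManifest",
    "SyntheticDataset",
    "simulate_gene_models",
    "simulate_peak_sets",
    "simulate_counts",
    "simulate_peak_sequences",
    "simulate_reads",
    "simulate_dataset",
    "write_dataset",
]

FACTOR_A = "SOX4"
FACTOR_B = "RELA"
BASAL = "untreated"
INDUCED = "tnf"

_MAX_GENE_SPAN = 20_000
_SLOT_MARGIN = 5_000


@dataclass
class CountsConfig:
    """RNA-seq arm of the design: two genotypes x two treatments, replicated.

    Defaults describe the clean, strong-effect regime used for planted-label
    recovery: fold changes of 3-5x, low biological dispersion (0.005, the
    near-isogenic-replicate regime), and base means drawn log-uniformly from
    150-3000 (emulating a count matrix already filtered for low expression).
    """

    n_responsive: int = 250
    fraction_dependent: float = 0.6
    fraction_reversed: float = 0.2
    true_fc_range: tuple[float, float] = (3.0, 5.0)
    nb_dispersion: float = 0.005
    depth_per_sample: int = 2_000_000
    n_replicates: int = 3
    base_mean_range: tuple[float, float] = (150.0, 3000.0)
    poisson: bool = False


@dataclass
class MotifConfig:
    consensus: str = "WWCAAW"  # SOX-like default
    planting_rate: float = 1.0


@dataclass
class SyntheticConfig:
    seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 25_000_000
    n_genes: int = 300
    n_peaks_a_induced: int = 585
    n_peaks_b_induced: int = 585
    n_peaks_a_basal: Optional[int] = None  # default: induced / induced_fold
    n_peaks_b_basal: Optional[int] = None
    induced_fold: float = 3.0
    cobind_fraction: float = 0.704
    summit_jitter_sd: float = 0.0
    max_summit_distance: int = 50
    n_switch_loci: int = 2
    n_class1: int = 20
    n_class2: int = 30
    upstream_pad: int = 50_000
    counts: CountsConfig = field(default_factory=CountsConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.cobind_fraction <= 1.0):
            raise ValueError("cobind_fraction must be in [0, 1]")
        if min(self.n_genes, self.n_peaks_a_induced, self.n_peaks_b_induced, self.n_switch_loci) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_genes > self.total_slots:
            raise ValueError(
                f"genome too small: {self.n_genes} genes need {self.n_genes} slots "
                f"of {self.slot_length} bp but only {self.total_slots} fit"
            )
        n_cobound = self.n_cobound
        if self.n_class1 > n_cobound:
            raise ValueError("n_class1 exceeds the number of co-bound pairs")
        if self.n_switch_loci > self.n_peaks_a_induced - n_cobound:
            raise ValueError("n_switch_loci exceeds the factor-A-only peak budget")
        if self.n_class2 > self.n_peaks_b_induced - n_cobound:
            raise ValueError("n_class2 exceeds the factor-B-only peak budget")
        n_dep = round(self.counts.n_responsive * self.counts.fraction_dependent)
        if self.n_class1 + self.n_class2 > n_dep:
            raise ValueError("class-1 + class-2 genes exceed the dependent-gene budget")
        if self.counts.n_responsive + self.n_switch_loci > self.n_genes:
            raise ValueError("responsive + switch genes exceed n_genes")

    @property
    def slot_length(self) -> int:
        return 2 * (self.upstream_pad + _SLOT_MARGIN) + _MAX_GENE_SPAN

    @property
    def total_slots(self) -> int:
        return self.n_chroms * (self.chrom_length // self.slot_length)

    @property
    def n_cobound(self) -> int:
        return round(self.cobind_fraction * self.n_peaks_a_induced)

    @property
    def n_a_basal(self) -> int:
        if self.n_peaks_a_basal is not None:
            return self.n_peaks_a_basal
        return round(self.n_peaks_a_induced / self.induced_fold)

    @property
    def n_b_basal(self) -> int:
        if self.n_peaks_b_basal is not None:
            return self.n_peaks_b_basal
        return round(self.n_peaks_b_induced / self.induced_fold)


@dataclass
class TruthManifest:
    """Planted ground truth; fully determines expected outputs when noise-free."""

    config: dict
    genes: dict = field(default_factory=dict)  # gene_id -> planted labels
    peaks: dict = field(default_factory=dict)  # peak name -> planted group etc.
    switch_loci: list = field(default_factory=list)
    motif_plantings: dict = field(default_factory=dict)
    samples: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)

    def planted_class_counts(self) -> dict[str, int]:
        out = {"class1": 0, "class2": 0, "class3": 0, "class4": 0}
        for info in self.genes.values():
            cls = info.get("planted_class")
            if cls:
                out[cls] += 1
        return out


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    peaks: dict[str, dict[str, list[Peak]]]  # factor -> condition -> peaks
    counts: CountMatrix
    sequences: dict[str, str]
    manifest: TruthManifest


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


# ---------------------------------------------------------------------------
# gene models


def _gene_slots(config: SyntheticConfig) -> list[tuple[str, int]]:
    """All (chrom, slot_start) territories on the genome, in genomic order."""
    slots = []
    per_chrom = config.chrom_length // config.slot_length
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for k in range(per_chrom):
            slots.append((chrom, k * config.slot_length))
    return slots


def simulate_gene_models(config: SyntheticConfig) -> list[GeneModel]:
    """Non-overlapping genes, each centered in an exclusive slot whose width
    covers the gene body plus both annotation pads."""
    rng = _rng(config, 1)
    slots = _gene_slots(config)
    if config.n_genes == 0:
        return []
    chosen = sorted(rng.choice(len(slots), size=config.n_genes, replace=False).tolist())
    genes: list[GeneModel] = []
    for gi, slot_idx in enumerate(chosen):
        chrom, slot_start = slots[slot_idx]
        for _ in range(100):
            n_ex = int(rng.integers(2, 9))
            exon_lens = rng.integers(150, 501, size=n_ex)
            intron_lens = rng.integers(800, 3001, size=n_ex - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if span <= _MAX_GENE_SPAN:
                break
        start = slot_start + config.upstream_pad + _SLOT_MARGIN + int(rng.integers(0, 2000))
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(exon_lens[k])))
            pos = exons[-1][1] + (int(intron_lens[k]) if k < n_ex - 1 else 0)
        end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            utr5_len = int(rng.integers(30, min(100, exon_lens[0] - 20)))
            utr3_len = int(exon_lens[-1]) - 60
            cds = (start + utr5_len, end - utr3_len)
            utr3 = GenomicInterval(chrom, end - utr3_len, end, strand)
        else:
            utr5_len = int(rng.integers(30, min(100, exon_lens[-1] - 20)))
            utr3_len = int(exon_lens[0]) - 60
            cds = (start + utr3_len, end - utr5_len)
            utr3 = GenomicInterval(chrom, start, start + utr3_len, strand)
        genes.append(
            GeneModel(
                gene_id=f"g{gi + 1:04d}",
                interval=GenomicInterval(chrom, start, end, strand),
                exons=tuple(exons),
                cds=cds,
                utr3=utr3,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# gene role assignment (shared by peak and count simulation)


def _assign_gene_roles(config: SyntheticConfig, genes: Sequence[GeneModel]) -> dict:
    """Deterministic split of genes into switch / class1 / class2 / class3 /
    independent-responsive / null roles (one rng stream so peaks and counts agree)."""
    rng = _rng(config, 2)
    cc = config.counts
    n_dep = round(cc.n_responsive * cc.fraction_dependent)
    n_rev = round(n_dep * cc.fraction_reversed)
    order = rng.permutation(len(genes))
    switch_idx = list(order[: config.n_switch_loci])
    resp_idx = list(order[config.n_switch_loci : config.n_switch_loci + cc.n_responsive])
    dep_idx = resp_idx[:n_dep]
    class1_idx = dep_idx[: config.n_class1]
    class2_idx = dep_idx[config.n_class1 : config.n_class1 + config.n_class2]
    class3_idx = dep_idx[config.n_class1 + config.n_class2 :]
    reversed_set = set(dep_idx[:n_rev]) if n_rev else set()
    # interleave so reversal is spread across classes deterministically
    return {
        "switch": switch_idx,
        "responsive": resp_idx,
        "dependent": dep_idx,
        "class1": class1_idx,
        "class2": class2_idx,
        "class3": class3_idx,
        "reversed": reversed_set,
    }


# ---------------------------------------------------------------------------
# peaks


def _make_peak(
    rng: np.random.Generator,
    chrom: str,
    summit: int,
    factor: str,
    condition: str,
    name: str,
) -> Peak:
    left = int(rng.integers(100, 201))
    right = int(rng.integers(100, 201))
    return Peak(
        interval=GenomicInterval(chrom, max(0, summit - left), summit + right),
        summit=summit,
        factor=factor,
        condition=condition,
        score=float(rng.uniform(5, 50)),
        name=name,
    )


def _upstream_anchor(rng: np.random.Generator, gene: GeneModel, pad: int) -> int:
    offset = int(rng.integers(2000, pad - 10_000))
    return gene.tss - offset if gene.strand == "+" else gene.tss + offset


def simulate_peak_sets(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    manifest: Optional[TruthManifest] = None,
) -> tuple[dict[str, dict[str, list[Peak]]], TruthManifest]:
    """Factor x condition peak sets with planted co-binding, induction fold
    and switch loci. Background peaks live in gene-free territories, so no
    planted-class gene picks up stray binding evidence."""
    if manifest is None:
        manifest = TruthManifest(config=dataclasses.asdict(config))
    rng = _rng(config, 3)
    roles = _assign_gene_roles(config, genes)
    pad = config.upstream_pad
    maxd = config.max_summit_distance

    n_cobound = config.n_cobound
    n_a_only = config.n_peaks_a_induced - n_cobound
    n_b_only = config.n_peaks_b_induced - n_cobound
    n_bg_pairs = n_cobound - len(roles["class1"])
    n_bg_a_only = n_a_only - config.n_switch_loci
    n_bg_b_only = n_b_only - len(roles["class2"])

    # background placement sites in gene-free slots, >= 2 kb apart
    slots = _gene_slots(config)
    rng_genes = _rng(config, 1)
    used = set(
        sorted(rng_genes.choice(len(slots), size=config.n_genes, replace=False).tolist())
        if config.n_genes
        else []
    )
    sites: list[tuple[str, int]] = []
    for idx, (chrom, slot_start) in enumerate(slots):
        if idx in used:
            continue
        pos = slot_start + 10_000
        while pos < slot_start + config.slot_length - 10_000:
            sites.append((chrom, pos))
            pos += 2_000
    needed = n_bg_pairs + n_bg_a_only + n_bg_b_only
    if needed > len(sites):
        raise ValueError(
            f"genome too small for background peaks: need {needed} sites, have {len(sites)}"
        )
    site_order = rng.permutation(len(sites))
    site_iter = iter(site_order.tolist())

    def next_site() -> tuple[str, int]:
        chrom, pos = sites[next(site_iter)]
        return chrom, pos

    def cobound_pair_summits(anchor: int) -> tuple[int, int]:
        d = int(rng.integers(0, maxd + 1))
        if config.summit_jitter_sd > 0:
            d += int(round(rng.normal(0, config.summit_jitter_sd)))
        sign = -1 if rng.random() < 0.5 else 1
        return anchor, anchor + sign * abs(d)

    a_induced: list[Peak] = []
    b_induced: list[Peak] = []

    def add_pair(chrom: str, anchor: int, tag: str) -> None:
        b_summit, a_summit = cobound_pair_summits(anchor)
        na = f"{FACTOR_A}_{INDUCED}_{len(a_induced) + 1:04d}"
        nb = f"{FACTOR_B}_{INDUCED}_{len(b_induced) + 1:04d}"
        a_induced.append(_make_peak(rng, chrom, a_summit, FACTOR_A, INDUCED, na))
        b_induced.append(_make_peak(rng, chrom, b_summit, FACTOR_B, INDUCED, nb))
        manifest.peaks[na] = {
            "factor": FACTOR_A, "condition": INDUCED, "chrom": chrom,
            "summit": a_summit, "planted_group": "group1", "context": tag,
        }
        manifest.peaks[nb] = {
            "factor": FACTOR_B, "condition": INDUCED, "chrom": chrom,
            "summit": b_summit, "planted_group": "partner", "context": tag,
        }

    def add_single(chrom: str, summit: int, factor: str, group: str, tag: str) -> Peak:
        lst = a_induced if factor == FACTOR_A else b_induced
        name = f"{factor}_{INDUCED}_{len(lst) + 1:04d}"
        pk = _make_peak(rng, chrom, summit, factor, INDUCED, name)
        lst.append(pk)
        manifest.peaks[name] = {
            "factor": factor, "condition": INDUCED, "chrom": chrom,
            "summit": summit, "planted_group": group, "context": tag,
        }
        return pk

    # class-1 genes: co-bound pair in the gene's upstream window
    for gi in roles["class1"]:
        gene = genes[gi]
        add_pair(gene.chrom, _upstream_anchor(rng, gene, pad), f"class1:{gene.gene_id}")
    # class-2 genes: factor-B-only peak in the window
    for gi in roles["class2"]:
        gene = genes[gi]
        add_single(
            gene.chrom, _upstream_anchor(rng, gene, pad), FACTOR_B, "group3",
            f"class2:{gene.gene_id}",
        )
    # switch loci: factor-A induced peak in the 3' UTR (factor-B basal added below)
    switch_peaks: list[tuple[GeneModel, Peak]] = []
    for gi in roles["switch"]:
        gene = genes[gi]
        utr = gene.utr3
        mid = (utr.start + utr.end) // 2
        pk = add_single(gene.chrom, mid, FACTOR_A, "group2", f"switch:{gene.gene_id}")
        switch_peaks.append((gene, pk))
    # background
    for _ in range(n_bg_pairs):
        chrom, pos = next_site()
        add_pair(chrom, pos, "background")
    for _ in range(n_bg_a_only):
        chrom, pos = next_site()
        add_single(chrom, pos, FACTOR_A, "group2", "background")
    for _ in range(n_bg_b_only):
        chrom, pos = next_site()
        add_single(chrom, pos, FACTOR_B, "group3", "background")

    # basal sets: persistent subsets of the induced sets
    switch_names = {pk.name for _g, pk in switch_peaks}
    a_pool = [p for p in a_induced if p.name not in switch_names]
    a_basal_pick = rng.choice(len(a_pool), size=config.n_a_basal, replace=False)
    a_basal = [
        dataclasses.replace(a_pool[i], condition=BASAL, name=f"{FACTOR_A}_{BASAL}_{k + 1:04d}")
        for k, i in enumerate(sorted(a_basal_pick.tolist()))
    ]
    n_b_persistent = config.n_b_basal - len(switch_peaks)
    if n_b_persistent < 0:
        raise ValueError("basal factor-B peak budget smaller than n_switch_loci")
    b_basal_pick = rng.choice(len(b_induced), size=n_b_persistent, replace=False)
    b_basal = [
        dataclasses.replace(b_induced[i], condition=BASAL, name=f"{FACTOR_B}_{BASAL}_{k + 1:04d}")
        for k, i in enumerate(sorted(b_basal_pick.tolist()))
    ]
    # basal factor-B peaks at the switch loci (lost upon stimulation)
    for gene, a_pk in switch_peaks:
        shift = int(rng.integers(-30, 31))
        name = f"{FACTOR_B}_{BASAL}_{len(b_basal) + 1:04d}"
        pk = _make_peak(rng, gene.chrom, a_pk.summit + shift, FACTOR_B, BASAL, name)
        b_basal.append(pk)
        manifest.peaks[name] = {
            "factor": FACTOR_B, "condition": BASAL, "chrom": gene.chrom,
            "summit": pk.summit, "planted_group": "switch_basal",
            "context": f"switch:{gene.gene_id}",
        }
        manifest.switch_loci.append(
            {
                "gene": gene.gene_id,
                "chrom": gene.chrom,
                "start": pk.interval.start,
                "end": pk.interval.end,
                "utr3": True,
            }
        )

    peaks = {
        FACTOR_A: {INDUCED: a_induced, BASAL: a_basal},
        FACTOR_B: {INDUCED: b_induced, BASAL: b_basal},
    }
    return peaks, manifest


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    manifest: Optional[TruthManifest] = None,
) -> tuple[CountMatrix, TruthManifest]:
    """Negative-binomial counts for control/knockout x untreated/stimulated.

    Responsive genes carry a planted linear fold change under stimulation in
    the control genotype; dependent genes have that response nulled in the
    knockout (or reversed, for the planted reversal fraction); switch genes
    stay flat everywhere.
    """
    if manifest is None:
        manifest = TruthManifest(config=dataclasses.asdict(config))
    rng = _rng(config, 4)
    cc = config.counts
    roles = _assign_gene_roles(config, genes)
    n_genes = len(genes)

    lo, hi = cc.base_mean_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_genes))
    fc = np.ones(n_genes)
    up = rng.random(n_genes) < 0.5
    draw = rng.uniform(cc.true_fc_range[0], cc.true_fc_range[1], size=n_genes)

    resp_set = set(roles["responsive"])
    dep_set = set(roles["dependent"])
    rev_set = roles["reversed"]
    switch_set = set(roles["switch"])

    # per-gene multipliers for (genotype, treatment)
    mult = {
        ("control", "untreated"): np.ones(n_genes),
        ("control", "tnf"): np.ones(n_genes),
        ("soxc_ko", "untreated"): np.ones(n_genes),
        ("soxc_ko", "tnf"): np.ones(n_genes),
    }
    for gi in range(n_genes):
        info: dict = {"planted_response": "none", "planted_dependence": None,
                      "planted_class": None, "true_fc": None,
                      "is_switch": gi in switch_set}
        if gi in switch_set:
            info["planted_class"] = "class4"
        elif gi in resp_set:
            f = float(draw[gi])
            eff = f if up[gi] else 1.0 / f
            mult[("control", "tnf")][gi] = eff
            info["planted_response"] = "up" if up[gi] else "down"
            info["true_fc"] = f
            if gi in dep_set:
                if gi in rev_set:
                    mult[("soxc_ko", "tnf")][gi] = 1.0 / eff
                    info["planted_dependence"] = "dependent_reversed"
                else:
                    info["planted_dependence"] = "dependent_unchanged"
                if gi in set(roles["class1"]):
                    info["planted_class"] = "class1"
                elif gi in set(roles["class2"]):
                    info["planted_class"] = "class2"
                else:
                    info["planted_class"] = "class3"
            else:
                mult[("soxc_ko", "tnf")][gi] = eff
                info["planted_dependence"] = "independent"
        manifest.genes[genes[gi].gene_id] = info

    scale = cc.depth_per_sample / base.sum() if n_genes else 0.0
    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for genotype in ("control", "soxc_ko"):
        for treatment in ("untreated", "tnf"):
            for rep in range(1, cc.n_replicates + 1):
                depth_factor = rng.uniform(0.9, 1.1)
                mu = base * mult[(genotype, treatment)] * scale * depth_factor
                if cc.poisson or cc.nb_dispersion <= 0:
                    col = rng.poisson(mu)
                else:
                    r = 1.0 / cc.nb_dispersion
                    p = r / (r + mu)
                    col = rng.negative_binomial(r, p)
                cols.append(col.astype(np.int64))
                sid = f"{'ctrl' if genotype == 'control' else 'ko'}_{'unt' if treatment == 'untreated' else 'tnf'}_{rep}"
                samples.append(
                    SampleMeta(sample_id=sid, genotype=genotype, treatment=treatment, replicate=rep)
                )
    cm = CountMatrix(
        gene_ids=[g.gene_id for g in genes],
        samples=samples,
        counts=np.column_stack(cols),
    )
    manifest.samples = [dataclasses.asdict(s) for s in samples]
    return cm, manifest


# ---------------------------------------------------------------------------
# sequences and reads


def _sample_iupac_instance(consensus: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[int(rng.integers(len(IUPAC[c])))] for c in consensus)


def simulate_peak_sequences(
    config: SyntheticConfig,
    peaks: dict[str, dict[str, list[Peak]]],
    manifest: TruthManifest,
) -> tuple[dict[str, str], TruthManifest]:
    """Random sequence per stimulated factor-A peak; a planting_rate share of
    co-bound (group 1) peaks gets one planted consensus instance at a
    recorded offset and strand."""
    from .motifs import reverse_complement

    rng = _rng(config, 5)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    motif_len = len(config.motif.consensus)
    for pk in peaks[FACTOR_A][INDUCED]:
        L = len(pk.interval)
        seq = "".join(bases[rng.integers(0, 4, size=L)])
        planted_group = manifest.peaks.get(pk.name, {}).get("planted_group")
        if (
            planted_group == "group1"
            and L > motif_len
            and rng.random() < config.motif.planting_rate
        ):
            inst = _sample_iupac_instance(config.motif.consensus, rng)
            offset = int(rng.integers(0, L - motif_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = inst if strand == "+" else reverse_complement(inst)
            seq = seq[:offset] + planted + seq[offset + motif_len :]
            manifest.motif_plantings[pk.name] = {
                "offset": offset,
                "strand": strand,
                "instance": inst,
            }
        seqs[pk.name] = seq
    return seqs, manifest


def simulate_reads(
    peaks: Sequence[Peak],
    seed: int = 0,
    reads_per_peak: int = 20,
    spread: float = 100.0,
    read_length: int = 50,
) -> list[GenomicInterval]:
    """Read intervals scattered around peak summits with Gaussian spread
    (for coverage-profile tests)."""
    rng = np.random.default_rng(seed)
    reads: list[GenomicInterval] = []
    for pk in peaks:
        centers = rng.normal(pk.summit, spread, size=reads_per_peak)
        for c in centers:
            start = max(0, int(round(c)) - read_length // 2)
            reads.append(GenomicInterval(pk.chrom, start, start + read_length))
    return reads


# ---------------------------------------------------------------------------
# top level


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    genes = simulate_gene_models(config)
    manifest = TruthManifest(config=dataclasses.asdict(config))
    peaks, manifest = simulate_peak_sets(config, genes, manifest)
    counts, manifest = simulate_counts(config, genes, manifest)
    seqs, manifest = simulate_peak_sequences(config, peaks, manifest)
    return SyntheticDataset(
        config=config, genes=genes, peaks=peaks, counts=counts, sequences=seqs, manifest=manifest
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as narrowPeak/BED12/TSV/FASTA/JSON under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for factor, by_cond in ds.peaks.items():
        for cond, plist in by_cond.items():
            p = out / f"{factor.lower()}_{cond}.narrowPeak"
            write_peaks(plist, p)
            paths[f"peaks_{factor.lower()}_{cond}"] = p
    paths["genes"] = out / "genes.bed12"
    write_gene_models(ds.genes, paths["genes"])
    paths["counts"] = out / "counts.tsv"
    paths["samples"] = out / "samples.tsv"
    write_count_matrix(ds.counts, paths["counts"], paths["samples"])
    paths["sequences"] = out / "peaks.fa"
    write_fasta(ds.sequences, paths["sequences"])
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(ds.manifest.to_json())
    return paths
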