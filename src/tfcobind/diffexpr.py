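"""Differential expression by the Audic-Claverie test.

The Audic-Claverie statistic compares one tag count between two sequencing
libraries. Given x reads for a gene in a library of size n1, the posterior
predictive distribution of the count y in a second library of size n2 is

    P(y | x) = (n2/n1)^y * (x+y)! / (x! * y! * (1 + n2/n1)^(x+y+1)),

which is exactly a negative binomial with r = x + 1 successes and success
probability n1/(n1+n2). Tail probabilities are therefore computed through the
regularized incomplete beta function (scipy's nbinom), which is exact at any
count magnitude — no truncated summation or normal approximation is needed.

Replicates are pooled by summation before testing (the test is defined for
two libraries); library sizes are the summed median-of-ratios size factors.
The two-sided p-value is min(1, 2 * min(P(Y<=y|x), P(Y>=y|x))).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import CountMatrix

__all__ = [
    "DEParams",
    "DERecord",
    "ResponseLabel",
    "size_factors",
    "audic_claverie_p",
    "audic_claverie_pvalues",
    "bh_adjust",
    "contrast",
    "classify_response",
    "dependence_summary",
]

DIRECTIONS = ("up", "down", "unchanged")
DEPENDENCE = ("dependent_unchanged", "dependent_reversed", "independent", "not_applicable")


@dataclass(frozen=True)
class DEParams:
    """fc_threshold is a linear fold change (1.5 means 1.5x either way);
    alpha is the BH FDR cutoff. fc_only drops the FDR requirement so that a
    gene is called on the fold threshold alone."""

    fc_threshold: float = 1.5
    alpha: float = 0.05
    fc_only: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    count_a: int
    count_b: int
    n_a: float
    n_b: float
    fold_change: float  # linear, normalized b/a
    p: float
    q: float
    direction: str
    pseudocounted: bool = False


@dataclass(frozen=True)
class ResponseLabel:
    gene_id: str
    tnf_response: str  # up / down / none
    soxc_dependence: str  # dependent_unchanged / dependent_reversed / independent / not_applicable


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    count_ij / geometric_mean_i.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat.astype(float))
    log_geomean = log_mat.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "filter genes or use a pseudo-reference"
        )
    ratios = np.exp(log_mat[usable] - log_geomean[usable, None])
    return np.median(ratios, axis=0)


def audic_claverie_p(x: int, y: int, n1: float, n2: float, sided: str = "two") -> float:
    """Audic-Claverie p-value for observing count y (library n2) given count x
    (library n1). `sided` is 'two', 'greater' (P(Y>=y|x)) or 'less' (P(Y<=y|x))."""
    return float(audic_claverie_pvalues(np.array([x]), np.array([y]), n1, n2, sided)[0])


def audic_claverie_pvalues(
    x: np.ndarray, y: np.ndarray, n1: float, n2: float, sided: str = "two"
) -> np.ndarray:
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"unknown sided {sided!r}")
    p_success = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p_success)  # P(Y <= y | x)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)  # P(Y >= y | x)
    if sided == "less":
        out = lower
    elif sided == "greater":
        out = upper
    else:
        out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    # tails this extreme underflow double precision; the true p is positive
    return np.clip(out, np.finfo(float).tiny, 1.0)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def contrast(
    counts: CountMatrix,
    group_a: dict,
    group_b: dict,
    params: DEParams | None = None,
) -> list[DERecord]:
    """Audic-Claverie contrast of group_b against group_a.

    Groups are metadata filters, e.g. ``{"genotype": "control", "treatment":
    "untreated"}``. Replicate counts are summed per group; library sizes are
    the summed per-sample size factors (computed over the selected samples).
    The fold change is the normalized pooled mean of b over a; a +1
    pseudocount enters the ratio only when either pooled count is zero
    (flagged in the record).
    """
    params = params or DEParams()
    idx_a = counts.select(**group_a)
    idx_b = counts.select(**group_b)
    if not idx_a or not idx_b:
        raise ValueError("both groups must be non-empty")
    if set(idx_a) & set(idx_b):
        raise ValueError("groups must be disjoint")
    sub = counts.counts[:, idx_a + idx_b].astype(np.int64)
    sf = size_factors(sub)
    sf_a, sf_b = sf[: len(idx_a)], sf[len(idx_a) :]
    pooled_a = counts.counts[:, idx_a].sum(axis=1)
    pooled_b = counts.counts[:, idx_b].sum(axis=1)
    n_a = float(sf_a.sum())
    n_b = float(sf_b.sum())

    pvals = audic_claverie_pvalues(pooled_a, pooled_b, n_a, n_b, sided="two")
    qvals = np.asarray(bh_adjust(pvals.tolist()))

    records: list[DERecord] = []
    for i, gid in enumerate(counts.gene_ids):
        ca, cb = int(pooled_a[i]), int(pooled_b[i])
        pseudo = ca == 0 or cb == 0
        norm_a = (ca + (1 if pseudo else 0)) / n_a
        norm_b = (cb + (1 if pseudo else 0)) / n_b
        fc = norm_b / norm_a
        significant = params.fc_only or (qvals[i] < params.alpha)
        if fc >= params.fc_threshold and significant:
            direction = "up"
        elif fc <= 1.0 / params.fc_threshold and significant:
            direction = "down"
        else:
            direction = "unchanged"
        records.append(
            DERecord(
                gene_id=gid,
                count_a=ca,
                count_b=cb,
                n_a=n_a,
                n_b=n_b,
                fold_change=float(fc),
                p=float(pvals[i]),
                q=float(qvals[i]),
                direction=direction,
                pseudocounted=pseudo,
            )
        )
    return records


def classify_response(
    de_control: Sequence[DERecord],
    de_ko: Sequence[DERecord],
    params: DEParams | None = None,
) -> list[ResponseLabel]:
    """Label each gene's stimulus response and its knockout dependence.

    The response (up/down/none) comes from the control contrast. For
    responsive genes: the gene is dependent_unchanged when the knockout shows
    no response, dependent_reversed when the knockout responds in the
    opposite direction, and independent when the knockout response matches.
    """
    ko_by_gene = {r.gene_id: r for r in de_ko}
    if set(ko_by_gene) != {r.gene_id for r in de_control}:
        raise ValueError("gene universes of the two contrasts differ")
    labels: list[ResponseLabel] = []
    for rc in de_control:
        rk = ko_by_gene[rc.gene_id]
        if rc.direction == "unchanged":
            labels.append(ResponseLabel(rc.gene_id, "none", "not_applicable"))
            continue
        if rk.direction == "unchanged":
            dep = "dependent_unchanged"
        elif rk.direction == rc.direction:
            dep = "independent"
        else:
            dep = "dependent_reversed"
        labels.append(ResponseLabel(rc.gene_id, rc.direction, dep))
    return labels


def dependence_summary(labels: Sequence[ResponseLabel]) -> dict:
    """Counts of responsive genes and the knockout-dependent fraction."""
    responsive = [l for l in labels if l.tnf_response != "none"]
    dep = [l for l in responsive if l.soxc_dependence in ("dependent_unchanged", "dependent_reversed")]
    n_resp = len(responsive)
    return {
        "n_genes": len(labels),
        "n_responsive": n_resp,
        "n_up": sum(1 for l in responsive if l.tnf_response == "up"),
        "n_down": sum(1 for l in responsive if l.tnf_response == "down"),
        "n_dependent": len(dep),
        "n_dependent_unchanged": sum(
            1 for l in dep if l.soxc_dependence == "dependent_unchanged"
        ),
        "n_dependent_reversed": sum(
            1 for l in dep if l.soxc_dependence == "dependent_reversed"
        ),
        "n_independent": n_resp - len(dep),
        "dependent_fraction": (len(dep) / n_resp) if n_resp else 0.0,
    }
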