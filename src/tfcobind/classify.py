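"""Regulatory-mode classification: joining binding, switch and expression evidence.

Stimulus-responsive, knockout-dependent genes are assigned one of four
regulatory modes:

* class1_cobound_direct — a co-bound (Group 1) peak is assigned to the gene:
  a direct target requiring both factors.
* class2_rela_only — only factor-B-only (Group 3) peaks are assigned: a
  direct target of the second factor alone.
* class3_indirect — no peak of either factor is assigned: an indirect target.
* class4_switch — a regulatory-switch locus is assigned to the gene. Switch
  genes are exempt from the dependence filter (binding turnover can maintain,
  rather than change, expression), and the switch call takes precedence.

Genes with a dependent response that fit none of the rules (e.g. only
factor-A-only peaks) are retained as `unclassified` with their evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cobinding import GROUP1, GROUP2, GROUP3, CobindAssignment, CobindSummary, SwitchCall
from .diffexpr import ResponseLabel, dependence_summary
from .genomic_io import CountMatrix, Peak

__all__ = ["RegClassCall", "IntegrationReport", "assign_reg_class", "assign_reg_classes", "build_report"]

CLASSES = (
    "class1_cobound_direct",
    "class2_rela_only",
    "class3_indirect",
    "class4_switch",
    "unclassified",
)

_DEPENDENT = ("dependent_unchanged", "dependent_reversed")


@dataclass
class RegClassCall:
    gene_id: str
    reg_class: str
    evidence: dict


@dataclass
class IntegrationReport:
    venn_counts: dict
    fraction_a_cobound: float
    n_tnf_responsive: int
    n_soxc_dependent: int
    dependent_fraction: float
    class_counts: dict
    class_genes: dict
    expression_by_class: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "IntegrationReport":
        return cls(**json.loads(text))


def _gene_evidence(
    gene_id: str,
    gene_peaks: Mapping[str, Sequence[Peak]],
    group_of: Mapping[Peak, str],
    switch_genes: Mapping[str, list[SwitchCall]],
) -> dict:
    peaks = gene_peaks.get(gene_id, [])
    cobound = [p for p in peaks if group_of.get(p) == GROUP1]
    a_only = [p for p in peaks if group_of.get(p) == GROUP2]
    b_only = [p for p in peaks if group_of.get(p) == GROUP3]
    return {
        "cobound_peaks": cobound,
        "sox4_only_peaks": a_only,
        "rela_only_peaks": b_only,
        "switch_calls": switch_genes.get(gene_id, []),
    }


def assign_reg_class(
    gene_id: str,
    gene_peaks: Mapping[str, Sequence[Peak]],
    cobind_assignments: Sequence[CobindAssignment],
    switch_calls: Sequence[SwitchCall],
    response: ResponseLabel,
) -> RegClassCall:
    """Classify one gene; see :func:`assign_reg_classes` for the batch form."""
    group_of = {a.peak: a.group for a in cobind_assignments}
    switch_genes: dict[str, list[SwitchCall]] = {}
    for call in switch_calls:
        if call.gene is not None:
            switch_genes.setdefault(call.gene, []).append(call)
    return _assign_one(gene_id, gene_peaks, group_of, switch_genes, response)


def _assign_one(
    gene_id: str,
    gene_peaks: Mapping[str, Sequence[Peak]],
    group_of: Mapping[Peak, str],
    switch_genes: Mapping[str, list[SwitchCall]],
    response: ResponseLabel,
) -> RegClassCall:
    ev = _gene_evidence(gene_id, gene_peaks, group_of, switch_genes)
    ev["response"] = response
    dependent = response.soxc_dependence in _DEPENDENT
    if ev["switch_calls"]:
        cls = "class4_switch"
    elif dependent and ev["cobound_peaks"]:
        cls = "class1_cobound_direct"
    elif dependent and ev["rela_only_peaks"] and not ev["cobound_peaks"]:
        cls = "class2_rela_only"
    elif dependent and not (ev["cobound_peaks"] or ev["rela_only_peaks"] or ev["sox4_only_peaks"]):
        cls = "class3_indirect"
    else:
        cls = "unclassified"
    return RegClassCall(gene_id=gene_id, reg_class=cls, evidence=ev)


def assign_reg_classes(
    responses: Sequence[ResponseLabel],
    gene_peaks: Mapping[str, Sequence[Peak]],
    cobind_assignments: Sequence[CobindAssignment],
    switch_calls: Sequence[SwitchCall],
) -> list[RegClassCall]:
    """Classify every gene in the response universe.

    gene_peaks maps gene_id -> assigned peaks (both factors, induced
    condition); cobind_assignments supply each peak's Group 1/2/3 label;
    switch_calls must already be gene-annotated.
    """
    group_of = {a.peak: a.group for a in cobind_assignments}
    switch_genes: dict[str, list[SwitchCall]] = {}
    for call in switch_calls:
        if call.gene is not None:
            switch_genes.setdefault(call.gene, []).append(call)
    response_by_gene = {r.gene_id: r for r in responses}
    missing = [g for g in switch_genes if g not in response_by_gene]
    if missing:
        raise ValueError(f"switch genes absent from response labels: {sorted(missing)[:5]}")
    return [
        _assign_one(r.gene_id, gene_peaks, group_of, switch_genes, r) for r in responses
    ]


def build_report(
    calls: Sequence[RegClassCall],
    responses: Sequence[ResponseLabel],
    cobind_summary: CobindSummary,
    counts: Optional[CountMatrix] = None,
) -> IntegrationReport:
    """Aggregate per-gene class calls into the run-level report.

    When a count matrix is supplied, the report includes the mean
    size-factor-normalized expression per class for each genotype x treatment
    group (the group-mean expression matrix).
    """
    call_genes = {c.gene_id for c in calls}
    resp_genes = {r.gene_id for r in responses}
    if call_genes != resp_genes:
        offenders = sorted(call_genes ^ resp_genes)
        raise ValueError(f"inconsistent gene universes, offenders: {offenders[:10]}")
    dep = dependence_summary(responses)
    class_genes: dict[str, list[str]] = {c: [] for c in CLASSES}
    for call in calls:
        class_genes[call.reg_class].append(call.gene_id)
    for genes in class_genes.values():
        genes.sort()
    # unclassified genes with no dependent response and no evidence at all are
    # not interesting to list; keep only dependent-or-evidenced ones
    interesting_unclassified = [
        c.gene_id
        for c in calls
        if c.reg_class == "unclassified"
        and (
            c.evidence["response"].soxc_dependence in _DEPENDENT
            or c.evidence["cobound_peaks"]
            or c.evidence["rela_only_peaks"]
            or c.evidence["sox4_only_peaks"]
        )
    ]
    class_genes["unclassified"] = sorted(interesting_unclassified)
    class_counts = {c: len(class_genes[c]) for c in CLASSES}

    expression_by_class: dict = {}
    if counts is not None:
        from .diffexpr import size_factors

        sf = size_factors(counts)
        norm = counts.counts / sf
        gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
        groups = sorted({(s.genotype, s.treatment) for s in counts.samples})
        for cls in CLASSES:
            rows = [gene_index[g] for g in class_genes[cls] if g in gene_index]
            if not rows:
                continue
            entry = {}
            for genotype, treatment in groups:
                cols = counts.select(genotype=genotype, treatment=treatment)
                entry[f"{genotype}:{treatment}"] = float(norm[np.ix_(rows, cols)].mean())
            expression_by_class[cls] = entry

    return IntegrationReport(
        venn_counts={
            "group1": cobind_summary.n_group1,
            "group2": cobind_summary.n_group2,
            "group3": cobind_summary.n_group3,
        },
        fraction_a_cobound=cobind_summary.fraction_a_cobound,
        n_tnf_responsive=dep["n_responsive"],
        n_soxc_dependent=dep["n_dependent"],
        dependent_fraction=dep["dependent_fraction"],
        class_counts=class_counts,
        class_genes=class_genes,
        expression_by_class=expression_by_class,
    )
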