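"""End-to-end run: annotate -> co-bind -> switch -> DE -> classify -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation, classify, cobinding, diffexpr, genomic_io
from .annotation import AnnotationParams
from .cobinding import CobindParams
from .diffexpr import DEParams

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for a full integration run.

    Factor A is the factor whose summits are tested for proximity to factor B
    (the co-bound fraction is reported from A's perspective); the switch
    detector looks for basal factor-B binding replaced by induced factor-A
    binding (the stimulation-induced turnover direction).
    """

    peaks_a_induced: str
    peaks_b_induced: str
    peaks_a_basal: str
    peaks_b_basal: str
    genes: str
    counts: str
    samples: str
    out_dir: str
    factor_a: str = "SOX4"
    factor_b: str = "RELA"
    basal_condition: str = "untreated"
    induced_condition: str = "tnf"
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    cobind: CobindParams = field(default_factory=CobindParams)
    de: DEParams = field(default_factory=DEParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key, klass in (
            ("annotation", AnnotationParams),
            ("cobind", CobindParams),
            ("de", DEParams),
        ):
            if key in data and isinstance(data[key], dict):
                if key == "annotation" and "feature_priority" in data[key]:
                    data[key]["feature_priority"] = tuple(data[key]["feature_priority"])
                data[key] = klass(**data[key])
        return cls(**data)

    def input_paths(self) -> list[str]:
        return [
            self.peaks_a_induced,
            self.peaks_b_induced,
            self.peaks_a_basal,
            self.peaks_b_basal,
            self.genes,
            self.counts,
            self.samples,
        ]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %s finished in %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig) -> classify.IntegrationReport:
    """Execute every stage and write groups/switches/classes/report artifacts."""
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    a_ind = genomic_io.read_peaks(
        config.peaks_a_induced, factor=config.factor_a, condition=config.induced_condition
    )
    b_ind = genomic_io.read_peaks(
        config.peaks_b_induced, factor=config.factor_b, condition=config.induced_condition
    )
    a_bas = genomic_io.read_peaks(
        config.peaks_a_basal, factor=config.factor_a, condition=config.basal_condition
    )
    b_bas = genomic_io.read_peaks(
        config.peaks_b_basal, factor=config.factor_b, condition=config.basal_condition
    )
    genes = genomic_io.read_gene_models(config.genes)
    counts = genomic_io.read_count_matrix(config.counts, config.samples)
    t0 = _stage("load", t0)

    annotations = annotation.classify_peaks(a_ind + b_ind, genes, config.annotation)
    pd.DataFrame(
        {
            "peak": [a.peak.name for a in annotations],
            "factor": [a.peak.factor for a in annotations],
            "category": [a.category for a in annotations],
            "genes": [",".join(a.genes) for a in annotations],
            "tss_distance": [a.tss_distance for a in annotations],
        }
    ).to_csv(out / "annot.tsv", sep="\t", index=False)
    gene_peaks = annotation.assign_peaks_to_genes(a_ind + b_ind, genes, config.annotation)
    t0 = _stage("annotate", t0)

    assignments, summary = cobinding.group_summits(a_ind, b_ind, config.cobind)
    pd.DataFrame(
        {
            "peak": [a.peak.name for a in assignments],
            "factor": [a.peak.factor for a in assignments],
            "group": [a.group for a in assignments],
            "partner": [a.partner.name if a.partner else "" for a in assignments],
            "distance": [a.distance if a.distance is not None else "" for a in assignments],
        }
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    t0 = _stage("cobind", t0)

    # switch direction: basal factor-B binding replaced by induced factor-A binding
    switches = cobinding.detect_switch(
        {config.basal_condition: b_bas, config.induced_condition: b_ind},
        {config.basal_condition: a_bas, config.induced_condition: a_ind},
        basal=config.basal_condition,
        induced=config.induced_condition,
    )
    switches = cobinding.annotate_switches(switches, genes, config.annotation)
    pd.DataFrame(
        {
            "chrom": [s.locus.chrom for s in switches],
            "start": [s.locus.start for s in switches],
            "end": [s.locus.end for s in switches],
            "gene": [s.gene or "" for s in switches],
            "utr3": [s.utr3_overlap for s in switches],
            "basal_peak": [s.basal_peak_factor_a.name for s in switches],
            "gained_peak": [s.gained_peak_factor_b.name for s in switches],
        }
    ).to_csv(out / "switches.tsv", sep="\t", index=False)
    t0 = _stage("switch", t0)

    de_control = diffexpr.contrast(
        counts,
        {"genotype": "control", "treatment": "untreated"},
        {"genotype": "control", "treatment": "tnf"},
        config.de,
    )
    de_ko = diffexpr.contrast(
        counts,
        {"genotype": "soxc_ko", "treatment": "untreated"},
        {"genotype": "soxc_ko", "treatment": "tnf"},
        config.de,
    )
    for name, recs in (("de_control.tsv", de_control), ("de_ko.tsv", de_ko)):
        pd.DataFrame([dataclasses.asdict(r) for r in recs]).to_csv(
            out / name, sep="\t", index=False
        )
    responses = diffexpr.classify_response(de_control, de_ko, config.de)
    pd.DataFrame([dataclasses.asdict(r) for r in responses]).to_csv(
        out / "response.tsv", sep="\t", index=False
    )
    t0 = _stage("de", t0)

    calls = classify.assign_reg_classes(responses, gene_peaks, assignments, switches)
    pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "reg_class": [c.reg_class for c in calls],
            "n_cobound_peaks": [len(c.evidence["cobound_peaks"]) for c in calls],
            "n_rela_only_peaks": [len(c.evidence["rela_only_peaks"]) for c in calls],
            "n_sox4_only_peaks": [len(c.evidence["sox4_only_peaks"]) for c in calls],
            "n_switch_calls": [len(c.evidence["switch_calls"]) for c in calls],
            "tnf_response": [c.evidence["response"].tnf_response for c in calls],
            "soxc_dependence": [c.evidence["response"].soxc_dependence for c in calls],
        }
    ).to_csv(out / "classes.tsv", sep="\t", index=False)
    report = classify.build_report(calls, responses, summary, counts)
    (out / "report.json").write_text(report.to_json())
    pd.DataFrame([report.venn_counts]).to_csv(out / "venn.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "params": {
            "annotation": dataclasses.asdict(config.annotation),
            "cobind": dataclasses.asdict(config.cobind),
            "de": dataclasses.asdict(config.de),
        },
        "inputs": config.input_paths(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list))
    _stage("classify", t0)
    return report
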