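# tfcobind

Integration analysis of two-factor ChIP-seq with knockout RNA-seq, built for
the question: *when an inflammatory stimulus activates both a signalling
transcription factor (NF-κB/RELA) and a co-operating factor (SOX4/SOXC), which
responsive genes do the two factors control directly, together, or not at
all?* The package was written around the mouse fibroblast-like synoviocyte
(FLS) setting — SOX4 and RELA downstream of TNF — but every rule is
parameterized and works on any factor pair with peak calls, gene models and a
genotype × treatment count matrix.

It is a library plus a CLI covering:

* **Summit-proximity co-binding.** A peak of factor A is *co-bound* (Group 1)
  when its summit lies within `d` bp (default 50, inclusive) of a factor-B
  summit on the same chromosome; remaining A peaks are Group 2 (A only) and
  unpartnered B peaks Group 3 (B only). Matching is nearest-summit,
  many-to-one, with a deterministic tie-break.
* **Peak annotation.** Summit-based classification into
  upstream / 5′ UTR / CDS / intron / 3′ UTR / downstream / intergenic, and
  peak→gene assignment to every gene whose body or upstream window (default
  50 kb) contains the summit.
* **Regulatory-switch detection.** A switch locus is a basal factor-A peak
  with (i) no induced factor-A overlap, (ii) no basal factor-B overlap, and
  (iii) an induced factor-B peak overlapping the same interval — the
  binding-turnover pattern seen at autoregulated loci (e.g. stimulus-induced
  replacement of RELA by SOX4 in a 3′ UTR).
* **Differential expression.** Median-of-ratios size factors, the
  Audic–Claverie exact test on replicate-pooled counts, Benjamini–Hochberg
  FDR, a linear fold-change threshold (default 1.5× with q < 0.05), and
  response/dependence labels: a stimulus-responsive gene is
  *knockout-dependent* when the response disappears (or reverses) in the
  knockout.
* **Regulatory classes.** Dependent responsive genes are assigned
  Class 1 (co-bound direct target), Class 2 (factor-B-only direct target),
  Class 3 (indirect: no peak of either factor) or Class 4 (regulatory
  switch; exempt from the dependence filter because binding turnover can
  maintain rather than change expression).
* **Coverage profiles and motifs.** TSS/anchor-centred reads-per-million
  matrices, Tukey box-plot summaries, IUPAC consensus and log-odds PWM
  scanning, site-mutation rescans and dinucleotide-shuffle enrichment.
* **A synthetic-data generator** that plants all of the above — co-bound
  fraction, condition fold, switch loci, negative-binomial counts with
  dependence structure, motif instances — and records the truth in a
  manifest, so every stage is testable by recovery.

## The count test

For a gene with `x` reads in a library of effective size `n1` and `y` reads
in a library of size `n2`, the Audic–Claverie posterior predictive
distribution of `y` given `x` is

    P(y | x) = (n2/n1)^y (x+y)! / ( x! y! (1 + n2/n1)^(x+y+1) )

which is a negative binomial with `x+1` successes and success probability
`n1/(n1+n2)`. Tail probabilities are computed exactly through the regularized
incomplete beta function at any count magnitude; the two-sided p-value is
`min(1, 2·min(P(Y≤y|x), P(Y≥y|x)))`. Replicates are pooled by summation and
library sizes are summed per-sample size factors.

## Worked example

Generate the default synthetic study (585 stimulated peaks per factor, 300
genes, 3 replicates per genotype × treatment) and group the stimulated
summits:

```python
from tfcobind.simulate import SyntheticConfig, simulate_dataset
from tfcobind.cobinding import group_summits

ds = simulate_dataset(SyntheticConfig(seed=7))
_assignments, summary = group_summits(ds.peaks["SOX4"]["tnf"], ds.peaks["RELA"]["tnf"])
print(summary.as_dict())
```

prints

```
{'n_a': 585, 'n_b': 585, 'n_group1': 412, 'n_group2': 173, 'n_group3': 173,
 'fraction_a_cobound': 0.7042735042735043}
```

i.e. 412 of 585 SOX4 summits (70.4%) lie within 50 bp of a RELA summit —
exactly the co-bound fraction the generator planted. The same dataset run
through the full pipeline (`tfcobind run --config run.yaml`, or
`tfcobind.pipeline.run_pipeline`) writes `report.json` whose class counts

```
"class_counts": {"class1_cobound_direct": 20, "class2_rela_only": 30,
                 "class3_indirect": 100, "class4_switch": 2, "unclassified": 0}
```

recover the planted regulatory classes gene-for-gene, with a knockout-
dependent fraction of 0.60 among the 250 stimulus-responsive genes and both
planted 3′ UTR switch loci called.

The same stages are available as shell subcommands:

```bash
tfcobind simulate --seed 7 --out simdata/
tfcobind cobind --peaks-a simdata/sox4_tnf.narrowPeak \
                --peaks-b simdata/rela_tnf.narrowPeak --dist 50 --out groups.tsv
tfcobind de --counts simdata/counts.tsv --meta simdata/samples.tsv \
            --genotype control --out de_control.tsv
```

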