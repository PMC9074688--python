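# Methods

## Coordinate conventions

All genomic coordinates are 0-based, half-open (BED convention), enforced at
parse time; GTF input (1-based, inclusive) is converted on read. Peak summits
are absolute positions; a narrowPeak summit offset of −1, and every BED6
peak, falls back to the interval midpoint (floored for even lengths).
Chromosome names are compared as exact strings; `normalize_chrom` can
add/strip a `chr` prefix when two inputs disagree. A single convention
matters here because the co-binding rule is a ±50 bp window on summit
positions — an off-by-one in either direction moves peaks across the
boundary.

## Co-binding (summit grouping)

Factor-A peaks are Group 1 when at least one factor-B summit lies within
`max_summit_distance` bp (default 50, **inclusive**: distance 50 is co-bound,
51 is not) on the same chromosome; the nearest B summit is recorded as the
partner, ties broken toward the lower coordinate (configurable to
first-listed). Matching is many-to-one — two A summits may share a partner —
because the quantity of interest is the *fraction of A summits with a nearby
B summit*, not an exclusive pairing. Group 2 is the A remainder; Group 3 is
every B peak with no A summit within the threshold. The grouping is
implemented with per-chromosome sorted summit arrays (binary search); tests
verify equivalence with an O(n²) all-pairs scan on random instances. The
summary reports both the A-perspective fraction and raw pair counts, and
swapping the argument order yields the B-perspective count; the two
perspectives differ in general, so neither is silently preferred.

## Peak annotation and assignment

Classification is **summit-based**, not whole-interval, so the annotation and
the co-binding analysis share one anchor. Per overlapping gene, the summit is
categorized as 3′ UTR / CDS / 5′ UTR (exonic positions split by the CDS span;
genes lacking a CDS treat exonic positions as CDS), intron, or — outside the
body — upstream/downstream within the pad (default 50 kb), strand-aware.
When several genes give different categories, a fixed priority
(5′ UTR > CDS > 3′ UTR > intron > upstream > downstream > intergenic)
selects the reported one; exonic features are more specific, so they win.
`downstream` exists as a reported category (mergeable into intergenic via
config) but does **not** create gene assignments: a peak is assigned to every
gene whose body or upstream window contains the summit. Assignment is
deliberately many-to-many (divergent promoters share upstream peaks); a
nearest-gene-only mode is available. The signed TSS distance is negative
upstream of the TSS of the nearest assigned gene.

## Condition comparison and switch detection

Peak presence/absence across conditions uses interval overlap (≥ 1 bp by
default), not summit distance, because gain/loss is a track-level statement
about a region. `compare_conditions` reports gained/lost/persistent peaks and
the peak-count fold change `|b|/|a|` (undefined and reported as such when the
reference set is empty). A switch call requires, for a basal factor-A peak:
no induced factor-A overlap, no basal factor-B overlap, and an induced
factor-B overlap; the induced peak with the greatest overlap is recorded
together with the four evidence booleans. Detection is purely positional — no
signal-strength threshold by default (a `min_score` hook exists) — since the
phenomenon being modelled is qualitative binding turnover. Annotated calls
pick the assigned gene by the standard window rule, preferring a gene whose
3′ UTR overlaps the locus, then the nearest TSS, and carry a 3′ UTR overlap
flag.

## Differential expression

Size factors are DESeq-style median-of-ratios: per sample, the median over
genes (restricted to genes with a positive geometric mean across samples) of
count/geometric-mean. Only factor *ratios* are identified — rescaling one
sample rescales the geometric-mean reference by `c^(1/m)` — which is all the
downstream test needs. The implementation is cross-checked against pydeseq2's
normalization in the test suite.

The Audic–Claverie statistic is evaluated through the exact
negative-binomial identity `P(y|x) = NB(y; x+1, n1/(n1+n2))`, so tails come
from the regularized incomplete beta function and are exact at every count
magnitude; no truncated summation or large-count normal approximation is
needed, and the test suite checks the full x, y ≤ 50 grid against exact
rational (big-integer) enumeration at 1e-10 relative tolerance. Tail
probabilities that underflow double precision are floored at the smallest
positive normal float rather than returned as zero. The two-sided p doubles
the smaller of the two closed tails; note that this convention is *not*
exactly symmetric under swapping (x, n1) with (y, n2) — the discrete boundary
term differs — whereas the one-sided tails satisfy the exact complementarity
`P(Y≤y|x; n1,n2) + P(X≤x|y; n2,n1) = 1`, which is what the property test
asserts.

Replicates are pooled by summation before testing (the statistic is defined
for two libraries) with library sizes equal to the summed per-sample size
factors of each group. A gene is called responsive when the normalized pooled
fold change is ≥ 1.5× in either direction **and** BH q < 0.05; the
fold-threshold-only reading is available via `fc_only`. Fold changes are
linear; a +1 pseudocount enters the ratio only when a pooled count is zero,
and the record is flagged. Dependence labels compare the control and
knockout contrasts: responsive genes whose knockout direction is `unchanged`
are dependent (response lost), opposite-direction genes are
dependent-reversed, matching-direction genes independent.

The Audic–Claverie test assumes Poisson sampling; under biological
overdispersion it is anticonservative, which is observable in the generator's
negative-binomial mode. False-positive calibration is therefore checked in
the generator's Poisson mode, while power (recall of planted 3× responses at
dispersion 0.05) is checked under the negative binomial. The fold-change
threshold, not the q cutoff, is what keeps the false-positive rate near the
nominal level on overdispersed nulls.

## Regulatory classes

Only knockout-dependent responsive genes enter Classes 1–3:
Class 1 requires ≥ 1 assigned Group-1 (co-bound) peak; Class 2 requires ≥ 1
assigned Group-3 (factor-B-only) peak and no Group-1 peak; Class 3 requires
no assigned peak of either factor. Class 4 is any gene with an assigned
switch call; it takes precedence over Classes 1–3 and is exempt from the
dependence filter, because a binding switch can maintain constant expression
(flat mRNA at the autoregulated loci is the expected pattern, not an
exception). Dependent genes fitting none of the rules — e.g. only
factor-A-only peaks — are retained as `unclassified` with their evidence;
nothing is silently dropped. The report cross-checks counts against per-gene
lists, includes the Venn counts and dependent fraction, and (when counts are
supplied) a per-class mean normalized expression matrix over
genotype × treatment groups. Report JSON is deterministic (sorted keys and
gene lists), so identical inputs give byte-identical files.

## Coverage profiles

Reads are supplied as intervals (BED-style); each read adds 1 to every bin
its interval overlaps within ± window of an anchor, rows of minus-strand
anchors are flipped so bins run 5′→3′, and values are scaled to reads per
million. Defaults (± 2 kb, 50 bp bins) are configuration, not contract.
Box-plot summaries use type-7 (linear interpolation) quartiles and Tukey
1.5·IQR whiskers — one stated convention makes the tests exact. Group
comparisons of per-peak normalized counts use Welch t-tests with BH
adjustment.

## Motifs

Consensus scanning honours IUPAC degeneracy on both strands via regex with
overlapped matching; a sequence `N` matches only the consensus code `N`. PWMs
are probability matrices from aligned sites with per-base pseudocount α
(default 1): `p_b = (count_b + 4·α·bg_b)/(n_sites + 4·α)`; scores are log2
odds against the background and windows containing `N` are skipped. A
consensus converted to a degenerate PWM thresholded at its maximum score
reproduces the consensus hit set exactly (tested). The default SOX-like
(`WWCAAW`) and NF-κB-like (`GGRNNYYCC`) consensi are configuration defaults
only; all asserted tests use planted synthetic motifs. Site-mutation rescans
apply length-changing substitutions (validated against the stated original
bases), map pre-edit hit offsets through the cumulative shifts, and report
destroyed/created hits. Enrichment compares observed hit counts against
per-sequence dinucleotide-preserving shuffles (Altschul–Erickson Euler-path
shuffle, seed-controlled), with `empirical_p = (1 + #{null ≥ obs})/(n+1)`,
bounded below by `1/(n_shuffles+1)`.

## Synthetic data generator

The generator emulates the study design: two factors × two conditions of
peaks, two genotypes × two treatments × n replicates of counts. Design
choices, with defaults:

* **Genome and genes.** 2 chromosomes × 25 Mb, 300 genes. Each gene occupies
  an exclusive 130 kb slot (gene span ≤ 20 kb plus both 50 kb pads plus
  margins), so every peak-to-gene assignment is unambiguous and planted
  classes are recoverable exactly. Genes have 2–8 exons, random strand, an
  explicit CDS and 3′ UTR.
* **Peaks.** 585 stimulated peaks per factor; a planted co-bound fraction of
  0.704 (412/585) places a partner summit at distance U{0..50} (optional
  Gaussian jitter, default 0 — the jitter-free construction makes recovery
  exact); non-co-bound summits are ≥ ~1.9 kb from any partner. Basal peak
  counts are stimulated/3 (fold 3.0 exactly), realized as persistent subsets
  of the stimulated sets. Two switch loci are planted in the 3′ UTRs of
  designated genes as (A basal present, A induced absent, B basal absent,
  B induced present). Background peaks live only in gene-free slots.
* **Counts.** Base means log-uniform 150–3000, emulating a matrix already
  filtered for low expression (standard pre-DE filtering). 250 responsive
  genes with linear fold 3–5 (random direction) under stimulation in the
  control genotype; 60% of them dependent (knockout response nulled), of
  which 20% reversed instead; switch genes flat everywhere. Counts are
  negative binomial at dispersion 0.005 — the clean, strong-effect regime in
  which planted labels are recoverable essentially deterministically — with a
  Poisson mode for exact type-I calibration and per-sample depth jitter of
  ±10% around 2 M reads. The DE power analyses use dispersion 0.05 (typical
  biological replicates) via explicit configs.
* **Classes.** Of the 150 dependent genes, 20 receive a co-bound pair and 30
  a factor-B-only peak in their upstream windows (Classes 1 and 2); the
  remaining 100 get no peaks (Class 3); the 2 switch genes are Class 4.
* **Sequences.** Random sequence per stimulated factor-A peak; co-bound peaks
  receive one planted consensus instance at a recorded offset/strand.

All randomness flows through numpy `SeedSequence([seed, stream])` substreams,
so each component is independently reproducible and the whole dataset is a
pure function of the config. Every planted fact is written to the truth
manifest; recovery tests read expectations from the manifest only.

**What the generator does not emulate:** chromatin background and GC bias,
fragment-length effects, peak-calling noise, shared regulatory territories
(enhancers serving several distant genes), correlated gene expression, or
dispersion heterogeneity across genes. Passing recovery tests therefore
demonstrate correctness of the *rules* under their stated assumptions, not
performance on real, noisy data — on real data the co-binding fraction,
switch calls and class counts all inherit the error of the upstream peak
caller and the miscalibration of the count test under overdispersion.

## Problem sizes

Module and acceptance tests run the default 300-gene / 585-peak design and
2,000-gene count simulations; the whole suite completes in well under a
minute on one CPU, and `scripts/acceptance.py` in a few seconds. These sizes
were chosen as the smallest at which every planted structure is comfortably
identifiable; all are config fields and scale up linearly.

## Known limitations

* The Audic–Claverie test ignores biological variance; it is kept because it
  is the method under study, not because it is recommended practice for
  replicated designs (a dispersion-based GLM is out of scope by design).
* Class 2 ignores factor-A-only (Group 2) peaks entirely; a dependent gene
  whose only evidence is a Group-2 peak is `unclassified`. The alternative
  reading (excluding such genes from Class 2) is configurable at the caller
  level by filtering evidence.
* 3′ UTRs are stored as unspliced genomic spans; overlap tests are span-based.
* `cobind_fraction_recovery` and the generator place peaks so that recovery is
  exact by construction; they validate bookkeeping, not statistical power.
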