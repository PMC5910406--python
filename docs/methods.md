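# Methods

## Locus segmentation

Reads are consumed as a pre-mapped table (sequence, 1-based inclusive
interval, strand, redundant count xᵢ, genomic hit count mᵢ, library).
Filtering retains 15-30 nt reads with at most 1000 genomic hits, removes
reads with ≥10 identical bases in any 11-nt window, and removes any
sequence in a caller-supplied exclusion set (the stand-in for known
miRNA/tRNA/rRNA sequences).

**Scaling factors.** Each library's depth surrogate is the sum of the
lowest 75% of its unique-sequence abundances (the ⌈0.75 n⌉ least abundant
distinct sequences contribute their full counts). The sequence-rank
reading is used rather than a count-weighted quantile; it is robust to a
few extremely abundant sRNAs dominating a library.

**Candidate regions** are maximal covered intervals, pooling all
libraries, in which every internal uncovered gap is shorter than 100 nt
(a gap of exactly 100 splits).

**Heuristic segmentation** runs per replicate group within each region.
Per-base coverage is summed over a moving 50-nt window (the window size is
a package choice) and converted to an RPKM against the group's summed
scaling factors; above-threshold (≥1000) runs are merged across
sub-threshold gaps of at most 100 nt and trimmed to their covered extent.
Two thresholds apply jointly: the RPKM rule, whose absolute scale assumes
realistically deep libraries, and an absolute windowed-mass floor of 50
coverage-bases — a window must hold more read mass than two stray
single-copy reads. Without the floor, shallow groups let isolated
background reads seed candidates, which in pathological configurations
floods the candidate set and corrupts the background estimate downstream.
The candidate set is the de-duplicated union over groups.

**Posterior likelihood of expression.** Counts at each candidate, per
library, follow a two-component negative-binomial mixture with shared
dispersion (size 5): a background component with mean
width × background density (background density = out-of-candidate read
mass over out-of-candidate span, computed on the *merged union* of
candidates so nested candidates are not double-counted), and an expressed
component with mean max(width × expressed density, half the library's
typical per-locus abundance, 10 × background). The abundance floor is
count-weighted (Σwk²/Σwk) so a crowd of near-empty candidates cannot
dilute it; it is what lets the model reject isolated background reads,
whose density-based expressed mean would otherwise be too forgiving.
Because both components share the dispersion and the expressed mean
strictly exceeds the background mean, the per-locus log-likelihood ratio
is monotone in every count. Evidence multiplies over a group's libraries;
the mixing proportion (per group) and the expressed density/abundance
(per library, posterior-weighted) are re-estimated over three cycles.

**Selection.** Within each group, loci are ranked by descending
likelihood and the largest prefix whose mean (1 − likelihood) is ≤ 0.05
is retained; a retained locus must additionally be more likely expressed
than not (p > 0.5) in at least one group — without this, the prefix rule
spends its whole error budget on loci the model itself calls unexpressed
everywhere, and the union over many groups multiplies that budget.
Overlapping selections from different groups merge to their union (the
merged likelihood per group is the members' maximum), and a final
map-level pass applies the same cumulative-mean rule to Π_g(1 − p) so the
expected fraction of loci expressed in no group — exactly what
`estimate_false_positives` reports — is bounded by the FDR. Locus ids
are assigned in genomic order (ATSL000010, ATSL000020, …).

## Locus features

Intrinsic features use wild-type reads only (mutant and IP libraries do
not reflect endogenous sRNA populations). Depth-dependent estimates are
binned through a 95% CI (Wilson for binomial proportions, exact chi-square
for Poisson rates, seeded percentile bootstrap with B = 1000 for
methylation means): wholly within one partition → that label; crossing
one threshold → the partition nearest the feature's default; crossing
more than one → "unknown", which is a real categorical level downstream.
Bin thresholds are configuration values; the defaults (21/24 and
repetitiveness {0.2, 0.8}; strand {0.1, 0.3, 0.7, 0.9} folded
symmetrically; CpG {0.3, 0.7}; CHG/CHH {0.3}; H3 rate
{0.02, 0.1, 0.3}/base; marks {0.33, 0.66}) were chosen once against the
default archetypes' signal levels, standing in for thresholds that in
real data would be read off empirical density plots.

- **Width**: (0, 50], (50, 2000], (2000, ∞) nt, width = end − start + 1.
- **21/24 ratio**: proportion of 21-22 nt among 21-24 nt redundant reads.
- **Strand ratio**: proportion on the plus strand, five symmetric bins
  folding to strong/medium/no around 0.5; default "no".
- **Repetitiveness**: R = 1 − Σᵢ(xᵢ/mᵢ)/Σᵢxᵢ over distinct sequences at
  the locus; CI treats Σxᵢ/mᵢ as binomial successes among Σxᵢ trials.
- **Tissue**: expressed (p > 0.5) in ≥10 wild-type groups → common, 2-9 →
  intermediate, ≤1 → specific.
- **Phasing**: per wild-type group, a hypergeometric register test —
  distinct 5′ positions (minus-strand 5′ offset by +2) on the 21-nt
  register anchored at the locus start, against all occupied positions;
  the test is exact under a uniform null and conservative by
  discreteness. Significant (p < 0.05) in >5 groups → high, ≥1 →
  moderate, else none. Loci shorter than three phase cycles are "none".
- **5′ base preference**: one-sided binomial enrichment of each 5′ base
  among 21-24 nt reads against the genome-wide wild-type composition
  (recomputed from the data, never hard-coded), BH-adjusted over all
  loci × 4 bases; up to three bases may be preferred.
- **Methylation (CpG/CHG/CHH)**: percentile bootstrap of the mean
  per-cytosine proportion over cytosines overlapping the locus.
- **H3**: reads per base with an exact Poisson CI; bins are placed on the
  rate scale, equivalent under the monotone log to binning the log-rate.
- **Histone marks**: proportion k_mark/(k_mark + k_H3) with a Wilson CI —
  the bounded-proportion reading of "compared to the H3 dataset".
- **Dependency**: DCL2/3/4 uses expression mode — loci selected as
  expressed in the mutant group at FDR 0.05 are independent, all others
  dependent. RDR2/PolIV/PolV use a differential comparison: a no-loss
  model in which the mutant keeps the wild-type depth-normalised rate
  versus a loss model capping the mutant at 1/4 of it (a 2-fold
  alternative is not identifiable at dispersion 5 with 5 replicates);
  an empirically re-estimated mixing proportion yields per-locus loss
  posteriors, and FDR prefixes plus a posterior-majority guard give the
  three-way dependent/unknown/independent call. Loci with fewer than 5
  reads overall are "unknown".
- **Annotation overlap**: one or more shared bases; promoters are the
  500 nt upstream of gene starts, strand-aware. Overlap indicators are
  excluded from the MCA covariates and held out for validation.

## Classification

The feature table is expanded to complete disjunctive coding ("unknown"
is a level; single-level features are dropped with a warning; row sums
equal the number of features Q). Correspondence analysis of the indicator
matrix: standardised residuals S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, SVD,
eigenvalues = squared singular values, loci in principal coordinates.
Total inertia is J/Q − 1 for J levels; no Benzécri/Greenacre correction
is applied. K-means (25 k-means++ restarts, seeded) runs on the leading
principal coordinates; classes LC1..LCk are numbered by descending size.

Dimension choice is diagnosed by bootstrap stability: resample loci with
replacement, refit MCA + k-means, match resample clusters to the
reference by Hungarian assignment on the shared loci, and record the
proportion preserving their cluster. Cluster number combines Tibshirani's
gap statistic (uniform bounding-box reference, one-standard-error rule;
the full curve is returned so a conservative larger k can be taken) with
NMI against the held-out annotation-overlap features: when the one-SE
rule does not settle below the top of the k range — which happens when
the features carry genuine sub-structure — the k maximising held-out NMI
decides. NMI is I(A;B)/√(H(A)H(B)); two identical constant labelings
score 1, a single constant labeling otherwise scores 0.

Per-class enrichment uses two-sided Fisher's exact tests on (in class ×
has level) tables with BH adjustment across all pairs; sign follows the
odds ratio. Class hierarchies report, for each cluster at a higher k, the
distribution of its members over the clusters at the next lower k.
Paragons are the loci nearest each class centroid (Euclidean, ties broken
by locus id).

## Synthetic data

The generator defines the study conditions. A toy genome of two 2 Mb
chromosomes is split into arm/pericentromere/centromere zones
(0.4/0.3/0.3). Three archetypes of 200 loci each are planted in their
zones, ≥200 nt apart: *gene21* (80-300 nt, 21-nt reads, strand bias 0.95,
5′C-biased, unique-mapping, expressed in two of ten wild-type groups,
DCL-dependent, unmethylated, active chromatin, inside genes), *rddm24*
(120-500 nt, 24-nt, unbiased strand, 5′A-biased, losing expression in
dcl234/rdr2/polIV/polV, highly methylated, H3-poor, promoter-overlapping,
RC/Helitron- and mobile-associated), and *het24* (400-1200 nt, 24-nt,
multimapping 5-20 hits, PolV-independent but rdr2/polIV-dependent,
highly methylated, H3- and H3K9me2-rich, TE/IR/easiRNA-associated).

Per locus and library, read totals are negative-binomial (dispersion
size 5) with mean = per-library depth factor (log-normal, σ = 0.25) ×
class expression (default 5000 reads/library) × mutant retention, split
into at most 30 stacks carrying class-conditional lengths, strands, 5′
bases and hit counts. Background reads (count 1, unique-mapping) are
scattered uniformly outside planted loci at 0.5% of each library's
depth. The default expression and genome size were chosen so that scaled
library sizes reach the ~10⁶ scale the absolute RPKM threshold assumes;
at much shallower depths the heuristic's thresholds no longer separate
single background reads from signal, which is a property of the
published constants, not of this implementation. Methylation proportions
are Beta-distributed (concentration 20) around class means inside loci
and around 0.05 outside, on a regular cytosine grid cycling contexts;
degenerate means 0/1 produce exact 0/1. ChIP read counts per locus and
mark are Poisson at rate mark_rate × width, with uniform background;
H3 is always generated.

`sample_feature_table` draws categorical tables directly from per-class
signature levels with 8% uniform label noise — the fast path for
dimension/cluster-selection experiments.

What the generator does **not** emulate: sequence-level realism (no
hairpins, no real miRNA biogenesis, random nucleotide content), mapping
ambiguity (multimap counts are labels, reads appear at one location),
bisulfite reads (proportions only), positional correlation of
methylation, or adapter/quality artefacts. Passing tests therefore show
that the statistical machinery recovers planted structure of the assumed
form, not that it is robust to alignment or chemistry artefacts in real
libraries.

## Numerical choices and degenerate inputs

Wilson intervals for binomial CIs and exact chi-square intervals for
Poisson rates (stable at small n, deterministic); the Wilson point
estimate is clamped into its own interval at the 0/1 boundaries.
Bootstrap B = 1000 with a config seed. NB log-likelihood ratios are
clipped to ±700 before exponentiation; mixing proportions to
[10⁻⁴, 1 − 10⁻⁴]. Empty libraries raise; empty annotation files yield
empty sets; a locus with no overlapping cytosines, no eligible reads or
no ChIP coverage is "unknown" for that feature. K-means ties in label
ordering and paragon distance break deterministically (original label,
then locus id). All stochastic operations take explicit seeds; pipeline
stages derive distinct sub-seeds from the single config seed, and two
runs with the same config produce byte-identical outputs
(manifest-verified).

## Problem sizes

The shipped validation experiments use 600 planted loci on 2 × 2 Mb
(segmentation/class recovery), 20 seeded repeats of 600-locus
feature-table draws (cluster-number recovery), 400 loci × 10 libraries
(dependency calls), and 1000-fold simulations for the calibration checks
— sizes at which every planted effect is comfortably detectable while a
full run completes in about a minute.

## Known limitations

The posterior model is a deliberately simple two-component mixture, not a
full empirical-Bayes treatment with per-locus dispersion; its absolute
likelihood values saturate at 0/1 for strong signal, so the
false-positive estimate is meaningful mainly in aggregate. The RPKM
heuristic's constants are absolute and assume deep libraries (see above).
Bin thresholds are not re-derived from data density plots. Phasing uses a
fixed 21-nt register anchored at the locus start rather than a
phase-offset scan, trading a little power for exactness under the null.
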