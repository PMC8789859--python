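# Methods

`recurrevol` analyzes paired primary and early-recurrent tumor genomes to
decide whether a recurrence is *ancestral* (clonally derived from the
primary, typically via intra-hepatic dissemination in liver cancer) or
*de novo* (an independent second primary), and to reconstruct the clonal
evolution connecting the two tumors. Because matched-pair whole-genome
datasets of this kind are access-restricted, the package ships a synthetic
cohort generator that emulates the statistical structure of such a study;
every analysis stage is validated by recovering the generator's ground
truth.

## Mutation-set harmonization

Per-sample somatic mutation sets are made comparable in three steps, in
this order:

1. **High-confidence filter.** A called variant is kept iff tumor and
   normal are covered ≥ 10×, tumor VAF ≥ 5%, normal VAF < 1% (strict),
   and ≥ 3 reads support the variant in the tumor.
2. **CNV drop.** A mutation present in one sample but absent from another
   sample whose locus lies in a copy-number-loss region (total copy number
   ≤ 1) is excluded from *all* samples: its absence is explainable by the
   loss, so its sharing status carries no phylogenetic information.
3. **Force calling.** For every key in the patient's aggregate set, a
   sample lacking a call recovers the mutation when covered ≥ 10× with
   ≥ 2 supporting reads. The normal-depth requirement is not re-applied at
   this step (the site already passed it where originally called).

Statuses (`called`, `force_called`, `cnv_dropped`, `absent`) are recorded
per (mutation, sample) with an audit log from which the final sets can be
replayed. Sharing between tumors is summarized by the per-tumor shared
fractions f_A = |A∩B|/|A|, f_B = |A∩B|/|B|, their mean (the grouping
scalar; both components are reported so either denominator convention is
recoverable) and the Jaccard index. Force calling can only add members to
sets, so the mean shared fraction is non-decreasing across the step — an
invariant asserted on every synthetic case.

## Clonality index and cutoff calibration

For two tumors sharing M nonsynonymous mutations with population
frequencies p_m (occurrence count over the total mutation count of a
background cohort catalog), the chance that mutation m arose independently
in both is the binomial P(X) = C(2,2) p_m² (1−p_m)⁰ = p_m², and the
clonality index is

    CI = −log10 ∏_m P(X)_m = −2 Σ_m log10 p_m,

accumulated in log space (an exact big-integer product is used as the test
oracle). Keys never seen in the catalog get a pseudo-count of 1
(p = 1/N_cohort): the most conservative nonzero frequency, under which
rarer shared mutations count as stronger evidence of relatedness. Only
nonsynonymous SNVs and indels enter the CI; silent, noncoding and promoter
events are excluded.

The decision cutoff is calibrated on a cohort of unrelated tumors: per
repeat, each tumor contributes three positive-control pairs (two
independent subsamples at 40, 60 and 80% of its mutation set — we pair
duplicate against duplicate, not against the parent set) and an equal
number of random unrelated tumor pairs serve as negatives; the
accuracy-maximizing threshold is found by sweeping midpoints between
sorted observed CI values (ties resolved toward the smaller cutoff), and
the calibrated cutoff is the median over 100 repeats. Tumors are put in a
canonical content order first, so the result is invariant to input order.
A pair is called ancestral iff CI ≥ cutoff (ties ancestral).

Recurrence location uses the hepatic segment interval (HSI): the minimum
Couinaud-segment number distance between the segments hosting the two
tumors, capped at 4; HSI ≤ 1 is *local*, otherwise *distant*. This
linearizes segments I–VIII by number; true 3-D adjacency is not modeled.
Whole-genome doubling is called when tumor ploidy exceeds 2.9 (strict),
and gene-level CNV classes relative to the median ploidy are: deletion
(copy number 0) > amplification (> 2× ploidy) > gain (> ploidy) > loss
(< ploidy) > neutral.

## Cancer cell fractions and clustering

The cancer cell fraction (CCF) of a mutation follows from

    VAF = p · CCF / (CPN_norm (1−p) + p · CPN_mut)

with tumor purity p, local tumor copy number CPN_mut (from the sample's
segments, fallback round(ploidy)) and CPN_norm = 2. One mutated copy per
carrying cell is assumed (the CCF formula has no multiplicity term);
CPN_norm is fixed at 2 on all chromosomes — sex-chromosome hemizygosity is
a documented limitation.

Mutations are grouped by shared CCF vectors across the patient's samples
with a finite binomial mixture: cluster k has one CCF per sample, a
mutation's alt count in sample s is Binomial(depth, a·CCF_ks) with
a = p/(2(1−p)+p·CPN_mut) its locus factor. Crucially, the union mutation
set is *truncated*: a mutation enters only if it cleared the caller's
thresholds in at least one sample. The fitted model is therefore the
mixture conditioned on inclusion — the E step uses the plain component
densities (inclusion is a deterministic function of the observed counts),
while the observed-data likelihood divides by the mixture inclusion
probability and the M step augments each component with its expected
censored mass and censored read-count means (Poisson-tail detection model:
calling requires alt ≥ max(3, ⌈0.05·depth⌉) at ≥ 10×). Without this
correction, low-CCF private clusters are biased upward by ~0.1 and shared
clusters split along detection patterns.

Model size K is chosen by BIC over K = 1..8. Because k-means
initialisation on observed CCFs cannot see heavily censored clusters
(their observed tails are geometrically indistinguishable from mid-CCF
clusters), the search combines seeded k-means restarts, warm starts that
split the worst-explained (highest-deviance) mutations or components into
a new component, censoring-aware half-CCF split candidates, and a
downward prune chain from the richest fit. Components whose centers agree
within 0.08 (L∞ over samples; half the generator's identifiability
separation) are merged, which suppresses spurious splits at zero
separation. Everything is deterministic under the seed.

Clusters with fewer than 5/1,000 of the patient's mutations (strict) or
containing only silent mutations are filtered out. Categories are then
assigned with presence threshold 0.05 CCF and clonal threshold 0.8
(strict, on cluster centers — the package's reading of an ambiguous
definition): ancestral pairs get trunk clone / trunk subclones /
primary- and recurrence-branch subclones; de novo pairs per-tumor clones
and subclones; multi-region cases trunk / branch / leaf subclones by
presence pattern. When several clusters qualify as the clone, the one
with the highest minimum CCF keeps the title (exactly one clone per
scheme instance).

## Subclonal architecture

Trees over filtered clusters obey the pigeonhole constraints, within
tolerance ε = 0.05 CCF (sampling noise at ~54×; configurable): a parent
dominates each child in every sample, and the children of any node never
jointly exceed it. These two constraints propagate pairwise: clusters
whose CCFs sum above 1 in some sample are forced onto one lineage, and
clusters whose relative CCFs reverse between samples are forced onto
separate branches; the three-way conflict rule is enforced as the
sibling-sum constraint. Construction is greedy and deterministic:
clusters insert in decreasing total-CCF order (ties: larger size, then
lexicographic id), attaching to the feasible parent with the largest
minimum CCF margin, with backtracking; a brute-force enumerator over all
rooted trees (≤ 6 clusters) serves as the oracle, and the constructed
tree is always a member of the enumerated valid set. Phylogeny branch
lengths are cluster mutation counts scaled by the primary tumor's total.

Driver alterations are nonsynonymous SNVs/indels or promoter mutations in
a configured liver-cancer driver list (timed by the category of their
cluster), oncogene amplifications / TSG deletions, and SV breakpoints
inside driver genes (both timed by their sample-presence pattern, since
copy-number events are not clusterable here). Heterogeneity is
1 − Jaccard on final harmonized sets, averaged within tumors (spatial)
and across tumors (temporal); both per-sample and union denominators are
recoverable from the reported per-pair values. Polyclonal seeding of a
multi-region recurrence is called when ≥ 2 non-clonal trunk clusters are
subclonally present (0.05 ≤ CCF ≤ 0.8) in ≥ 2 recurrent regions; clusters
present in every recurrent region but no primary region are flagged as
monophyletic-dissemination candidates.

## Mutational spectra and signatures

Spectra use the pyrimidine-reference convention over the six classes
C>A, C>G, C>T, T>A, T>C, T>G, optionally at 96 trinucleotide-context
resolution. Exposures are refitted by nonnegative least squares against a
reference signature matrix, iteratively zeroing weights below 6% and
refitting, then renormalizing — the standard multiple-regression
refitting behaviour. Exposures are computed on normalized per-category
spectra. Tumors with > 9 mutations/Mb (strict; 2,800 Mb callable genome)
are flagged hypermutated. Per-category exposures across patients are
compared with paired t tests; categories with < 50 mutations are flagged
low-confidence, and single-patient comparisons report descriptive means
only.

The shipped reference matrix is **synthetic**: a deterministic
30-signature stand-in with the etiologically load-bearing shapes
(CpG C>T deamination, C>A tobacco/aflatoxin-like, flat aging-like, T>C,
and a dominant-T>A aristolochic-acid-like Signature.22); any externally
supplied 96×k matrix with matching labels drops in via
`signatures.read_signature_matrix`.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every benchmark runs under:

* 40 patients, 22/40 ancestral; 2–5 clusters per tumor; per-tumor burdens
  lognormal (median ≈ 13,000, σ = 0.8) clipped to 3,000–85,000, matching a
  right-skewed whole-genome burden distribution; 12.5% of patients are
  hypermutators (> 9/Mb, T>A-dominant spectrum). Burden parameters are
  *true* somatic mutation counts; the detected (caller-passing) counts run
  lower, by roughly half at the lowest purities.
* Mean depth 54× (tumors) / 36× (normal), Poisson; binomial allele counts
  at the expected VAF; purity uniform on 0.3–0.9; baseline copy number
  round(ploidy), with WGD tumors (ploidy > 2.9) enriched among ancestral
  recurrences.
* Ancestral pairs share 25–80% of mutations through a single clone tree
  whose recurrence branches descend from trunk subclones; de novo pairs
  are two disjoint trees whose only overlap (0–0.5% of keys) comes from
  population hotspots, emulating the near-zero sharing of independent
  pairs.
* The background catalog holds 200 tumors × 1,000 mutations; each tumor
  mixes a 5% hotspot fraction drawn from a Zipf(s = 1.5) law with private
  uniform-genome keys. A pure Zipf draw would put ~38% of draws on rank 1
  and make unrelated tumors share hundreds of saturated hotspots —
  inverting the calibration — so the Zipf law governs the hotspot
  component while most catalog entries remain singletons, which is also
  how real cohort catalogs look.
* Nonsynonymous rates are 15% in shared (trunk/clonal) clusters and 5% in
  branches. The trunk enrichment mirrors the empirical observation that
  nonsynonymous sharing exceeds genome-wide sharing in clonally related
  pairs; the overall level is chosen so patients' CI-eligible burdens are
  on the same scale as the catalog tumors' 1,000 coding mutations — the
  same-scale property that real calibrations rely on, at the cost of a
  coding fraction higher than real whole genomes.
* Planted stress features: copy-number-loss windows masking private
  mutations (exercising the CNV drop), low-CCF trunk subclones falling
  below caller thresholds in one sample (exercising force calling), a
  silent-only decoy cluster (exercising the cluster filter), driver
  SNVs/CNVs on designated nodes, trinucleotide contexts drawn from
  per-patient signature mixtures (optionally trunk-only Signature.22),
  and shared vs absent SV/viral-integration breakpoints by pattern.
* Cluster CCFs are drawn by stick breaking under the pigeonhole
  constraints with a minimum inter-cluster separation of 0.2 (L∞),
  progressively relaxed when a crowded tree makes the target infeasible;
  truth-recovery benchmarks score center accuracy only for clusters that
  actually kept ≥ 0.2 separation.
* Genome model: 22 autosome-proportioned intervals totalling 2,800 Mb;
  indels are 10% of mutations; indel identity uses suffix/prefix-trimmed
  anchored normalization (full left-alignment needs a reference sequence,
  which is out of scope).

What the generator does *not* emulate: sequencing error (so force calling
never fabricates sharing between truly independent tumors — real data
would recover more), germline variation, subclonal copy number, mutation
multiplicity > 1, sex chromosomes, and 3-D liver anatomy. Passing
benchmarks therefore demonstrate correctness of the inference machinery
under the stated generative assumptions, not end-to-end accuracy on real
sequencing data.

## Benchmark sizes and numerical choices

The truth-recovery benchmarks (see `recurrevol.evaluation` and
`scripts/acceptance.py`) use: 20 cohorts × 40 patients for pattern
recovery with per-cohort calibrated cutoffs (100 calibration repeats); 20
seeded ancestral cases for cluster-center (±0.10) and category recovery;
200 random configurations (≤ 5 clusters) for the pigeonhole oracle; 1,000
random key sets (≤ 50 keys) for the exact-CI oracle; 5,000 sampled
mutations for signature-mixture refitting; 20 patients for trunk-vs-branch
signature enrichment; and 20 multi-region seeds for the heterogeneity
direction. These sizes give stable rates while keeping a full run in the
tens of minutes on one core.

Numerical details: CI is computed in log10 space; EM tolerance 1e-5
relative log-likelihood with at most 60 iterations; detection tails use
the Poisson approximation to the binomial (accurate exactly where
detection is uncertain) with a truncation-correction gate at mean
expected alt count 20; NNLS is SciPy's active-set solver; chi-square
tests are run without continuity correction when all expected counts are
≥ 5, otherwise Fisher's exact test; empty-set shared fractions are 0 by
definition; heterogeneity means are absent (not zero) when no qualifying
region pairs exist.
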