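# Methods

This note documents the models, conventions and numerical choices behind
each canidkit module, what the synthetic generators do and do not emulate,
and where the design was genuinely open.

## Cohort simulation (`synthio`)

**Drift model.** Population allele frequencies follow a Balding–Nichols
parameterization: at a site with ancestral frequency *p*, population *k*
with differentiation *F_k* draws its frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean *p* and variance
F·p(1−p). This was chosen over coalescent simulation because it gives a
closed-form F_ST target: Hudson's estimator between two populations that
drifted independently from a shared ancestor has expectation *F*, so the
generator's parameter is directly recoverable from its output (checked to
±0.03 at 2×50 samples × 10⁴ sites). Genotypes are binomial in the
population frequency; sites are exchangeable, so there is **no linkage
disequilibrium** — anything that depends on LD structure (haplotype
sharing, realistic ROH length distributions, LD-based imputation accuracy)
is out of the simulation's reach and is either driven by explicitly
planted structure or consumed as precomputed input.

Ancestral frequencies default to Uniform(0.05, 0.95); a log-uniform
option exists for experiments that need appreciable rare-variant mass
(NRC stratification, discovery projection).

**Quality layers.** DP ~ Poisson(30) per genotype (≈30× short-read
coverage), GQ ~ min(99, Poisson(55)), and AD consistent with the genotype:
heterozygote alt reads ~ Binomial(DP, 0.5), homozygote alt reads 0 or DP.
Genotype errors are dosage swaps; missingness is injected uniformly at a
configurable rate (default 0 — no missingness mechanism is asserted by the
data this emulates).

**Sex chromosomes.** Male genotypes at X non-PAR sites are haploid
(ploidy 1, dosage ∈ {0, 1}) so the chrX-specific code paths (AB filter
skip, haploid NRC, chromosome counting in the SFS) are exercised.

**Admixed breeds.** `admixed_breeds > 0` creates breed labels whose
samples are drawn from two different hidden source populations; such a
"breed" cannot be monophyletic on any informative tree, giving a negative
control for the clade-support machinery.

**Autozygosity tracts.** `generate_roh_cohort` plants non-overlapping
per-sample tracts (mean 1000 SNPs at 2 kb spacing ≈ 2 Mb) inside which
the heterozygosity rate drops from 0.30 to 0.005 (residual genotyping
error); outside, genotypes are drawn i.i.d. Drift alone cannot produce
contiguous homozygous runs under an exchangeable-sites model, which is why
tracts are planted explicitly. Planted F_ROH is recovered within ±0.02
(measured ≤ ±0.006 at defaults).

**Structural variants.** Gene models are laid out on one chromosome with
fixed 150-bp exons and random 0.5–5 kb introns. For each designated
retrogene parent every intron is emitted as a deletion carried by the
designated samples. Background deletion/insertion lengths come from a
two-component mixture: with probability `sine_peak_fraction` a draw from
Uniform[180, 220] (the carnivore SINEC insertion mode at ~200 bp),
otherwise log-uniform on [50 bp, 100 kb] excluding [180, 220] — the
exclusion makes the peak fraction an exact binomial probability.
Background deletions are rejection-sampled so that none reciprocally
overlaps an annotated intron at ≥ 0.99, keeping the planted retrogene
truth the unique signal.

**Coverage tracks.** Truth-uncallable spans (200–2000 bp) receive one of
four violating signals: a reference N-run, MQ0 fraction ≥ 0.10,
depth below half the median, or depth far above it. Callable background
depth is Poisson around the median but clipped to [0.6, 1.4]× so the
realised median cannot drag background positions over the ±50% boundary.

**Mitochondria.** A random circular reference of length L = 16,727 with
a star-like haplogroup tree (shared group-defining variants plus private
ones per haplotype). Calls against each linear reference drop variants
within `edge_loss` (300 bp) of that reference's own linear ends —
the alignment failure mode the dual-reference merge exists to repair.
Heteroplasmic (allele fraction < 0.5) and strand-bias artifacts can be
injected for filter tests.

**Imputation pairs.** Each site carries a per-genotype corruption
probability from its MAF bin; a configurable fraction of sites is
"low-INFO" with the rate multiplied up (default ×5) and INFO drawn from
a lower range. Two corruption modes exist:

- `nonref` (default): only genotypes whose truth call is non-reference
  are corrupted. Under this model the bin's corruption rate equals the
  expected non-reference discordance, so the rate is identifiable as
  1 − NRC — the property the recovery checks rely on.
- `all`: every genotype is corrupted independently; overall genotype
  discordance then equals the rate, but 1 − NRC exceeds it (the NRC
  denominator excludes concordant homozygous-reference calls).

The two notions cannot hold simultaneously; `nonref` was made the default
because non-reference concordance is the metric the evaluator reports.

All generators are deterministic: identical (config, seed) gives
bit-identical output (NumPy `default_rng` with a fixed draw order).

## Callability mask (`maskcall`)

A position is uncallable iff (i) the reference base is N, (ii) the MQ0
read fraction is ≥ 0.10, or (iii) pooled depth deviates from the median
by strictly more than 50%. Boundary semantics are deliberate: MQ0
exactly 0.10 fails, depth exactly 1.5× or 0.5× the median passes. The
median is computed over non-N positions only (N-runs have zero depth and
would bias it) and separately for {autosomes + X-PAR} and {X non-PAR},
whose expected coverage differs by the male haploid X. The depth track is
a pooled cohort track, not per-sample. Masks round-trip losslessly
through 4-column BED.

The fraction-of-theoretical-variation report uses callable positions as
the denominator (one potential SNV per position), with complementary
reference bases collapsed (A/T, C/G) and per-base-change classes kept.

## Strict genotype filters (`strictfilter`)

Genotypes are nulled on DP < 5, then GQ < 20, then — heterozygotes only —
allelic balance alt/(ref+alt) outside the closed interval [0.30, 0.70]
(the only coherent reading of the "0.70 ≥ AB ≤ 0.30" convention); a called
het with zero AD reads is nulled under AB. Thresholds are inclusive
(DP = 5, GQ = 20, AB = 0.30/0.70 survive), matching the ≥ semantics of the
vcftools-style flags they mirror. AB is undefined for homozygotes, whose
read-level outliers are left to DP/GQ; haploid X non-PAR genotypes skip AB.
Site- then sample-missingness removal (defaults: site > 5%,
sample > 10%) alternates to a fixed point; the loop terminates because
both kept-sets shrink monotonically. Filters only ever null genotypes,
never change a called value.

AF classes use the exact boundaries rare AF ≤ 0.01,
0.01 < intermediate < 0.05, common AF ≥ 0.05, with ploidy-aware allele
counts. The HWE screen is the plain 1-df chi-square against expected
counts from the sample allele frequency (not the exact test), Bonferroni
threshold 0.05/m over the m polymorphic autosomal sites actually tested,
with candidates labeled homozygote-depleted or -excess. Note that a
structured cohort legitimately yields candidates (Wahlund homozygote
excess); single-population HWE simulations keep the family-wise rate at
the nominal level.

## Allele sharing, D and discovery projection (`sharing`)

"Presence" everywhere means ≥ 1 alternate allele regardless of zygosity.
The category partition assigns each polymorphic autosomal site to one of
7 presence cells over {breed+mixed, village, wolf}. F2 sites are carried
by exactly two samples with no missing genotype at the site.

Patterson's D uses the allele-frequency form,
ABBA = (1−p_W)p_X p_Y(1−p_Z), BABA = p_W(1−p_X)p_Y(1−p_Z),
D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA), so single samples and populations
share one code path. The standard error is a weighted delete-one block
jackknife over contiguous 5-Mb blocks (weights = per-block site counts,
Busing-style pseudovalues), Z = D/SE, significance |Z| ≥ 3. With fewer
than two blocks the SE is undefined and reported as NaN. Null
calibration and the 10% gene-flow detection are run at 50,000 sites ×
8 samples per population with F_ST 0.2 — sizes at which a 10% admixture
signal clears |Z| ≥ 3 while the null false-positive rate stays ≤ 5%.

The discovery projection models the observed spectrum as binomial
sampling from a frequency mixture, E[c_k] = Σ_j w_j Binom(k; 2n, f_j)
over a grid of 64 log-spaced frequencies on [1/(8N), 1]. Two linear
programs (HiGHS) minimise and maximise the expected discovery
g(w) = Σ_j w_j (1 − (1−f_j)^{2N}) subject to w ≥ 0 and
|{Bw}_k − c_k| ≤ ε_k with ε_k = 3√max(c_k, 1) (per-bin Poisson 3σ;
the tolerance is doubled with a recorded relaxation factor if the LP is
infeasible, which protects against pathological spectra). The point
estimate evaluates g at the non-negative least-squares fit of w, clipped
into [lower, upper]; fraction discovered = observed/point estimate.
Because Σ_k {Bw}_k = g(w) at N = n, any feasible w reproduces the
observed count within Σ_k ε_k, which pins the projection at the observed
sample size.

## Runs of homozygosity (`roh`)

PLINK-style scheme: slide a 100-SNP window one SNP at a time; a window
passes with ≤ 3 heterozygotes and ≤ 2 missing calls; a SNP is a hit if
≥ 5% of the windows overlapping it pass (0.05 is the PLINK
`--homozyg-window-threshold` default, which the parameter set this
mirrors does not restate); maximal hit runs are split at inter-SNP gaps
> 1000 kb, then filtered to length ≥ 200 kb, ≥ 100 SNPs (PLINK
`--homozyg-snp` default) and density ≤ 50 kb/SNP. Segment coordinates
are first/last SNP positions, not window bounds. The X chromosome is
excluded by default. F_ROH divides per-sample total segment length by a
caller-supplied genome size (assembly vs callable length is a reporting
choice, so it is a required parameter, not a constant). ROH-free regions
are the complement of the union of all samples' segments, annotated with
their overlap fraction against uncallable mask intervals and flagged at
the 80% and 20% levels.

## Cladistics (`phylo`)

1-IBS distance: Σ|g_a − g_b| / (2M) over the M mutually called sites
(equivalently 1 − (IBS2 + 0.5·IBS1)/M). Neighbor joining is Saitou–Nei
with the Studier–Keppler Q-matrix, deterministic via lowest-flat-index
tie-breaking; negative branch lengths are clamped to zero with a count
kept, matching PHYLIP behaviour. NJ is exactly consistent on additive
matrices (verified exhaustively for every topology up to 8 leaves and on
random 16-leaf trees).

Consensus: each of 100 replicates subsamples 10% of sites **without
replacement** (a bootstrap-with-replacement variant is a flag), builds an
NJ tree, and records which bipartition sides are unions of complete
breeds. Breed monophyly support is the fraction of replicates in which
the breed's samples form a branch; clusters of ≥ 2 breeds with support
> 0.65 are clades. The consensus tree uses extended majority rule
(clusters accepted greedily by support if compatible with those already
accepted). Supports are invariant to sample order.

IBD haplotype sharing consumes a segment table (pair, coordinates, LOD),
keeps segments with LOD > 3.0 and length ≥ 250 kb, totals per pair, and
averages within breed / within clade / between clades; the significance
threshold is the 95th percentile of the between-clade (background) pair
totals.

## Retrogenes and SV summaries (`svretro`)

A deletion matches an intron iff overlap/|deletion| ≥ 0.99 **and**
overlap/|intron| ≥ 0.99 (boundary inclusive). Matches aggregate per
parent gene. Carrier quorum: in a multi-intron gene a sample must match
≥ 2 distinct introns (one shared intron deletion is indistinguishable
from an ordinary deletion); single-intron genes require their one intron.
The quorum is configurable and flagged as interpretive — pooled-evidence
alternatives are defensible. Coordinates are 0-based half-open
internally, converted at VCF/GFF boundaries.

SV–SNV LD is genotype-dosage r² (composite LD; phase not assumed) against
every SNV within 100 kb of either breakpoint, best SNV reported,
strong-LD flag at r² > 0.8. Dosage r² approximates haplotype r² only
under HWE — a documented approximation, not an equivalence. Burden
summaries count carried variants (≥ 1 alt allele) and affected bp per
sample and category, with log2-spaced size histograms per SV type.

## Mitochondrial pipeline (`mitopipe`)

Coordinates: primary→rotated is ((pos − S) mod L) + 1 with S = 8000;
the inverse composes to the identity at every position (tested
exhaustively at L = 16,727). Merging takes positions in [1, 4000] ∪
(L−4000, L] from the rotated call set (converted to primary coordinates)
and the interior from the primary set; duplicates resolve strictly by
window membership (the rotated set wins inside the windows,
unconditionally). Filtering drops strand-bias failures and allele
fractions strictly below 0.5 (0.5 itself is kept); the consensus masks
positions with depth < 100 and the reference-specific positions
15,512–15,535 and 15,990 (configurable — they belong to one particular
reference). Haplogroup assignment is nearest labeled panel haplotype by
Hamming distance over positions unmasked in both sequences; exact ties
are flagged and resolved to the lexicographically first label. Pairwise
diversity is the mean Hamming distance over all pairs in groups of ≥ 3,
masked positions excluded pairwise.

## Imputation evaluation (`imputeval`)

Panel preparation removes multiallelic sites and sites with missingness
strictly above 5%. NRC considers genotypes where truth or imputed is
non-reference; concordance is all-or-nothing (het vs hom-alt gets no
partial credit). Strata: reference-panel MAF bins {(0, 0.01],
(0.01, 0.05], (0.05, 0.5]} × region {autosome+PAR, X non-PAR}. Sites
need INFO > 0.9 (configurable) except on the haploid male X, where
imputation software emits no scores and no INFO filter applies. Sites
present in truth but absent from the imputed set are counted separately,
never silently dropped. Raising the INFO cut cannot decrease NRC when
corruption is INFO-correlated and strictly reduces usable sites — the
monotone trade-off the evaluation is designed to expose.

## Problem sizes and limitations

Every check runs at desk scale: cohorts of tens of samples and 10³–10⁵
sites, chosen so the full suite completes in a couple of minutes while
Monte-Carlo tolerances (±0.03 F_ST, ±1% mask fraction, ±0.01 NRC,
±0.02 F_ROH) still bind. Because the simulator has exchangeable sites,
passing tests demonstrate correctness of the *computations* on inputs
with known truth — not that the statistics behave identically on real,
LD-structured genomes. The HWE screen's downstream triage against
alignment-level statistics, SV discovery itself, imputation itself and
IBD inference itself are out of scope: the package consumes their
outputs under documented record contracts.
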