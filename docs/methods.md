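# Methods

This note documents the statistical model behind `wasppop`, the defaults
it ships with, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want explained.

## Data model and filters

Genotypes are alt-allele dosages {0, 1, 2} with −1 for missing; phase is
discarded because every downstream statistic is allele-frequency based.
Positions are 1-based (VCF convention); windows are half-open
[start, start + window).

Site filters follow the conventions of the VCFtools options they mirror:
`max_missing` is a minimum call-rate fraction (boundary inclusive, so a
site with exactly 80% called survives at 0.8), and `min_mac` counts the
minor allele over non-missing calls only, boundary inclusive (mac 3
keeps a count of exactly 3). Physical thinning is greedy first-kept per
chromosome — deterministic, unlike a random pick per window — which is
what "one SNP every X bp" describes and what reproducibility demands.
Filtering is idempotent; thinning guarantees within-chromosome gaps of
at least the window size.

## Kinship and pruning

KING-robust within-pair kinship: φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i) +
N_Aa(j)) over sites called in both samples. It needs no allele
frequencies and tolerates population structure, which matters because
samples span differentiated regions. φ is invariant to allele-label
flips and site order; a duplicated non-inbred sample gives φ = 0.5 and a
parent–offspring pair ~0.25. Pairs sharing no heterozygous site are
undefined (NaN) and never trigger pruning — they are logged instead.

Pruning is greedy: repeatedly take the worst pair above the threshold
(default 0.1) and drop the member with the higher missing-genotype
fraction, breaking exact ties toward the lexicographically larger id so
runs are reproducible. Which member to drop is a free choice; keeping
the better-genotyped sample maximizes downstream information.

## Diversity statistics

Windowed π sums 2p̂q̂ · 2n/(2n−1) over sites and divides by the full
window span (not callable sites), matching the windowed-π convention of
standard VCF tooling so magnitudes are comparable to whole-genome tables
(~10⁻³–10⁻⁴). The mean is over windows containing at least one genotyped
site.

H_e uses Nei's unbiased per-site estimator 2p̂q̂ · 2n/(2n−1) — the same
small-sample correction π carries. The raw 2p̂q̂ alternative biases F_IS
by about −1/(2n) under Hardy–Weinberg, which would make the panmictic
control systematically negative at the sample sizes this package is
designed for (5–20 individuals per region). F_IS aggregates as a ratio
of sums across windows, 1 − Σ_w H_o,w / Σ_w H_e,w, which is stable when
individual windows have tiny H_e; a mean of per-window ratios is not.

Nuclear pairwise F_ST is the Weir–Cockerham (1984) two-population
weighted estimator Σa / Σ(a+b+c). Negative estimates are legitimate
small-sample outcomes and are preserved in raw output. Mitochondrial
F_ST is Hudson's 1 − H_w/H_b on the concatenated haploid genes, with H_w
the unweighted average of the two within-population mean pairwise
differences — the standard estimator for haplotype sequence data.
Alignment columns containing an ambiguous base in *any* retained sample
are dropped globally before any mitochondrial computation, so results do
not depend on which subset of samples a pair involves.

## Isolation by distance and dispersal

Group coordinates are centroids of member sample lat/long; distances are
haversine on a sphere of radius 6371.0088 km. The regression is OLS of
F_ST/(1 − F_ST) on distance in km over all unordered population pairs;
pairs at fixation (F_ST = 1) linearize to infinity and are excluded with
a flag. The OLS p-value is primary; a seeded two-sided Mantel
permutation p (labels of the differentiation matrix permuted, Pearson
correlation recomputed) is reported alongside because the n(n−1)/2
pairwise points share populations and are not independent. The Mantel
test is implemented in-package: linearized F_ST can be legitimately
negative, which distance-matrix containers in general-purpose libraries
reject.

Rousset's one-dimensional-transect relation σ² = 1/(4π·D_e·b) converts
the slope to the mean squared axial parent–offspring dispersal distance,
reported in meters at full precision (round only at presentation).
Two caveats travel with every estimate: σ scales as D_e^(−1/2), so an
overestimated density understates dispersal; and haplodiploid alleles
coalesce at three quarters of the diploid rate, inflating b and likely
overstating dispersal. A non-positive slope means no IBD signal: the
estimator refuses (no imaginary σ) with an explanatory error.

## Sex-biased dispersal

Under equal male and female dispersal in a diploid system the
mitochondrial genome — maternally inherited and effectively one quarter
the autosomal effective size — satisfies F_ST(mito) = 4F/(1+3F). The
test computes per-pair differences (observed mito − expected) and a
two-sided one-sample t against zero.

Two direction conventions exist in the literature on this system and
they conflict: the standard theory reads *excess* mitochondrial
structure (observed > expected) as reduced male gene flow relative to
female — i.e. female philopatry with male-biased dispersal — while the
empirical inference rule applied to these wasps read observed *below*
expectation as male-biased. The result object therefore carries the raw
signed difference plus both flags (`direction` for the empirical rule,
`direction_excess_mito` for the standard theory) and documents the
conventions in its metadata, so users cannot be misled by a single
label. Zero-variance difference vectors (within 1e-12 relative rounding)
are flagged degenerate with |t| = ∞ rather than a meaningless huge t.

## MDS and haplotype networks

Identity-by-state distance is 1 minus mean allele sharing over shared
non-missing sites (dosage difference 0/1/2 → sharing 1/0.5/0). Classical
(Torgerson) MDS double-centers −½JD²J and eigendecomposes; axes are
ordered by decreasing eigenvalue, scaled by √λ, and sign-canonicalized
(largest-magnitude loading positive) since eigenvector sign is
arbitrary. Negative eigenvalues — IBS distances are not exactly
Euclidean — are dropped with a warning rather than imputed, truncating
the requested axis count if needed.

The haplotype network collapses identical sequences into nodes (counts
and per-population composition attached) and joins them by a minimum
spanning tree on Hamming distances, Kruskal's algorithm with the
deterministic tie-break (weight, nodeA id, nodeB id). A non-tree edge is
flagged `is_alternative` when its weight exactly equals the maximum
weight on the tree path between its endpoints — the strictest reading of
equal-weight alternative connections (epsilon 0). A seeded
`balanced_subsample` utility caps per-group sample counts for analyses
sensitive to uneven sampling.

## The synthetic-data generator

The simulator is a forward-time Wright–Fisher stepping-stone model on a
torus lattice with two explicit sexes per deme:

* **Females** (`deme_breeders`, default 30/deme) are diploid and carry
  the mitochondrial sequence; with 1 km spacing the default breeder
  density is D_e = 30 females/km² — a deliberately scaled-down analogue
  of nest density (real surveys give ~10³/km²; scaling D_e down by ~30×
  at fixed σ scales F_ST differences up ~30×, giving measurable signal
  from hundreds rather than millions of SNPs while leaving the
  σ²·D_e·b = 1/4π geometry intact).
* **Males** (equal pool) are haploid maternal gametes under
  `haplodiploid=True` (the default — the organism is a wasp) or diploid
  otherwise. Two explicit sexes matter: the 4F/(1+3F) mitochondrial
  expectation presumes mito N_e = N_f against 2(N_f+N_m) autosomal
  copies; a single monoecious pool would halve that ratio and bias the
  equal-dispersal null.
* **Dispersal**: each offspring's mother comes from a deme displaced by
  a discretized Gaussian kernel (axial SD σ_f/spacing, truncated at
  4 SD, renormalized, torus wraparound) and its father's deme by σ_m.
  Kernels reaching halfway around an axis are rejected as boundary
  artifacts.
* **Genetics**: nuclear sites are unlinked (per-site random parental
  allele — free recombination, matching the thinned-SNP regime the
  analyses assume) with symmetric two-allele mutation (default 10⁻³ per
  site per gamete, chosen so a few hundred sites stay informatively
  polymorphic at desk scale); the mitochondrial sequence (default
  1,200 bp at 2×10⁻⁴) mutates on transmission. Default burn-in is
  10 × deme_breeders generations from interior starting frequencies.

Measured behavior matches theory without tuning: single-deme allele
frequency drift variance is p(1−p)/(4N_f) for the diploid two-sex model
and 4/3 of that under haplodiploidy (the ¾-coalescent effect emerges
from the mechanics); diversity equilibrates to the symmetric two-allele
stationary value α/(2α+1), α = 4N_e μ; isolated demes diverge to
F_ST > 0.5 with disjoint mitochondrial haplotypes.

**What the generator does not emulate**: linkage and recombination maps,
selection and background selection, demographic change or range
expansion (glacial-refugia history), overlapping generations, nest-level
social structure beyond maternity, genotyping error and coverage-driven
missingness. Passing tests therefore demonstrate correctness of the
estimators and the inference chain under the idealized stepping-stone
model, not robustness to those real-data complications.

The default sampling plan takes 8 females from each of the first 10
demes of the 20-deme ring: confining the transect to half the ring keeps
geographic distance monotone in lattice distance (no torus shortcut),
and spans 2–18× σ, inside the sampling window where Rousset's regression
is documented to behave.

## Validation design

* Estimators are checked against independent oracles: an explicitly
  looped transcription of the Weir–Cockerham variance components,
  exhaustive pair enumeration for Hudson F_ST, exhaustive spanning-tree
  minima for the network, closed forms for KING (duplicates, i.i.d. HWE
  draws), and Procrustes self-consistency for MDS.
* Parameter recovery runs 20 replicate 20-deme ring simulations
  (σ_f = σ_m = 0.5 km, diploid) through the full chain and requires the
  Rousset σ within a factor of two of truth in ≥80% of replicates; the
  same replicates serve as the equal-dispersal null for the sex-bias
  test (mean observed−expected mitochondrial F_ST within 3 SE of zero),
  and 20 further replicates with σ_m/σ_f = 10 must show the
  male-biased signature (sign test). The ring geometry differs from the
  infinite-plane derivation of the 2-D Rousset formula; the observed
  recovery ratios (~0.95–1.2) show the combined geometry and
  density-definition effects stay well inside the factor-two band.
* Replicate counts (20), site counts (250–500) and deme sizes (20–60)
  are chosen so the full suite runs on a laptop in a few minutes while
  leaving each stochastic check several standard errors of headroom.

## Known limitations

* Windowed F_IS aggregation (ratio of sums) is one of several defensible
  conventions; per-window-mean aggregation gives slightly different
  values on sparse windows.
* The Rousset estimator inherits every assumption of the underlying
  model: equilibrium, constant density and dispersal through time, and a
  one-dimensional sampling geometry; the haplodiploidy correction is
  directional only.
* Hudson mitochondrial F_ST on very few sequences per population is
  noisy and can go negative; values are not clamped in raw output.
* The pipeline drops populations reduced below two members by kinship
  pruning rather than imputing or merging them.
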