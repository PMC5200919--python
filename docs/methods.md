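# Methods

`padnet` implements a pathway-and-module discovery procedure for case-control
GWAS data in four stages: (1) SNP-set association testing per pathway with a
logistic kernel machine score test, (2) an exhaustive pairwise epistasis scan
over the SNPs of the significant pathways, (3) construction of a gene network
whose edges require both an epistatic signal and protein–protein interaction
(PPI) support, followed by topology, scale-free, hub and modularity analysis,
and (4) GO over-representation analysis of the resulting modules. A synthetic
data generator with planted truth makes every stage testable without any
external data.

## SNP-set kernel machine test

For a pathway whose mapped SNPs have dosage columns `z_1 … z_p`, the model is

    logit P(y_i = 1) = α0 + h(z_i1, …, z_ip)

with `h` in the reproducing-kernel space of a positive semi-definite kernel
`K`. The default kernel is weighted linear, `K(z_i, z_i') = Σ_j w_j z_ij z_i'j`;
Gaussian and identical-by-state kernels are options. The null `h = 0` is
tested with the variance-component score statistic

    Q = (y − μ̂0)ᵀ K (y − μ̂0) / 2 ,

where `μ̂0` are fitted probabilities of the null logistic model
(intercept-only by default; covariates supported). Under H0, Q is a mixture
`Σ λ_k χ²_1` with `λ_k` the eigenvalues of `(1/2) P0^{1/2} K P0^{1/2}`,
`P0 = D − D X (XᵀDX)^{-1} Xᵀ D`, `D = diag(μ̂0(1−μ̂0))`. For the linear
kernel the same non-zero spectrum is obtained from the p×p matrix
`(1/2) W^{1/2} Zᵀ P0 Z W^{1/2}` at O(np²) cost, which is what
`test_pathways` uses; the dense n×n route is kept for the other kernels and
as the reference implementation.

Tail probabilities are computed by numerical inversion of the characteristic
function (Imhof/Davies-type integral, absolute accuracy 1e-6 via adaptive
quadrature). A single mixture component reduces to the exact 1-df chi-square
tail. If the integration does not converge, or returns a value below 1e-12
where integration noise dominates, the moment-matching (Liu–Tang–Zhang)
approximation is used instead and the fallback is logged. Eigenvalues below
−1e−8·λmax indicate a broken projection and raise; small negative values are
clipped to zero.

### Weights

`beta` weights follow the SKAT convention `w_j = Beta(maf_j; a1, a2)²` with
default (1, 25), which strongly up-weights rare variants; `flat` weights set
all `w_j = 1`. The default scheme is `beta`, but note that for a study of
common variants with comparable per-SNP effects — exactly what the synthetic
generator produces — flat weighting is the matched analysis: Beta(1,25)²
assigns a SNP at MAF 0.3 roughly 10⁻⁶ of the weight of a SNP at MAF 0.05 and
can discard most of the signal. The power/recovery tests therefore use flat
weights, while calibration (type-I error) is verified under the beta default.

### Multiple testing

Bonferroni across the `N` sets tested: `p_adj = min(1, p_raw · N)`, with
significance claimed when `p_raw · N < 0.05`.

## Genotype QC

Filters run in a fixed order — SNP missingness (< 5%), sample missingness
(< 5%), MAF (> 0.01, recomputed after sample removal), Hardy–Weinberg screen
in controls (P > 1e-4) — and every removal is recorded in a `QcReport`. HWE
uses the 1-df chi-square goodness-of-fit test by default (deterministic and
adequate at the 1e-4 screen); a conditional exact test is available.
Monomorphic SNPs return P = 1 by convention. Missing genotypes are then
imputed with the SNP's modal observed code (ties toward the smaller dosage).

Tag-SNP selection slides a 50-SNP window by 5 SNPs per chromosome; within a
window, while any retained pair has dosage r² > 0.8, one member of the
offending pair is removed. The removal rule is deterministic: more
pre-imputation missingness first, then lower MAF, then later position. r² is
the squared Pearson correlation of dosage vectors (composite LD; no phasing).
SNPs map to genes if they fall within 5 kb of the gene body; genes use BED
0-based half-open coordinates and SNPs 1-based positions, so a SNP at
position p maps to gene [s, e) iff s + 1 − 5000 ≤ p ≤ e + 5000.

## Epistasis scan

Every unordered pair of distinct SNPs in the union of the significant
pathways' SNP sets is tested with the full logistic interaction model
`logit P(y=1) = b0 + b1 g1 + b2 g2 + b3 g1 g2` (Newton/IRLS, tolerance 1e-8,
max 50 iterations) and the two-sided Wald test of `b3 = 0`. Pairs whose
interaction column is constant (minor alleles never co-occurring) are
recorded as not testable; fits escaping to |b| > 15 are flagged as
quasi-separation and excluded. Pairs at nominal P < 0.05 are retained — no
multiple-testing correction at this stage by design: the downstream
requirement of experimentally-supported PPI evidence acts as the false
positive filter. Retained SNP pairs expand to gene pairs through the SNP–gene
map; same-gene combinations are dropped and duplicates collapse with a
support count and minimum p.

## Gene network

An edge exists iff the gene pair is both an epistatic candidate and a PPI
record; candidate genes without a supported edge remain as isolated nodes.
Analysis focuses on the largest connected component: degree, unnormalized
betweenness, local clustering, density and diameter (largest finite
eccentricity).

Scale-freeness: the degree tail k ≥ xmin (default xmin = 1) is fitted with
the exact discrete power-law MLE — numerically maximizing
`−α Σ ln k − n ln ζ(α, xmin)` — rather than the popular closed-form
continuous approximation, which is strongly biased at xmin = 1 (it recovers
≈2.16 for a true α of 3). Goodness of fit is the KS sup-distance between the
tail empirical CDF and the fitted CDF; its p-value is the fraction of
`n_boot = 1000` seeded bootstrap samples from the fitted law whose refitted
KS distance exceeds the observed one (high p ⇒ power law not rejected).
Clauset-style minimal-D xmin selection and an asymptotic KS p are options.

Hubs: per node, `P(X ≥ degree)` for `X ~ Poisson(λ)` with λ the mean degree
2E/V of the tested (sub)graph, computed by direct summation of the
complement; Bonferroni over the node count; hubs flagged at adjusted
p < 0.05. Both λ and the correction denominator are conventions the source
analyses leave unstated, so they are explicit and configurable.

Modules: Newman modularity maximization. The default algorithm is the
fast-greedy agglomerative heuristic (networkx `greedy_modularity_communities`);
a leading-eigenvector spectral bisection (recursive splits on the modularity
matrix, stopping when a split no longer increases Q) is the alternative.
Nodes are processed in sorted order and modules numbered by decreasing size,
so partitions are deterministic. Reported Q is always a direct evaluation of
`Σ_c (e_c/m − (d_c/2m)²)` on the returned partition.

## GO enrichment

Annotations are propagated along is_a edges (true-path rule; part_of is not
used by default). For each module of at least 10 genes, each term with
overlap k ≥ 1 gets the one-sided hypergeometric tail `P(X ≥ k)` with
N = background size, K = genes annotated to the term or its descendants,
n = module size; an `ease` switch reproduces the DAVID/EASE variant (tail at
k − 1). Bonferroni uses the number of terms tested for that module. Reported
terms are filtered to ontology depth ≥ 4, where depth is 1 + the minimum
is_a distance to the namespace root (root depth 1; minimum-path rule for
multi-parent terms). The background defaults to all genes in the annotation
table. The module-size threshold is inclusive (≥ 10) and configurable: the
source analyses are ambiguous between "more than 10" and the 10-gene modules
they report on.

## Synthetic data generator

The generator emulates a retrospective case-control genotyping study:
biallelic autosomal SNPs grouped into genes (non-overlapping intervals on up
to 22 chromosomes), gene sets of 5–30 genes per pathway (optionally disjoint,
so non-risk pathways are genuinely null), per-SNP MAF uniform on [0.05, 0.5],
genotypes Binomial(2, MAF), and a binary phenotype from

    logit P(y=1) = β0 + Σ_j β_j g_j + Σ_(a,b) γ_ab g_a g_b

where risk pathways contribute a per-SNP log-odds β to all SNPs of their
genes and planted epistatic SNP pairs contribute interaction log-odds γ.
β0 is tuned by bisection (tolerance 1e-4 on a 20,000-draw Monte-Carlo panel;
closed form when no effects are planted) so the expected prevalence matches
the target case fraction; individuals are then sampled until the exact
case/control quotas are filled, mimicking the 2000-case / 3000-control
design of the motivating study at configurable scale. Missingness is MCAR.
Optional within-gene LD uses a Gaussian copula with a shared per-gene latent
factor (latent correlation 0.99 by default; discretization attenuates this
to dosage r² ≈ 0.85, above the 0.8 pruning cutoff), giving blocks of
correlated dosages for the pruning stage to remove; it is off by default for
association tests. The PPI table always contains every planted epistatic
gene pair (so end-to-end recovery is well-posed) plus Bernoulli background
edges. The GO generator builds a ≥6-level DAG with a guaranteed-depth chain,
annotates genes to 1–3 random terms, and deliberately enriches one term of
depth ≥ 4 in a designated gene slice.

All randomness derives from a single root seed through per-stage child
streams, so identical configurations give byte-identical output files, and
planting extra effects does not perturb the gene/pathway draws.

What the generator does **not** emulate: realistic human LD maps and
recombination structure, population stratification, genotyping batch
effects, informative missingness, allele-frequency spectra skewed toward
rare variants, or overlapping pathway hierarchies of real databases.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated on idealized data, not that the pipeline is robust to the
confounders of real cohorts.

## Problem sizes in the shipped tests

Calibration and recovery runs use desk-scale versions of the study design:
type-I error from 1,000 null replicates at n = 500 with a 20-SNP pathway;
planted-pathway recovery from 50 replicates at n = 2,000 with one 10-SNP
risk pathway (per-SNP β = 0.35) among 19 disjoint null pathways; epistasis
calibration from the ~19,900 pairs of 200 null SNPs at n = 400 and power
from 50 replicates of a γ = 1.0 pair at n = 2,000; power-law self-consistency
from 20 samples of 500 degrees at α = 3 with 1,000 bootstrap replicates
each. The end-to-end pipeline checks use ~700 samples, 40 genes and 6
pathways with a strongly planted risk pathway and three planted,
PPI-supported epistatic pairs.

## Known limitations

- The Davies-type integration loses relative accuracy for p below ~1e-12;
  such tails are reported through the moment approximation, which preserves
  ranking but not exact tail values.
- The mixture null is asymptotic. Against the exact phenotype-permutation
  null its body differs by O(1/n): the permutation mean of Q carries a
  factor n/(n−1) and the permutation variance is smaller (finite-population,
  two-valued residuals). At n = 60 this produces visible (~0.02–0.03)
  p-value offsets in the distribution body, disappearing by n ≈ 300; with
  Beta(1,25)² weights on a near-rare SNP the kernel can additionally
  collapse onto one discrete direction, widening the gap. Small-sample
  pathway p-values should therefore be read as approximate.
- The fast-greedy modularity heuristic can merge small cliques on graphs
  with resolution-limit structure; the leading-eigenvector option behaves
  differently on such inputs, and neither is an exact maximizer.
- The hub test treats edges as independent Poisson draws; on dense graphs
  the Bonferroni-corrected Poisson tail is conservative.
- Sliding-window pruning is order-dependent by construction (a SNP removed
  in any window stays removed); the deterministic removal rule makes runs
  reproducible but is one of several defensible conventions.
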