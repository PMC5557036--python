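# Methods

`synchromet` quantifies how much the co-existing (synchronous) metastases of
one cancer patient differ from each other — genomically, immunologically and
radiographically — and how those differences relate to each lesion's response
to therapy. This note records the statistical procedures, the conventions
behind every tunable default, what the synthetic-cohort generator does and
does not emulate, and the design choices made where more than one reasonable
reading existed.

## Somatic variant filtering and mutation overlap

Input calls are somatic SNVs with tumor/normal read depths and variant
allele fractions (VAFs). The post-calling filter retains a call iff

* tumor depth ≥ 20 and matched-normal depth ≥ 10,
* tumor VAF ≥ 0.01,
* matched-normal VAF ≤ 0.01, and
* the site is absent from germline databases (dbSNP / 1000 Genomes /
  ESP-6500), tested as membership in *any* of them.

The normal-VAF condition is sometimes printed in the opposite direction in
write-ups of this filter; as printed that direction would retain only
contaminated calls, so the standard somatic orientation (≤) is the default
and the comparator is configurable (`FilterThresholds.normal_vaf_keep`).
Filtering is order-preserving and idempotent.

Mutation identity is the genomic key `(chrom, pos, ref, alt)` — two distinct
substitutions in one gene are distinct events. The shared percentage between
two lesions is `100·|A∩B|/|A∪B|`; no convention for the denominator is
universal, and the union makes the statistic symmetric and bounded. For
patients with more than two lesions the patient-level value is the
unweighted mean over all lesion pairs. The C>T fraction folds strands
(G>A counts as C>T) and divides by all SNVs supplied.

## Neoepitopes

For a missense change at protein position *p*, every window of length
8–12 containing *p* and lying fully inside the protein is emitted as a
mutant/wild-type peptide pair (the count per length *k* is
`min(p, L−k+1) − max(1, p−k+1) + 1`). Binding is delegated to a pluggable
oracle mapping (peptide, allele) → IC50 in nM; binders are called at
IC50 < 500 nM and high-affinity binders at < 100 nM, both strict. The
bundled `SyntheticAffinityOracle` is a salted-hash log-normal stand-in
(median ≈ 5 µM, log10-sd 0.8, ≈10% binders among random peptides) — it
encodes no biochemistry and exists so the classification and overlap
machinery is testable without an external predictor; measured or predicted
affinities can be imported from TSV. The HLA allele is an opaque string
parameter throughout.

## Immune score, flow fractions, IHC

The immune score is the geometric mean of expression over five gene sets
(cytolytic effectors GZMA/GZMB/PRF1/GNLY; 18 HLA genes; six IFN-γ-pathway
genes; seven chemokines/receptors; six adhesion molecules — 41 genes).
Because raw digital counts can be zero, a pseudocount (default 1) is added
before the log-mean; at pseudocount 0 the score is exactly scale-equivariant.
The mean is pooled over the union of the five sets by default — the natural
reading when the sets are listed in one breath — with `per_set=True`
returning one geometric mean per set. Flow results are subset percentages of
CD45+ cells; IHC markers are summarized as an H-score (Σ intensity ×
percent positive, 0–300) or as the mean positive-cell density per mm² over
five analyzed areas.

## TCR repertoire statistics

All statistics use productive clones only, identified by the CDR3
amino-acid sequence. Clonality is `1 − H/log2(U)` with `H` the Shannon
entropy (bits) of clone frequencies and `U` the number of productive unique
clones; a single-clone repertoire is assigned clonality 1.0 by convention
(the formula is 0/0 there, and a monoclonal repertoire is maximally clonal).
Clone sharing between lesions is the Jaccard percentage over the union of
productive clone ids. "Top X%" selects the minimal set of highest-frequency
clones whose cumulative frequency reaches X% (the repertoire convention; a
rank-percentile mode is available), with frequency ties broken by clone id
for determinism. A top clone is *restricted* to a lesion when it appears in
no sibling lesion of the same patient. Top-n rank correlations pair the top
clones of one lesion with their frequencies in the other (0 when absent) and
report mid-rank Spearman rho with a seeded two-sided permutation p.

## Radiomics

Masked gray-level co-occurrence matrices: intensities inside the
region-of-interest mask are quantized by equal-width binning over the masked
min–max range (32 levels by default), which makes all downstream features
invariant to positive affine intensity rescaling. For each offset (the four
distance-1 2-D directions by default; arbitrary N-D offsets are accepted) a
pixel pair contributes only when both ends are inside the mask; symmetric
mode accumulates both orderings. An offset with fewer than two in-mask pairs
is an error; the lesion profile skips failing offsets and errors only when
all fail. Features: entropy (−Σ p log₂ p), energy (Σ p²), homogeneity
(Σ p/(1+|i−j|), the inverse-difference form; the inverse-difference-squared
form is available via `GLCMSpec.homogeneity_form` since published texture
toolkits disagree), dissimilarity (Σ p|i−j|) and contrast (Σ p(i−j)²). The
lesion profile is the unweighted mean over offsets — the standard
direction-averaging convention.

## Responses and heterogeneity flags

Per-lesion percent change from baseline is classified with RECIST-1.1-style
thresholds applied to single lesions: CR at −100%, PR at ≤ −30%, PD at
≥ +20%, SD otherwise. True RECIST operates on sums of diameters across
target lesions; applying the thresholds per lesion is a deliberate,
documented divergence, since the analysis is about per-lesion heterogeneity.
A patient is flagged response-heterogeneous at threshold t when the maximum
pairwise difference in percent change among their lesions is ≥ t (t = 10,
20, 50 by default). The best-responding lesion is the most negative percent
change ("largest tumor size change" is read as largest decrease), the worst
the most positive, ties broken by lesion id.

## Clustering and branch-length heterogeneity

Samples are clustered with Ward linkage in the ward.D2 convention (merge
cost on squared dissimilarities, heights on the dissimilarity scale; scipy's
`linkage(..., method="ward")` on a condensed distance matrix). Genomic
blocks — which legitimately contain zeros — use Euclidean distance;
continuous immune blocks use Pearson correlation distance 1 − r (a
zero-variance sample is an error naming the sample). The *average branch
length* of a group of leaves is the mean cophenetic distance (height of the
lowest common merge) over all pairs in the group; the alternative reading —
the height of the merge that first contains the whole group — is available
as `mode="spanning_height"`. Group comparisons use the two-sided Wilcoxon
rank-sum test, exact for small tie-free samples. Variable heatmaps z-score
each variable row and cluster variables with Ward on 1 − Spearman distance.

## Marker–response association

The response indicator is binary within patients (best or worst lesion vs
the rest). Rather than fitting a random-intercept ANOVA, the default test
permutes the indicator *within each patient* — the exact exchangeability
structure the random intercept models — and uses the difference of marker
means between classes as the statistic, with
`p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm)` (the +1 correction keeps
Monte-Carlo p-values valid). Patients whose lesions all carry one indicator
value contribute no contrast and are excluded with a warning. A
patient-random-intercept linear model (statsmodels MixedLM) is available as
`backend="mixedlm"`. p-values are Benjamini–Hochberg adjusted across
markers. Dichotomized comparisons split a marker at its median (ties to the
low group) and apply Fisher's exact test (two-sided, point-probability
rule). Random forests use 1000 trees, node size 1, mtry = √p and Gini
splitting, with importance the mean decrease in node impurity and the
out-of-bag misclassification rate as the error estimate. Plain pairwise
correlations (Pearson or mid-rank Spearman) carry seeded permutation
p-values (10 000 permutations by default).

## The synthetic cohort generator

No per-patient data tables are packaged, so every stage is exercised on a
seeded generator that emulates the *statistical structure* the analysis
assumes. Per patient it draws a mutation pool, a clone universe, latent
immune and complexity factors, and per lesion emits a variant table,
repertoire, expression vector, flow fractions, a 64×64 16-bit image with a
central-disk mask, and baseline/follow-up sizes. All distributions are
generator conventions (stand-ins), not claims about any measured dataset:

* **Mutations.** The pool size is `n_trunk_mutations + n_private_mutations`
  (default 200). Each mutation is trunk (present in all lesions) with
  probability `p = 2s/(L(1−s)+2s)`, calibrated so the expected pairwise
  union-denominator shared percentage equals `shared_nsem_fraction` (default
  0.55) for any lesion count L; non-trunk mutations belong to exactly one
  lesion. Depths are negative binomial (mean 150, dispersion 10), tumor VAF
  Beta(5, 15), matched-normal VAF Beta(1, 2000). The normal-VAF distribution
  is deliberately tight: a heavier contamination tail makes the normal-VAF
  filter fire independently per lesion on true trunk calls, which
  decorrelates lesions and biases the recovered shared percentage downward.
  Substitutions are C>T/G>A with probability `ct_fraction` (default 0.79,
  the UV-signature convention for cutaneous melanoma), otherwise uniform
  over the remaining types. Database contamination flags are drawn per
  mutation (shared across lesions) at rate 0.05.
* **Repertoires.** Each lesion carries `n_clones_per_lesion` clones (default
  300) with counts `ceil(C/rank^a)` (Zipf exponent default 1.1, ranks
  shuffled per lesion). A per-patient shared set of size
  `k = round(2nf/(1+f))` appears in every lesion, making the pairwise clone
  Jaccard equal `shared_clone_fraction` (default 0.08) by construction.
  Productivity is a per-clone property (rate 0.9).
* **Expression and flow.** Gene baselines are patient-level
  (log-normal, `expr_mu=4`, `expr_sigma=0.6` natural-log scale) and a
  per-lesion latent immune factor z (sd `immune_latent_sd=0.8`) shifts the
  41 immune-score genes only. Lesion expression is deterministic given the
  baselines and z, so at latent-sd 0 a patient's lesions have identical
  immune scores by construction; measurement noise is modeled separately via
  `replicate_expression` (log-sd 0.15), used for within-lesion replicate
  contrasts. The checkpoint arm attenuates the latent sd by 0.4
  (`arm_immune_sd_scale`), emulating immune-selection pressure reducing
  between-lesion immune divergence; targeted and naive arms are unattenuated.
  Flow fractions are Dirichlet over 12 CD45+ subsets scaled to sum ≤ 100%,
  with the CD8 concentration multiplied by e^z so CD8 infiltration couples
  positively to the same latent factor.
* **Images and responses.** A lesion's patch mixes a smooth Gaussian random
  field with white noise at weight c³ for latent complexity c ~ U(0.02,
  0.98); cubing keeps GLCM entropy approximately rank-linear in c (entropy
  saturates quickly once noise dominates a linear mix). Percent change from
  baseline is a Gaussian copula on c with correlation `texture_response_rho`
  (default 0.6), scaled by `response_scale` (default 25 percentage points)
  and clipped to [−95, 180]. The scale was set so a 60-patient two-arm
  cohort reproduces the response-heterogeneity conditions the analysis is
  designed around: ~83% of patients with ≥10-point intrapatient differences
  and median intrapatient growth differences in the 20–30-point range.
  Baseline sizes are log-normal around 25 mm.

What the generator does **not** emulate: read-level sequencing error,
subclonal structure beyond trunk/private, nucleotide-level clone identity,
V/J usage, NanoString normalization controls, 3-D image volumes (texture
formulas are dimension-agnostic; volumes are emulated as single slices) and
real lesion morphology. Passing tests therefore demonstrate that the
*statistics* are implemented correctly and recover known truth under the
assumed structure — not that the defaults match any particular measured
cohort.

## Numerical conventions

* Entropies are log base 2. `0·log 0 = 0` throughout.
* Permutation p-values always use the +1 correction and explicit seeds;
  comparisons of permuted to observed statistics use a 1e-12 tolerance so
  exact ties count as hits.
* Clonality of a single-clone repertoire is 1.0 (documented convention).
* Frequency ties in top-clone selection and lesion ties in best/worst
  response break by identifier, making every pipeline output reproducible.
* Ward merge ties follow scipy's lowest-index convention.
* Cohort CSV writers use 17-significant-digit floats and readers parse with
  round-trip precision, so a written cohort reloads losslessly; VAFs travel
  in VCF INFO as full-precision strings (htslib floats are 32-bit).
* GLCM probabilities must sum to 1 within 1e-12; constant regions quantize
  to a single level rather than erroring.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
parameter-recovery checks use ≥500 mutations, 2000 clones, 1000 SNVs and
~50 lesions per quantity; the permutation-test calibration uses 1000 null
cohorts of 8 patients × 2 lesions at 999 permutations; the arm-ordering
contrast uses 100 cohorts of 10 patients per arm; the end-to-end run uses a
12-patient cohort. These sizes were chosen as the smallest at which the
sampling tolerances quoted in the tests are comfortably non-trivial.

## Known limitations

* The shared-percentage calibration is exact for the pairwise union
  denominator; per-lesion denominators (also reported in the literature)
  would read ~10–15 points higher at the same truth.
* The permutation association test assumes within-patient exchangeability
  of lesions under the null; ordered or size-stratified lesions would
  violate it.
* The synthetic affinity oracle's binder rate (~10%) is a convention;
  absolute binder counts are not comparable to any real predictor.
* Single-lesion RECIST classes are not RECIST 1.1 sums-of-diameters calls.
* With 32 gray levels and 64×64 patches the GLCM entropy of near-noise
  images saturates; texture contrasts between very complex lesions compress.
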