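# Methods

## Data model

All statistics operate on a `GenotypeMatrix`: individuals × SNPs counts of
`allele1` copies (0/1/2, −1 missing), with SNP records sorted by
(chromosome, 1-based position). Pseudo-haploid individuals — one sequencing
read allele sampled per site and treated as homozygous — are encoded 0/2
and contribute a single allele to every frequency; male X genotypes are
hemizygous with the same encoding. Windows and jackknife blocks are
half-open physical intervals `[start, end)`. Only the text EIGENSTRAT
dialect is read and written (transparent, diffable; no packed formats).
X SNPs may carry a user-supplied pseudoautosomal-region mask; masked sites
are excluded from every X analysis. PAR coordinates are deliberately not
hard-coded — they depend on the reference build and must be supplied.

## f-statistics and the block jackknife

f3, D and f4 are computed from population allele frequencies as ratios of
per-SNP sums. By default each statistic uses every SNP at which all of its
populations have data ("allsnps" behavior, appropriate for low-coverage
data where a global intersection would discard most sites); a
strict-intersection mode exists for comparison. Standard errors use the
weighted delete-one-block jackknife with unequal block sizes m_j: with
h_j = n/m_j and pseudovalues τ_j = h_jθ̂ − (h_j−1)θ̂_{−j},
SE² = (1/g) Σ_j (τ_j − τ̄)²/(h_j − 1). Blocks are contiguous 5-Mb physical
intervals per chromosome; the length is configurable and recorded in
output, since jackknife SEs are only comparable under a stated block
scheme. With one value per block this reduces exactly to the classical SE
of a mean, which the tests assert to 1e-10.

Outgroup-f3 dissimilarities between individuals (each treated as a
population of one) are reported as (1 − f3) with per-pair usable-SNP
counts; pairs under 2000 overlapping SNPs are masked. No small-sample
heterozygosity correction is applied by default: for pseudo-haploid data
the comparability of pairs matters more than the absolute scale, and the
correction would require within-individual heterozygosity that a single
sampled allele cannot estimate.

Benjamini–Hochberg adjustment is delegated to statsmodels and checked
against a from-scratch step-up oracle in the tests.

## Admixture-weight estimation

With a base reference r0 and further references r1..rJ, each left
population l has the profile row(l)_j = f4(l, r0; r_j, r0). f4 linearity
makes the mixture constraint basis-independent: if the target is a mixture
with weights summing to one, row(target) = Σ wᵢ row(sourceᵢ) regardless of
r0. Weights minimize the GLS quadratic form of the residual under the
block-jackknife covariance of the residual vector; because the covariance
depends on the weights, the solve is iterated three times from an
ordinary-least-squares start (convergence is immediate in practice). The
minimized form is the model chi-square with dof = J − (k − 1) for k
sources; weight SEs come from refitting on each leave-one-block-out basis.
The covariance is ridge-regularized (1e-10 × trace on the diagonal) only if
its condition number exceeds 1e12, with a logged warning.

The dof convention and the whole machinery are validated behaviorally
rather than against another implementation: on synthetic mixtures the
chi-square p-value is uniform under the correct model (KS test), each
weight covers its truth within 3 SE in ≈98% of replicates, and a model
missing a 30% ancestry component is rejected essentially always at 50k
SNPs. Reference sets must be *differentially* related to the sources —
the `admixture_study_specs` design pairs each source with a sister
reference sharing an internal branch, which is what makes the weights
identifiable.

## Mismatch-rate kinship

P0 is the fraction of mismatching haploid calls among co-called sites,
computed in 1-Mb windows and combined overlap-weighted. The baseline is
the median genome-wide P0 across pairs (the median pair assumed unrelated),
so samples should be mostly unrelated — with ≤20% related pairs the
baseline shifts θ of unrelated pairs by well under 0.02. θ = 1 − normalized
P0. The SE of normalized P0 is the overlap-weighted SD of window P0 values
divided by √(number of windows), scaled by 1/baseline; this window-based
estimator is a design choice of this package (stated here because it
determines the |Z| > 2 significance rule).

Degrees are assigned by normalized P0 at the midpoints between expected
values 0.5 (identical), 0.75, 0.875, 0.9375 and 1.0 — cutoffs 0.625,
0.8125, 0.90625 and 0.96875. The third-degree bin extends the classical
three-bin scheme; it is the hardest class (expected separation from
"unrelated" is only 1/16) and correspondingly validated to a lower
accuracy target (≥80% vs ≥95% at 10k overlapping SNPs). Pairs with
≤2000 autosomal (≤200 X) overlapping SNPs are reported as
insufficient-data, and any pair whose normalized P0 is within 2 SE of 1 is
demoted to unrelated.

Identical pairs (normalized P0 near 0.5: same individual or identical
twins) are detected and merged: call vectors are unioned, co-called
conflicting sites become missing (conservative; preserves pseudo-haploid
semantics), and the conflict rate is reported — for true duplicates it
approximates half the heterozygosity. Chained identity merges the whole
connected component with a warning.

On the X the same pipeline runs with the 200-SNP threshold. A pair whose
θ_X exceeds θ_auto by more than 2 combined SEs is flagged as a
paternal-side relationship (for pairs where that is informative), the
reverse as maternal-side; combined SEs above 0.125 — too wide to separate
adjacent degrees — yield "inconclusive".

## Pedigree kinship and hypothesis ranking

Autosomal kinship uses the standard recursion φ(a,b) = ½(φ(father_a,b) +
φ(mother_a,b)) on a non-ancestor of b, φ(a,a) = ½(1+f_a), founders
unrelated. The X recursion encodes hemizygosity: for male a, φX(a,b) =
φX(mother_a,b), and male self-kinship is 1 — a convention chosen so that
mother–son and father–daughter both give θ_X = 0.5 and father–son 0
(conventions differ across packages; this one is stated explicitly and
used consistently by the gene-dropping oracle).

`enumerate_hypotheses` generates all sex-resolved variants of the standard
relationship classes: degree 1 (parent, offspring, full sibling), degree 2
(half-sibling, grandparent, avuncular, sibling's child — this package's
choice of classes), degree 3 (exactly great-grandparent, great-aunt/uncle,
half-aunt/uncle and first cousin, each in 4 lineage variants). A
"proband non-ancestral" constraint prunes hypotheses that would place the
proband upstream (e.g. a child who died before reproductive age). Ranking
minimizes the squared standardized distance of (θ_auto, θ_X) to the
observation; the full ranked list is reported, not just the top hypothesis,
since distinct pedigrees can share expected coefficients. An independent
gene-dropping Monte-Carlo oracle (unique founder alleles, per-replicate
transmission, exact averaging over within-replicate draw pairs) verifies
every enumerated hypothesis within 3 Monte-Carlo SEs at 10⁵ replicates.

## Spatial and permutation statistics

Geodesic distances use the haversine formula on a sphere of mean radius
6371.0088 km (an ellipsoidal alternative would differ by <0.5%, immaterial
at the precision of site coordinates). The isolation-by-distance fit is
ordinary least squares of (1 − f3) on km, with the standard caveat that
pairs sharing an individual are not independent — the reported lm-style
p-value is therefore accompanied by permutation-based group tests.
`residuals_by_group` permutes pair-group labels and tests the absolute
median residual, BH-adjusted across groups.

Classical MDS double-centers the squared dissimilarities (B = −½JD²J) and
eigendecomposes; masked low-overlap entries are imputed with the mean
off-diagonal value (with a warning; dropping individuals is the
alternative), axis signs are fixed so the largest-magnitude loading is
positive, and k shrinks to the number of positive eigenvalues if needed.

The coburial and diversity tests permute *individual* labels (building or
site assignments), preserving group sizes and respecting the dependence
among pairs sharing an individual; p-values carry the add-one correction,
so p ≥ 1/(n_perm + 1). The coburial effect size is the raw difference of
mean (1 − f3): between-building minus within-building, close-kin pairs
excluded. Both tests are calibrated: over 500 null datasets the empirical
type-I error at nominal 0.05 lies in [0.03, 0.07].

## Date comparisons

Calibrated-age distributions are consumed as integer year grids (cal BCE)
with probability masses; radiocarbon calibration itself is upstream and out
of scope. For synthetic data, truncated-Gaussian grids built from
(mean, sd) stand in for calibrated curves. Pairwise overlap draws 10,000
ages per individual; "overlap-compatible" means the 2.5–97.5% interval of
the differences contains zero (the rule is stated in output, as other
criteria are conceivable). SPDs sum per-individual mass into 100-year bins
aligned to multiples of the width; mass is conserved exactly.

## The synthetic-data generator

Populations derive from ancestral frequencies (uniform on (0.05, 0.95), so
every SNP is common — mirroring a MAF>10% panel) via Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) drift; admixed populations are exact
frequency mixtures of derived sources, with optional drift on top, which
also enables stepping-stone chains and sister-branch designs. Pedigrees
are gene-dropped per SNP (independent Mendelian transmission, hemizygous X
rules); identical pairs duplicate a diploid genome before independent
observation. The observation layer samples one allele per site, flips it
with the error rate, and drops sites per the individual's callable
fraction.

What it does **not** emulate: linkage (SNPs are independent; positions
exist only to define windows and blocks, so LD-sensitive methods cannot be
validated here), post-mortem damage profiles (the error model is a
symmetric flip), reference bias, and contamination. Passing tests
therefore show that the estimators are correct under their own sampling
assumptions — not that real aDNA artifacts are handled; damage and
contamination handling live upstream of this package.

Default study sizes (20k SNPs for f-statistics worlds, 50k for
admixture-weight recovery, 10k overlapping SNPs for kinship, 3–8k for
permutation studies; 20 chromosomes of 100 Mb) were chosen as the smallest
at which the validated effects are decisively detectable, keeping the full
validation suite runnable on a laptop in minutes.

## Numerical choices and degenerate inputs

- Frequencies clamped to [1e-6, 1−1e-6] after drift.
- A single jackknife block is an error (SE undefined); empty SNP
  intersections raise with the offending statistic named.
- Zero baseline P0, all-missing individuals, degenerate permutation
  groupings (one building, zero within-site pairs) raise or are logged
  rather than silently producing NaNs.
- Ranking ties break lexicographically by hypothesis name; MDS sign fixing
  makes coordinates deterministic.
- R_Y sexing thresholds default to 0.016 (XX) and 0.075 (XY), configurable;
  the verdict uses the 95% CI of R_Y, not the point estimate, producing
  "consistent with XY but not XX"-style intermediate calls at low coverage.

## Known limitations

- The admixture model's absolute p-values depend on the f4 basis and dof
  convention; they are validated by calibration, not by replicating any
  specific external implementation's output.
- Third-degree kinship classification is intrinsically noisy at low
  overlap; treat single-pair third-degree calls as hypotheses to be
  corroborated (e.g. by the X, by archaeological context).
- The IBD regression p-value ignores pair non-independence; use the
  permutation machinery for inference that must be exact.
- Outgroup-f3 distances respond to shared drift only: a population's
  private drift (small Ne) does not increase its (1 − f3) to others —
  deep-lineage outliers are detectable, recently bottlenecked ones are
  not. The within-site diversity test, by contrast, does detect private
  drift as reduced within-group (1 − f3).
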