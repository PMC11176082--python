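# Methods

This note documents the models and numerical conventions behind each
stage, the design choices made where several defensible options existed,
and what the synthetic-data experiments do and do not demonstrate.

## Expression quantification

TPM is computed per isolate as `1e6 * (count/length) / Σ(count/length)`;
all-zero libraries stay all-zero and are logged. The low-expression
filter removes reference genes with log2(TPM+1) < 1 in at least half of
the isolates; accessory features carrying a homolog link have their
abundance added to the homolog row and are dropped. Because TPM column
sums are not preserved under row subsetting, columns are renormalized to
1e6 after filtering/merging; the operation is idempotent (renormalization
only raises values, so no retained gene can newly fail the filter).
Homolog chains and cycles are rejected rather than resolved.

## Variance-stabilizing transform

Counts are normalized by median-of-ratios size factors, a per-gene
method-of-moments dispersion `α = (s² − μ)/μ²` is computed on normalized
counts, and a two-parameter trend `α(μ) = a0 + a1/μ` is fitted by least
squares with positivity clamps (a0 ≥ 1e-4, a1 ≥ 0). The transform is the
closed-form asymptotic stabilizer of the negative binomial under that
trend,

    vst(x) = log2( (1 + a1 + 2 a0 x + 2 sqrt(a0 x (1 + a1 + a0 x))) / (4 a0) ),

which is strictly increasing in x. The functional form was chosen for
determinism and speed; the contract the pipeline relies on — and the
tests assert — is that across mean-expression deciles of NB-simulated
data the transformed variance varies by less than 2x (raw counts vary by
orders of magnitude). Genes with a zero count in more than half the
samples are excluded first, which removes most accessory genes and is
consistent with treating their zeros as structural.

## Presence-aware abundance and dispersion

Abundance is the mean log2(TPM+1) over carrier isolates only; dispersion
is the mean absolute deviation over the same carriers, `(1/n) Σ|x_i − x̄|`,
preferred over the standard deviation for outlier robustness. Genes with
fewer than two carriers, or expressed in no carrier, are excluded. For
group contrasts the default test is the two-sided Mann–Whitney rank-sum:
the groups (core vs accessory genes) are unpaired and of unequal size,
for which the signed-rank statistic is not defined; a `test="signed-rank"`
switch exists for equal-size paired comparisons.

## Coexpression network and modules

Edges join gene pairs with |Pearson r| ≥ 0.67 on variance-stabilized
expression; nodes with degree < 5 are deleted — all current offenders at
once, recomputing degrees until a fixed point, which makes the result
independent of deletion order. The signed adjacency `((1+r)/2)^5`
downweights negative pairs even though the edge threshold is two-sided.
TOM similarity uses the standard shared-neighbour formula with unit
diagonal; dissimilarity is `1 − TOM`.

Modules come from average-linkage hierarchical clustering of TOM
dissimilarity. The cut is a light dynamic variant of a static height
cut at 0.95: a merge also splits when its height exceeds the internal
merge heights of its children by more than `split_gap` (default 0.15),
the signature of two tight branches joined just below the cut. The cut
may over-split; near-collinear pre-modules are re-fused by the eigengene
merge step (greedy, while the closest eigengene pair has correlation
dissimilarity < 0.2), so the two stages are deliberately complementary.
Eigengenes are unit-norm first principal components of the module's
gene-standardized expression, sign-oriented so that the mean
gene–eigengene correlation is non-negative; ties in average linkage are
resolved by scipy's deterministic ordering, and merges keep the smaller
module id. Clusters below `min_cluster_size` (5) leave their genes
unassigned.

## Differential expression and the cutoff sweep

Each clade is compared against all remaining isolates with a per-gene
negative-binomial log-linear model: offset log size factor, intercept,
mating-type covariate (haploid MATa / MATalpha, diploids as a third
level rather than dropped) and the clade indicator; Wald test on the
clade coefficient, BH adjustment within the clade. Dispersion is
per-gene method-of-moments with a floor of 1e-8 and no shrinkage — the
acceptance surface here is recovery of planted effects, not parity with
any particular DE engine, and at the simulated depths moment estimates
are adequate. A clade perfectly confounded with mating type produces a
singular design and is rejected explicitly.

Because larger clades reach significance at smaller effects, hit counts
correlate with clade size under an FDR-only rule. The sweep raises the
|log2FC| cutoff over a 0–1 grid in steps of 0.05 and chooses the
smallest cutoff at which the Spearman correlation between per-clade hit
counts and clade sizes is no longer significant (p ≥ 0.05); an undefined
correlation (all counts equal, all sizes equal) counts as independence
achieved. Spearman was chosen over Pearson for robustness to clade-size
outliers, and the p ≥ 0.05 rule is an explicit convention — a judgement
the original procedure leaves to inspection. Final hits require
|log2FC| strictly greater than the cutoff and adjusted p < 0.05; hits
overlapping the coexpression node set are flagged and left out of the
exported differential-expression gene set.

## Preranked GSEA

The enrichment score is the maximum deviation of the weighted
running-sum statistic (hit increments ∝ |score|^w, w = 1 by default).
The null draws random same-size gene subsets; the p-value compares the
observed ES against null scores of the same sign with a +1 pseudocount,
`p = (1 + #{null same sign, |null| ≥ |ES|}) / (1 + #{null same sign})`,
and NES divides ES by the mean |null ES| of that sign. The same-sign
convention (rather than doubling a one-sided p) is what makes null
p-values uniform, which the calibration test asserts by KS test. Sets
outside the size limits after intersection with the ranking universe are
skipped and reported. Gene-label permutation matches the preranked use
case; sample permutation is out of scope.

## Allele-specific expression

AAR is the exact ratio alt/(ref+alt); sites with AAR of exactly 0 or 1
lack expressed heterozygosity and are excluded. The filter chain applies,
in order: mappability flag, AAR support, coverage strictly greater
than 29, coding-sequence membership (strandless), and — when enabled —
genetic allele balance within [0.33, 0.66] inclusive, which removes
copy-number-distorted sites. The imbalance test is an exact two-sided
binomial by the minimum-likelihood convention (sum of outcome
probabilities no larger than the observed outcome's), vectorized with a
per-coverage pmf cache. The null probability defaults to the unweighted
mean AAR over all retained sites pooled across isolates — a choice
documented and switchable (`p0=0.5` restores the naive null); weighting
isolates equally would need a convention the data do not dictate. An
`ab_filtration_sweep` diagnostic reproduces the exploratory symmetric-AB
filtration; the pipeline default applies the final window directly.

## eQTL mapping

Kinship is `Z'Z/m` over column-standardized SNP dosages. Each trait
(TPM scale, untransformed) is fitted once under the null mixed model via
the spectral decomposition of K, maximizing the ML likelihood of the
variance ratio δ = σe²/σg² over a 61-point log grid (10⁻⁵–10⁵); every
variant is then a weighted regression in the rotated space, Wald-tested
with t(n−2). Small-instance tests pin this against a naive GLS oracle
with full covariance inversion (agreement to 1e-6) and the K = I limit
against OLS. Effect size is |β̂| on standardized dosage; variance
explained is β̂²/var(y), clipped to [0, 1].

Permutation thresholds permute phenotype values between isolates,
re-estimate δ per permutation, record the genome-wide minimum p, and
take the 5% order statistic (the fifth-lowest of 100). SNP and CNV
matrices get separate permutation runs, which is how threshold scaling
to matrix size is realized. The per-permutation statistic is the
minimum p (rather than a quantile of the full p distribution) — the
reading most consistent with a fifth-lowest-of-100 rule. Genomic
control deflates the observed χ² by λ when λ > 1, before thresholding;
permutation minima are left uncorrected. A secondary, cross-trait BH
adjustment of each trait's best-hit empirical permutation p is reported
alongside (`trait_padj`), with the per-trait threshold as the primary
gate.

Linkage groups are connected components of the R² > 0.6 graph among a
trait's significant variants — transitive closure, since pairwise-only
grouping is not well defined — represented by the minimum-p member
(ties: smaller position, then identifier). SNP eQTLs are local within
25 kb of the nearest gene boundary (0 inside the gene); CNV eQTLs are
local only when variant and trait share the ORF. Because the local
percentage can be read over SNP eQTLs only or over the whole catalog,
the catalog summary reports the SNP-based percentage and all the raw
counts needed for either reading.

## Synthetic data

The generator emulates: 200 isolates in 5 clades of unequal size
(realistic for a domesticated/wild population structure); 400 core and
100 accessory genes on 4 chromosomes with 1-based inclusive intervals
(a single linear coordinate system makes the 25-kb window unambiguous);
accessory presence Bernoulli per gene x clade with a boosted home clade,
absences becoming structural zeros; SNPs from a Balding–Nichols model
(F = 0.1) with every empirical MAF forced into the configured range by
rejection (with a constructive fallback), giving the kinship matrix real
block structure; CNVs as copy-number variants tied to an ORF; six
planted 25-gene modules driven by shared latent factors (factor sd 1.0
in log2 units, chosen to give within-module |r| ≈ 0.8 after counting
noise); per-clade DE effects of |log2FC| = 1; mating-type effects on
haploid MATa isolates; 20 local + 20 distant eQTLs with per-allele
effects of 0.75–1.25 log2 units; negative-binomial counts (dispersion
0.05 — the real dispersion magnitudes are not published, so this is a
testability choice) with log-normal library size factors (sd 0.3) so
size-factor estimation is non-trivial; and aneuploid isolates whose
extra-chromosome log2 ratio is scaled by (1 − dosage_compensation).
Planted effect classes are placed on disjoint pools of core genes so
each is recoverable without interference.

The ASE generator draws Poisson coverage (mean 60) and binomial alt
counts at probability 0.5 − bias (default bias 0.02) for null sites,
with optional planted imbalanced sites; genetic AB and mappability flags
are attached per site.

What the generator does not emulate: linkage-disequilibrium decay along
chromosomes (planted variants are linked only through clade structure),
sequence-level reads, GC or length biases, batch effects, and the
dependence structure of real pan-genome presence (one home clade per
gene is a simplification). Recovery results on synthetic data therefore
demonstrate the correctness and calibration of the statistics, not
field performance on real panels.

## Dosage response

For each (isolate, chromosome) pair whose copy number differs from base
ploidy, the observed ratio is the median over that chromosome's genes of
linear-scale expression relative to the per-gene median over euploid
isolates. TPM is compositional — an amplified chromosome dilutes every
other gene — so ratios are first renormalized by the isolate's median
ratio over its euploid chromosomes. Attenuation is
`(expected − observed)/(expected − 1)`; the statistic itself is a
convention of this package (the qualitative observation it quantifies is
not accompanied by a published formula). Note the generator scales the
*log* ratio while attenuation is defined on the linear ratio, so at
intermediate compensation the recovered attenuation is slightly above
the planted parameter (≈ 0.55 at 0.5); the two agree at the endpoints
and within the ±0.1 tolerance the tests use.

## Problem sizes

The validation experiments run at desk scale by design: 200 isolates,
500 genes and 330 variants per simulated dataset; 10 seeds for module
recovery; 3–10 seeds for eQTL recovery (each trait scanned with 100
permutation rounds); 200 null traits for the family-wise error check;
10,000 sites for ASE calibration; 500 sets x 500 permutations for GSEA
calibration. The accounting examples construct catalogs at the full
scale of a species-wide panel (6,680 gene rows; 9,470 eQTL records)
since they are pure arithmetic.

## Known limitations

- The NB dispersion trend is a global two-parameter fit; genes with
  strongly atypical dispersion are stabilized imperfectly.
- The DE engine refits a GLM per gene without dispersion shrinkage;
  at very low counts its moment estimates are noisy.
- The LMM estimates δ on a fixed grid; p-values are insensitive to grid
  resolution at the tested scales, and the GLS oracle tests use the
  fitted δ, so grid coarseness is not hidden by the tests.
- `conflate_linkage_groups` computes R² within a trait's significant
  set only; genome-wide LD pruning is out of scope.
- CLI subcommands cover the pipeline stages; sample-identity validation
  and dosage response are library-only (they need in-memory panels and
  karyotypes rather than single files).
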