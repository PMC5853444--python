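# Methods

This note documents the statistical choices behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Genotype handling

Genotypes are diploid biallelic dosages (0/1/2 alternate-allele copies,
−1 missing) with SNPs sorted by (chromosome, position). All internal
coordinates are 0-based half-open; VCF and GFF3, which are 1-based, are
converted at the I/O boundary so that window and overlap arithmetic is
unambiguous.

Allele frequencies are always computed over non-missing calls only
(complete-observation frequencies); no imputation is performed anywhere
except inside PCA/kinship/GWAS decompositions, where missing dosages are
set to the SNP mean for the linear algebra only. The minor-allele-frequency
filter is strict (`MAF > threshold`): a SNP at exactly the threshold is
removed. "Informative" SNPs are those passing the call-rate threshold
(default 0.8) and polymorphic over called genotypes; the call-rate default
is a conventional array-QC value, and both thresholds are configurable.
Group labels are matched case-insensitively against the three canonical
ecotype names (winter, spring, semi_winter); anything else is an error
rather than a silent fourth group.

## Windowed statistics

Windows are 100 kb sliding every 10 kb by default. Starts run 0, 10 kb,
20 kb, … while inside the chromosome and trailing windows are truncated at
the chromosome end, so the union of windows tiles each chromosome exactly
and every position lies in at most size/step windows.

**π.** Array panels carry no invariant sites, so per-bp diversity would be
an artifact of probe spacing. π is therefore reported per window as the
*mean per-SNP* unbiased site diversity `π_site = n/(n−1) · 2p(1−p)` (the
average pairwise difference among the n called alleles), with the summed
site π kept alongside because Tajima's D is defined on the windowed sum.

**Tajima's D.** The standard constants chain (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
e₂) with `D = (π_sum − S/a₁) / sqrt(e₁S + e₂S(S−1))`. The number of
sequences is 2 × the number of group samples with at least one non-missing
call in the window, while each site keeps its own allele total for π; this
is the simplest defensible treatment of missingness for a window statistic.
D is undefined (NaN) when S = 0 or fewer than 4 sequences are present.

**FST.** Two-population Weir–Cockerham (1984) moments estimator in the
allele-count ("random union of gametes") form: within groups
Hardy–Weinberg proportions are assumed, the 2N called alleles are the
sample, and no observed-heterozygote term enters. Per window the variance
components are combined as a ratio of sums across SNPs — the standard
multi-locus estimator, less noisy than averaging per-site ratios. Sites
where both groups are monomorphic for the same allele contribute zero to
both sums. The genotypic (heterozygote-aware) form would be a drop-in
replacement; the count form was chosen because array AB calls are
consistent with HWE sampling in these panels and the count form has a
closed-form simulation oracle.

**Missing-window rule.** A window with fewer than `min_snps` (default 3)
informative SNPs on either side of a contrast yields NaN statistics rather
than zeros, and a π ratio with a zero denominator is NaN (never ∞); NaN
windows are excluded from empirical tails.

## Sweep calling

Thresholds are nearest-rank empirical percentiles of the non-missing
windows: the 5% left and right tails of the π-ratio distribution and the
top 5% of FST, with values exactly at a threshold included in the tail. A
window is a sweep call only when it passes the FST tail *and* a π-ratio
tail; with ratio π_A/π_B, the left tail attributes the sweep to A (the
numerator group lost diversity), the right tail to B. Because thresholds
are rank-based, calls are invariant under any monotone rescaling of either
statistic. Same-label windows that overlap or are bookended merge into
regions (regions are unions of stepped windows, so adjacency is expected);
region FST is the member maximum and the reported π ratio is the most
extreme in the label's direction.

The permutation test pools the individuals of the two contrast sides,
reassigns them at random preserving side sizes, and recomputes every window
FST exactly from the permuted allele counts (no approximation). The
p-value uses the add-one estimator `(1 + #{perm ≥ obs}) / (n_perm + 1)` to
avoid zeros, and FDR is Benjamini–Hochberg — chosen as the default
interpretation where only "FDR" is specified. With genuinely differentiated
groups this test rejects essentially everywhere (permutation destroys all
structure, not just local sweeps); it is a structure diagnostic, and its
error control is verified on an exchangeable null (a single pool split into
labels at random), where the type-I rate at p < 0.05 sits in [0.03, 0.07]
and windows at q < 0.01 stay under 1%.

## LD structure

r² on unphased diploids is the composite (Rogers–Huff) estimate: the
squared Pearson correlation of dosage vectors over samples called at both
SNPs. It is deterministic, phasing-free, and converges to the haplotype r²
under HWE; an EM haplotype-frequency mode (`r2_em`) is provided for
cross-checks. Decay curves bin all intra-chromosomal pairs up to a maximum
distance (default 5 Mb, 50 kb bins); the half-decay distance is located on
a decreasing isotonic-regression smoothing of the binned means (weighting
by pair counts) to avoid bin-noise artifacts, and is NaN when the curve
never falls to half its maximum — which genuinely happens both for
independent SNPs (flat at the ~1/n sampling floor) and for pooled
structured panels, where admixture LD between unlinked loci raises the
baseline. Decay is therefore best measured within one group.

Weak/strong LD regions use *non-overlapping* 10 kb windows scored by the
mean r² of adjacent SNP pairs fully inside the window; windows with fewer
than two SNPs (or no scoreable pair) are unclassified. The bottom and top
5% genome-wide (nearest-rank, ties inclusive) are weak and strong
respectively; the two tails are disjoint by construction. Homoeology
joining counts (A-region, C-region) pairs of the same class whose members
overlap a mapped interval pair by ≥ 1 bp, deduplicated across mappings.

## Population structure

PCA runs on mean-centered (optionally standardized) dosages with
missing values mean-imputed for the decomposition only; scores are the
projections onto the top eigenvectors of the sample covariance. The
genetic distance is 1 − IBS proportion (per-SNP similarity
`1 − |x_i − x_j|/2`). The NJ tree is the standard Saitou–Nei agglomeration
with deterministic lowest-index tie-breaking; negative branch lengths are
clamped to zero with the deficit moved to the sister branch, standard
practice that preserves path lengths. Kinship is VanRaden method 1,
`K = ZZᵀ / (2Σp(1−p))` on centered dosages — chosen as the most common
kinship for mixed-model GWAS when the estimator is otherwise unspecified.

## BLUP and GWAS

The multi-year trait is condensed by `y_ij = µ + year_i + g_j + e_ij` with
year fixed and genotype random, variance components by REML (statsmodels
MixedLM); the reported value is µ̂ + ĝ_j, i.e. a shrinkage estimate of each
accession's year-adjusted mean. Treating year as fixed and genotype as
random is the conventional choice for few years and many genotypes; the
model is recorded here because the roles are genuinely open.

The association model is `y = Xα + Pβ + u + e` with `u ~ N(0, σ_g²K)`.
Variance components are estimated once on the null model via the spectral
decomposition of K (profile REML over δ = σ_e²/σ_g², grid-then-Brent on
log₁₀δ), and each SNP is then tested by generalized least squares with a
Wald t-test — the P3D/EMMAX approximation, which matches the behavior
class of the standard MLM tools and makes a 33k-SNP scan instantaneous.
With K = I and no PCs this reduces exactly to OLS (verified to 1e-8).
Three PCs are included by default (configurable); PVE is reported as
`2p(1−p)β̂² / var(y)` since no canonical definition exists. The
genome-wide threshold is 1/M. Candidate regions extend from each peak SNP
while r² with the peak stays ≥ 0.5, capped at ±200 kb, then merge.
Haplotype classes are joint genotype combinations over the block SNPs
(statistical phasing is out of scope), compared by Kruskal–Wallis across
classes with n ≥ 5.

## Synthetic data

The generator emulates the statistical structure of an array-genotyped
rapeseed diversity panel; its defaults are the study-scale conditions:
three groups of 196/71/60 accessions, 19 chromosomes (A01–A10 ≈ 25 Mb at
8 SNPs/100 kb; C01–C09 ≈ 40 Mb at 4 SNPs/100 kb, ~33 000 SNPs total),
group differentiation at Balding–Nichols F = 0.15, and a flowering-time
phenotype (µ = 155 d; group offsets +25/0/−20 d for winter/semi-winter/
spring; four years of ±5 d effects; residual SD 8 d; five causal SNPs of
4–8 d) spanning roughly 107–204 d.

- **Differentiation**: ancestral `p ~ U(0.05, 0.95)`, group frequency
  `~ Beta(p(1−F)/F, (1−p)(1−F)/F)`. The configured F is the expected FST —
  an analytic oracle for the estimator (recovered within ±0.02 at 5 000
  SNPs under linkage-free sampling).
- **LD**: within blocks of `block_len` bp each group has K_h founder
  haplotypes drawn from its frequencies; individuals sample two founders
  per block, so adjacent-pair r² scales like 1/K_h, blocks recombine
  freely, and subgenome LD contrasts are planted by varying K_h and
  block_len (A: many founders/short blocks; C: few founders/long blocks).
  `founders=0` requests direct HWE draws (no LD) for calibration
  scenarios. Note that per-group founder draws add block-level drift of
  order 1/K_h on top of F; a panel that must be exchangeable under label
  permutation should therefore be built as a single pool and split with
  `split_pool`, not as multiple groups with small F.
- **Sweeps**: inside a sweep interval the target group's frequencies are
  pinned to δ or 1−δ (nearer), collapsing local diversity to
  ≤ 2δ(1−δ)·n/(n−1) while leaving the other groups untouched — a
  recoverable truth for the tail-intersection caller.
- **Phenotype**: additive causal effects plus group, year and normal
  residual terms, written per sample per year.

Everything is reproducible bit-exactly from one seed (stage RNGs are
spawned from it). What the generator does **not** emulate: realistic
demography or admixture tracts, recombination maps (LD is blockwise, not
distance-continuous), genotyping error, ascertainment bias of array
probes, or homoeologous exchange at sequence level. Passing tests
demonstrate estimator correctness and calibrated error control under this
model, not performance on real array data, where estimator choices by
external tools, missingness patterns and ascertainment will shift absolute
counts.

## Validation scales and numerical choices

The acceptance checks run at desk scale on one CPU: FST calibration on
2 × 100 samples × 5 000 SNPs; sweep recovery on ten 100 kb sweeps
(δ = 0.02) in 20 Mb / 10 000 SNPs / 2 000 windows with 500 permutations;
LD asymmetry on 9 chromosomes × 1 000 SNPs; GWAS power on 20 seeds of
n = 300 × M = 5 000; NJ on 50 random additive trees (n ≤ 8). These sizes
were chosen as the smallest at which the binomial/permutation noise is
comfortably inside the asserted bands.

Ties in empirical thresholds are included in the tail (nearest-rank);
permutation p-values use the add-one estimator; BH handles the FDR;
negative NJ branches are clamped with length transfer; exact-fit GWAS
regressions keep a finite t by flooring the residual sum of squares;
degenerate inputs (monomorphic SNPs, S = 0 windows, empty contrasts,
< 3 taxa, single-year phenotypes) raise or return NaN per the contracts
above rather than fabricating values.

## Known limitations

- FST is implemented for two-sided contrasts (possibly pooled groups), not
  the general r-population estimator.
- The permutation test permutes individuals; family structure within
  groups is not preserved under permutation.
- The EM r² mode assumes HWE and ignores inbreeding; the composite r² is
  the supported default.
- BLUP assumes independent genotype effects (no kinship in the two-stage
  phenotype model); the kinship correction enters at the GWAS stage.
- Haplotype classes are genotype combinations, not phased haplotypes.
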