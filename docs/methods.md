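# Methods

Statistical models, parameter defaults and numerical choices, stage by
stage. Defaults live in the code next to the functions they control
(`FILTER_DEFAULTS`, `CNV_DEFAULTS`, `SimConfig`, `RunConfig`) and every one
is overridable.

## Reflectance colour metrics (`spectra`)

A spectrum is reflectance (%) on a strictly increasing wavelength grid.
Replicates of one sample are averaged after linear resampling to a common
1-nm grid on the intersection of their ranges.

- **Hue λR50**: restrict to 450–700 nm; find the long-wavelength maximum
  (first index on ties), the minimum to its left, and the first upward
  crossing of the halfway reflectance, linearly interpolated. Flat spectra
  (max = min) raise `UndefinedMetricError` rather than returning a number.
- **Mean brightness**: mean reflectance over 400–700 nm.
- **Carotenoid chroma**: (R700 − R450)/R700 — the fraction of
  long-wavelength reflectance absorbed in the carotenoid absorbance region.
- Group summaries report mean ± t-based 95% CI; groups of size 1 get NaN
  CIs instead of a fabricated interval.

## Pigment chemistry (`pigments`)

Each pigment carries three structural counts in {0, 1, 2}: C4(4′)-keto
groups, C3(3′)-oxygenations, ε-end rings, plus an origin class
(`dietary_yellow`, `metabolised_yellow`, `metabolised_red`). The shipped
table (`flameback/data/pigment_table.csv`) covers 13 common avian
carotenoids and is plain CSV so users can extend it; Greek letters and
prime marks in names are normalised on lookup (β-cryptoxanthin ≡
beta-cryptoxanthin).

The per-sample statistic is the concentration-weighted mean
ā = Σ aᵢCᵢ / Σ Cᵢ. It is scale-invariant in the concentrations and bounded
by the min/max count present — both properties are tested. Total carotenoid
content from absorbance uses Beer–Lambert bookkeeping:
(A·10⁴/E) · V / mass.

## LAB phenotype score (`colour_score`)

PCA of (L, a, b) triplets via eigendecomposition of the covariance matrix
(correlation optional). The scoring axis is the component, among those
explaining ≥ 5% of variance, that maximises |loading(a) − loading(b)| —
the red–yellow contrast — and is oriented so larger scores are redder
(positive correlation with a). Scores are centred. Eigenvector sign is
fixed deterministically (largest-magnitude loading positive) so runs are
reproducible.

## Permutation inference (`stats`)

Fisher–Pitman permutation tests: statistic is |mean difference| for two
groups and the between-group sum of squares Σ nⱼ(x̄ⱼ − x̄)² for k ≥ 3.
When the number of distinct relabellings is ≤ 200,000 the null is
enumerated exactly; otherwise seeded Monte Carlo with the add-one estimator
p = (1 + #exceedances)/(1 + R), which never returns 0 and is valid for any
R. Default R = 100,000. Pairwise post-hoc tests get independent child seeds
from one `SeedSequence` and Benjamini–Hochberg adjustment across pairs.
BH-FDR is delegated to `statsmodels` behind input validation. Spearman
correlation uses midranks (tie-correct) with either a permutation p or a
t approximation, flagged as such in the result.

## SNP handling and GWAS (`assoc`)

Filter order is fixed and counted per rule: (1) keep biallelic SNPs;
(2) mask genotypes with DP < 3 or GQ < 25; (3) drop sites with minor allele
count < 3 among unmasked genotypes; (4) drop sites with > 60% missing.
Missing genotypes are then mean-imputed (per phenotypic group by default,
falling back to the global mean where a group is entirely missing),
yielding fractional expected dosages. Mean imputation is deliberate: with
reduced-representation marker densities there is too little linkage
information for LD-based imputation, and the mixed model consumes expected
dosages naturally.

Kinship is the centred product K = XcXcᵀ/p (row sums zero, PSD). The LMM
y = Wα + xβ + u + ε profiles λ = σ²g/σ²e by maximum likelihood on a log₁₀
grid over [−5, 5] (50 points) with Brent refinement, after a single
eigendecomposition of K; by default λ is re-profiled per site (a null-only
fit is available for speed). The Wald statistic (β/se)² with σ² = RSS/(n−2)
is referred to χ²₁. With K = I the weights cancel and the result equals OLS
exactly — an identity the tests exploit as an oracle. FDR-adjusted p-values
and a Manhattan-ready table (significant ⇔ adjusted p ≤ α, boundary
inclusive) are emitted; the significant set is exactly `bh_fdr` applied to
the Wald p-vector, with no hidden re-thresholding.

**Known limitation — discrete stratification.** When the phenotype is
perfectly aligned with discrete group membership and the genotypes carry
group structure, a single-random-effect LMM removes most but not all
stratification signal: at realistic sizes (n ≈ 60–106, F_ST ≈ 0.05) about
40% of zero-effect replicates show one borderline FDR hit. The null-model
acceptance test therefore uses structure-free genotypes to isolate the
association machinery, and results on structured data should be read with
this residual inflation in mind.

## Windowed F_ST (`assoc`)

Hudson's estimator with sample-size-corrected numerator per site:
num = (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1), den = p₁q₂ + p₂q₁, combined as
a ratio of averages within windows (Weir–Cockerham is available by flag).
Fractional imputed dosages contribute fractionally to allele counts.
Windows advance over *sequenced* base pairs — chunks of N covered
positions — by default, matching reduced-representation data where genomic
bins would be mostly empty; fixed genomic bins are available by flag.
Windows with non-positive summed denominators are omitted.

Finite-sample note: the corrected estimator gives exactly −1/(n_alleles−1)
for populations with identical genotype columns (not 0); the bias is O(1/n)
and the tests assert the exact value rather than pretending it vanishes.
`genome_coverage_percent` provides the covered-fraction bookkeeping that
contextualises sequenced-bp windows.

## Duplication screen (`cnv`)

depth_ratio = site DP / individual genome-wide mean DP (over genotyped
sites). Verdicts per genotype: `high_copy` (ratio ≥ 10), `duplication_
consistent` (ratio ≥ 2 at a heterozygous call with alt-read fraction in
[0.15, 0.35] ∪ [0.65, 0.85] — the 3:1 band expected when a duplicated copy
collapses onto one reference position — and ≥ 8 informative reads),
`elevated_depth`, `normal`. The site report gives per-group verdict
fractions and marks sites whose flags all fall in one group. No GC-content
or fragment-length amplification-bias correction is attempted; the report
carries a note saying so.

## Synthetic study generator (`synthetic_data`)

The generator's defaults are the study conditions, not tuned quantities:
45 red / 25 orange / 36 yellow birds; hue targets 602 / 575 / 546 nm;
2,000 SNPs on 5 chromosomes; background F_ST 0.05; one causal locus
(effect 0.5) and one red-restricted duplication (3× depth).

- Pigment profiles are log-normal (σ = 0.3) around group-specific mixtures
  (red: astaxanthin-dominant; yellow: lutein/3′-dehydro-lutein with
  ε-ringed metabolites; orange: an intermediate blend).
- Reflectance is a logistic curve whose midpoint comes from a
  piecewise-linear monotone map anchored at (group mean keto statistic,
  group hue target), so hue tracks chemistry by construction and group
  means hit the targets.
- LAB: a follows the keto statistic, b the yellow-pigment share.
- Genotypes are Balding–Nichols: red and yellow frequencies drawn
  independently around a uniform ancestral frequency with drift
  F = background F_ST; orange is the admixed average. Causal loci
  optionally get a strong red/yellow frequency gap (`causal_divergent`);
  the phenotype is Σβ·z + a polygenic term (h² = 0.3) + noise. Duplication
  loci are forced heterozygous in the target group with multiplied Poisson
  depth and Binomial(DP, 0.25) alt reads. DP ~ Poisson(20), GQ ~ U{30..60},
  5% missingness.
- Determinism: every stage draws from
  `SeedSequence(entropy=seed, spawn_key=(crc32(stage),))`, so one integer
  seed reproduces every file byte-for-byte and stages are independently
  reproducible. (`crc32`, unlike Python's `hash`, is stable across
  processes.)

Scope limits: no linkage disequilibrium within chromosomes, no
genotype-calling error model beyond missingness, no spatial cline — groups
are exchangeable units, which is exactly what the permutation tests assume.

## Pipeline and sizes (`pipeline`, `cli`)

`run_all` chains simulate → colour metrics (+ hue permutation test) →
functional groups (+ omnibus, post-hoc, hue correlations) → phenotype score
→ filter/impute/kinship/LMM/FDR → red-vs-yellow windowed F_ST → CNV screen,
writing one artifact per stage plus `report.json`. Each stage logs its
parameters, seed, and SHA-256 input hashes. Stage seeds come from the same
crc32 spawning policy as the generator.

Problem sizes in the test-suite are the package's own scaling choices made
for runtime budgets: power simulations use n = 150 / 2,000 SNPs / 20
replicates; null-pipeline replicates use n = 60 / 400 SNPs; small unit
fixtures use a 40-sample / 300–500-SNP study. None of the generator
defaults were altered to make tests pass; where an estimator's exact
finite-sample behaviour deviates from the idealised value (the Hudson
−1/(n−1) floor, the Monte Carlo p floor of 1/(R+1)), the tests assert the
exact behaviour.
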