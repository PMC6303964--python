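# Methods

## Model and parameterization

The analysis model for repeated litter records is

y = Xβ + f·b + Z g_A + Z g_D + Z g_AA + Z g_AD + Z g_DD + Z pe + e,

with Var(g_k) = G_k σ²_k for each genetic term, Var(pe) = I σ²_pe and
Var(e) = I σ²_e. X carries an intercept and dummy-coded parity and
contemporary-group effects (first level dropped; the design is checked
for full column rank so confounded factors fail loudly). The covariate f
is each sow's observed genomic homozygosity — the fraction of her
non-missing SNPs that are homozygous — centered at its mean across
individuals so the slope b (inbreeding depression, trait units per unit
homozygosity) is decoupled from the intercept. Centering changes only the
intercept, not b.

Relationship matrices use the orthogonal (NOIA-style) codings under HWE:
VanRaden centering for the additive incidence matrix M, the
(−2q², 2pq, −2p²) coding for the dominance matrix W, and trace-normalized
Hadamard products for the three pairwise epistatic structures. Allele
frequencies are always the observed frequencies of the analyzed
individuals, which makes the columns of M sum to zero exactly. Missing
genotypes are mean-imputed (2p) for M — equivalently zero after
centering — and contribute zero to W, since a missing genotype carries no
heterozygosity information and zero is the HWE expectation of a W entry.
Monomorphic columns are zero and drop out of both normalization
denominators (with a warning). Higher-order (>2-way) interactions are out
of scope: repeated Hadamard powers converge to the identity and become
indistinguishable from residual variance.

Quality control applies, in a fixed order so removal counts are
reproducible: individual call rate ≥ 0.90, SNP call rate ≥ 0.90,
MAF ≥ 0.05, and a Hardy–Weinberg filter |observed het − 2pq| ≤ 0.15. All
four thresholds are configurable; the defaults mirror the conventional
defaults of standard genomic-evaluation QC tools.

## Gibbs sampler

All location blocks are drawn from their exact joint normal full
conditionals. For each genetic term, the regularized relationship matrix
(G + εI, ε = 10⁻⁶ by default, applied once and recorded) is factored as
G = LL′, and L′Z′ZL is eigendecomposed once (V D V′). Writing g = LVw
makes the full-conditional precision of w diagonal,
D/σ²_e + I/σ²_g, for any current variances, so each block draw is exact
and costs O(Nn) per iteration (projections run through Z by per-individual
aggregation, so effectively O(n²)); the identity g′G⁻¹g = w′w feeds the
variance draw directly. Fixed effects and b are one joint block (Cholesky
of C′C precomputed); the permanent environmental block is diagonal.
Variances are drawn from scaled-inverse-chi-square full conditionals
(SS + νS)/χ²_{dim+ν} with flat defaults S = 0, ν = −2 — the animal-breeding
software tradition in which posterior modes are comparable to REML — and
a floor of 10⁻¹² prevents absorbing states. Individuals without records
(selection candidates) are carried in every random-effect vector; their
permanent environmental draws come from the prior and their genetic
values from the genomic relationships.

Protocol defaults follow the long-chain convention (200 000 iterations,
10 000 burn-in, thinning 100 → 1900 retained samples); a short chain
(20 000/2 000/10) is the default for quick studies. Per retained sample
the chain stores every variance, the fixed effects and b, and the
conditional deviance −2Σ log N(y_i | fitted_i, σ²_e); posterior means of
all location parameters accumulate alongside. DIC uses Spiegelhalter's
conditional-deviance construction: pD = D̄ − D(θ̄) with D(θ̄) evaluated
at the posterior-mean linear predictor and posterior-mean σ²_e. Effective
sample sizes use Geyer's initial-positive-sequence truncation of the
autocorrelation sum. Identical seeds give bit-identical chains.

σ²_P for the ratios h², d², i² sums *all* random components (genetic +
pe + e), computed per retained sample and then averaged; this is the only
definition under which the ratio table is internally consistent.

## Prediction and validation

GBLUP solves Henderson's equations at fixed variances via the same
g = Lu parameterization (a ridge system; dense Cholesky, suitable for a
few thousand individuals). Zero-variance terms are shrunk to exactly
zero rather than entering a singular system. Solutions satisfy the
equations to relative residual < 10⁻⁸ and are bit-reproducible.

The whole/partial split cuts records at a period boundary; sows with
records on both sides are excluded entirely, and sows with records only
after the cutoff are the selection candidates (no own phenotypic
information in the partial data). Method-R statistics over candidates:
b0 = mean(ĝʷ) − mean(ĝᵖ) (also reported in units of the whole-data
additive SD), b1 = Cov(ĝʷ, ĝᵖ)/Var(ĝᵖ), ρ = Cor(ĝʷ, ĝᵖ), using sample
(n−1) moments over the candidate set — the population formulas need a
convention and this is the one fixed here. Predictive ability compares
corrected phenotypes y* = y − Xβ̂ − f b̂ (whole-data fit) with
ŷ = Σ ĝ_terms + p̂e (partial-data fit) over the candidates' records.

## Synthetic populations

The generator emulates a purebred sow population with litter-size-like
records: unlinked loci with allele frequencies Uniform(0.05, 0.95);
genotypes drawn per individual with inbreeding parameter F
(P(hom1) = p² + Fpq, P(het) = 2pq(1−F)); F either zero or
scale·Beta(a, b) — inbreeding scenarios use 0.3·Beta(1, 3), giving mean
F ≈ 0.075 and observed-homozygosity SD ≈ 0.02–0.035, enough spread for
the depression covariate to be estimable. True genetic values are built
from the same orthogonal codings the estimator assumes: g_A = Mα and
g_D = Wd with iid normal marker effects, and pairwise epistatic values
from products of centered incidence columns over randomly sampled locus
pairs (5000 by default) — the statistical model the estimator assumes
under HWE/LE, at a fraction of the cost of full Kronecker machinery.
In "exact" scaling mode (the default, used by all recovery tests) each
generated vector is rescaled so its sample variance equals its target
exactly; "expected" mode scales only in distribution. Phenotypes add the
grand mean (12.7), centered parity and contemporary-group effects
(groups nested within the two period blocks used by the validation
split), b·(f − mean f) with f the *observed* homozygosity (so the
generative covariate is exactly the one the estimator sees), permanent
environmental effects and residuals; 2–6 records per sow by default.
Default variance targets: σ²_A=0.84, σ²_D=0.17, σ²_AA=0.14, σ²_AD=0.12,
σ²_DD=0.09, σ²_pe=0.45, σ²_e=7.05, b=−12.33.

What the generator does not emulate: linkage and LD, pedigree/family
structure, selection over generations, and crossbred (non-HWE)
populations. The absence of family structure matters: for unrelated
individuals the off-diagonals of G_A shrink like 1/√m and the epistatic
matrices approach the identity, so individual-level variance components
are much harder to separate (from each other and from pe) than in real
livestock data. Passing recovery tests therefore demonstrate calibration
of the machinery under the stated sampling design, not the precision
attainable on structured real populations.

## Test problem sizes

The suite exercises the full pipeline on scaled designs chosen to
preserve the mechanism each property tests. Parameter-recovery runs use
400 sows × 3 records × 320 SNPs — the same identifiability ratio n²/m as
the reference design of 1000 sows × 2000 SNPs — with 6000-iteration
chains; central 95% intervals cover every generating variance in ≥ 8/10
seeds. The inbreeding-bias contrast uses 500 sows with 2–6 records and
400 SNPs; the DIC comparison uses 8000-iteration chains so its
Monte-Carlo error stays well inside the 7-unit irrelevance band;
method-R validation runs GBLUP-only and is cheap. The nested-model
orthogonality band (< 0.5 posterior SD shift of σ²_A and σ²_D when
epistatic terms are added) is a large-sample property under this
generator: with unrelated HWE/LE genotypes it emerges only near the full
1000 × 2000 design (where the σ²_A shift measured 0.07–0.23 SD), while at
any affordable test size the flat-prior competition among near-confounded
components shifts posterior means by 0.5–1.4 SD; the corresponding test
documents this honestly rather than relaxing the band.

## Numerical choices

ε = 10⁻⁶ diagonal regularization before factorization (dominance and
Hadamard matrices can be near-singular); variance floor 10⁻¹²; eigenvalue
clipping at zero for the whitened record-count matrix; KS-level
distributional tests use a (S=0, ν=0) residual prior so the closed-form
χ²_N oracle applies exactly. Seeds are explicit everywhere: the
simulation seed drives genotypes, effects and records through one RNG
stream, and each chain has its own seed recorded in its configuration.

## Known limitations

Dense O(n³) setup per relationship matrix bounds practical problem sizes
at a few thousand individuals. Confounded variance components mix slowly
under flat priors at small n (ESS of tens per thousand retained samples);
the reported ESS makes this visible. DIC is computed from thinned samples
only. No REML estimation, no multi-trait models, no pedigree blending,
and no reliabilities/PEV are provided.
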