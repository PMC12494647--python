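# Methods notes

This note records the statistical model behind each component, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducibility.

## Variant identity and harmonisation

Variants are identified positionally as `chrom:pos:a1:a2` with the
allele pair sorted lexicographically, never by rsID; rsIDs drift
between sources, positions on a single build do not. All inputs are
assumed to be on one genome build — no liftover is attempted. Only
biallelic SNPs over {A,C,G,T} are accepted; indels and multi-allelic
records are dropped at read time.

Palindromic (A/T, C/G) SNPs cannot be strand-checked from alleles. A
palindrome is treated as ambiguous — excluded from instruments, dropped
in harmonisation — when its effect-allele frequency lies within 0.08 of
0.5, or is missing. The 0.08 window is the conventional default of the
two-sample harmonisation ecosystem; it is exposed as `maf_window`
everywhere it applies. Unambiguous palindromes are oriented by
frequency concordance: the outcome is taken as strand-flipped when
|eaf_exp − (1 − eaf_out)| < |eaf_exp − eaf_out|.

After alignment both betas are negated if needed so that β_exposure > 0.
The Wald ratio is invariant to this orientation (a property test
asserts it); it only standardises result tables.

## Instrument selection

The cascade runs in a fixed order, and each stage's losses are
counted so that `union = retained + Σ losses` is machine-checkable:

1. union of genome-wide significant variants (p < 5×10⁻⁸, strict) in
   either study;
2. ambiguous-palindrome removal;
3. for variants present in both studies: cross-replication (other
   study p < 0.05, strict, same effect direction) and a pairwise
   heterogeneity screen keeping |Z| < 3, with
   Z = (β_A − β_B)/√(SE_A² + SE_B²). Variants absent from one study
   cannot be replication-tested and are dropped by default
   (`keep_untestable` retains them);
4. cis/trans classification: *cis* iff within ±500 kb of the gene body
   (inclusive), else *trans*;
5. best-source selection: the study with the smaller p-value supplies
   the summary statistics (ties go to study A);
6. greedy LD clumping at r² < 0.001 within a 10 Mb window, run
   separately on the cis and trans lists of each protein. Only the r²
   threshold is prescribed by the workflow; the wide window is the
   conservative convention of the tools this workflow interoperates
   with. p-value ties are broken lexicographically by key so clumping
   is deterministic;
7. MHC exclusion, chr6:26,000,000–34,000,000 inclusive;
8. multi-aptamer exclusion: any variant that survived stage 3 for five
   or more aptamers across the whole protein panel is removed as likely
   pleiotropic. The aptamer map is built after replication but before
   clumping, so clump order cannot hide a pleiotropic variant.

LD always comes from a user-supplied reference panel of dosages, never
from the GWAS cohorts (two-sample setting). A practical caveat
discovered by design analysis: with a panel of n samples, the expected
spurious r² between independent variants is 1/n, so panels with
n ≲ 1,000 produce random clumping at the 0.001 threshold. Panels of
10,000 samples are used throughout the synthetic studies.

## MR estimators

With harmonised pairs (β_X, SE_X, β_Y, SE_Y):

- **Wald ratio** (1 instrument): β_Y/β_X with first-order delta SE
  SE_Y/|β_X|. The second-order term is omitted deliberately — it
  matches the field's default and the difference is negligible for the
  strong instruments this workflow selects.
- **IVW** (≥2): weighted mean of ratios with w = β_X²/SE_Y², equal to
  no-intercept WLS of β_Y on β_X with weights 1/SE_Y². Cochran's Q on
  k−1 df; the fixed-effect SE is inflated by max(1, √(Q/(k−1)))
  (multiplicative random effects with an underdispersion floor).
- **MR-Egger** (≥3, dispatched at ≥6): WLS of β_Y on β_X with a free
  intercept, weights 1/SE_Y²; the intercept estimates the average
  directional pleiotropic effect. Same multiplicative floor; t
  reference distribution on k−2 df.
- **Weighted median** (≥3): ratios ordered, normalised cumulative
  weights s_j = (Σ_{i≤j} w_i − w_j/2)/Σ w_i, linear interpolation at
  s = 0.5. SE by parametric bootstrap: β_X and β_Y resampled from their
  sampling normals, 1,000 replicates, fixed seed (exposed).
- **Mode estimators** (≥3): Gaussian-kernel density of the ratios on a
  512-point grid spanning their range, bandwidth
  φ·0.9·min(sd, MAD)·k^(−1/5) with φ = 1; weights 1 (simple) or the
  IVW weights (weighted). SE by the same bootstrap.

Dispatch: 1 instrument → Wald; 2–5 → IVW; ≥6 → IVW + Egger + weighted
median + both modes. The cut at six reflects that sensitivity
estimators are uninformative below that and is the workflow's
documented convention (`SENSITIVITY_MIN_NSNP`).

The floored IVW test is slightly conservative at small k: Monte Carlo
gives a true type-I rate ≈ 0.037 at k = 3 and α = 0.05, which the
calibration suite measures empirically.

## Colocalisation

Per-variant evidence is the Wakefield approximate Bayes factor. With
V = SE², W the prior effect variance, z = β/SE and shrinkage
r = W/(V+W): log ABF = ½[log(1−r) + r z²]. This is exact for the
normal-likelihood, normal-prior model (the quadrature check in the
test suite is an independent confirmation, not an approximation
bound). Prior effect SDs: 0.15 for quantitative traits (SD units), 0.2
for binary traits (log-odds) — the defaults of the established
colocalisation methodology.

The five-hypothesis posterior uses per-variant priors p1 = p2 = 1×10⁻⁴
and p12 = 1×10⁻⁵, with all sums done by log-sum-exp: ABFs overflow
double precision beyond |z| ≈ 40, and the H3 sum S1·S2 − S4 is formed
as a log-space difference. Posteriors are asserted to sum to 1 within
1e-9 on every call.

SuSiE fine-mapping is the basic iterative Bayesian single-effect
(IBSS) algorithm on summary statistics: z-scores and a reference LD
matrix R, working on the standardized scale with residual variance
fixed at 1 and sufficient statistics X'X = (n−1)R, X'y = √(n−1)·z. Each
of L = 10 effects has its prior variance re-estimated per iteration by
bounded maximum likelihood with the null (V = 0) as a floor. No lambda
regularisation or refinement passes are implemented — a documented
simplification; R is ridge-regularised by 1e-6 on the diagonal.
Convergence is declared when the posterior-mean fitted vector changes
by less than 1e-3 (max norm), capped at 100 iterations. Credible sets
are the smallest per-effect sets reaching 0.95 cumulative posterior
inclusion, discarded when purity (minimum absolute within-set LD)
falls below 0.5. Credible-set colocalisation runs the same hypothesis
sums on the per-effect single-effect log Bayes factors, one result per
pair of surviving sets.

Colocalisation regions are the *cis* window (gene ± 500 kb) restricted
to variants present in both traits and the LD panel. SuSiE-based
colocalisation additionally requires at least 25 region variants —
below that, fine-mapping adds nothing over the single-variant analysis.

## Scan and multiple testing

The Bonferroni denominator is the number of proteins with ≥1 valid
*cis* instrument, recomputed from the audit trail and asserted
consistent; correction is within each outcome, not across outcomes
(the printed proteome-wide threshold 0.05/1,724 divides by proteins
only). Trans-inclusive secondary results are labelled
`cis_trans_secondary` and can never be confused with the primary rows.
Evidence calls are three-way: `H4_shared` (any coloc result with
PP(H4) > 0.8), `H1_underpowered` (PP(H1) > 0.8 — a real protein signal
the outcome cohort is too small to confirm), else `other`. The 0.8 cut
on H1 mirrors the H4 convention.

## Synthetic-data generator

Genotypes use a thresholded Gaussian copula: two latent haplotypes per
sample drawn from a blockwise AR(1) multivariate normal, each
dichotomised at the allele-frequency quantile and summed to a 0/1/2
dosage. This is seedable and needs no external haplotype data, at the
price of attenuating the latent correlation (latent ρ = 0.9 realises
dosage r ≈ 0.8–0.9; measured, not modelled). Causal effects are
specified as fractions q of trait variance, so per-allele effects are
√(q/(2f(1−f))). Protein and outcome residual noise is scaled against
the *empirical* variance of the genetic component so traits have unit
variance and the causal effect of the standardized protein on the
standardized outcome is exactly θ — avoiding an O(θ³) attenuation that
would otherwise bias recovery checks. Proteins are rank-based
inverse-normal transformed before marginal regression, as the real
proteome GWAS were; binary outcomes arise from a liability threshold
at the configured case fraction and are analysed by per-variant
logistic regression (log-odds effects), exercising the binary prior-SD
path honestly rather than through an analytic approximation.

What the generator does **not** emulate: realistic human haplotype
structure and allele-frequency spectra, assay cross-reactivity between
aptamers, sample overlap between cohorts, and population
stratification. Passing calibration on this generator therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

### Scenario library and problem sizes

Named scenarios fix the study conditions: `null` (θ = 0),
`recovery`/`pleiotropy_*` (θ = 0.3 with no, balanced, or directional
instrument-level pleiotropy), `causal_shared`, `causal_distinct`,
`underpowered_outcome` (coloc behaviour), and `multi_aptamer` (five
aptamers sharing one pQTL). Cohort sizes are scaled-down analogues of
real proteome/outcome GWAS chosen so every planted instrument has
per-study power > 99% (association z ≈ 8–9 against the 5.45 threshold):
24-variant regions with nA = nB = n_out = 5,000 for the estimator
calibration scenarios, and 120-variant regions with nA = 20,000,
n_out = 50,000 (2,000 for the underpowered case) for colocalisation
scenarios, where outcome association must itself be strong. The
`recovery` scenario uses nA = 20,000, n_out = 50,000 so that
weak-instrument and winner's-curse biases (≈ θ/F) are an order of
magnitude below the 0.02 recovery band.

Estimator calibration (type-I error, recovery means) instruments each
protein at its *known* causal variants via `oracle_harmonised_set`,
bypassing significance selection: these checks measure estimator
properties, which selection conditioning (winner's curse inflating
β_X, best-source selection taking a maximum over two studies) would
otherwise contaminate — an attenuation that affects any real
two-sample pipeline of this design and is visible in the end-to-end
scan's slightly shrunken estimates.

## Known limitations

- Proxy lookup searches only the protein's own valid instrument list,
  not genome-wide; both exposure and outcome statistics are taken at
  the proxy variant (the alternative — inheriting the original
  instrument's exposure effect — is not implemented).
- No sample-overlap correction, Steiger filtering, multivariable MR,
  or conditional secondary-signal discovery.
- SuSiE here is the plain IBSS variant; on pathological LD it may
  split one signal across effects, which purity filtering only partly
  mitigates.
- Binary-outcome simulation is slow relative to the quantitative path
  (per-variant logistic fits) and is exercised at small region sizes.
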