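# Methods

`twinmd` implements a genetic-epidemiologic analysis of the nine DSM-IV
symptomatic criteria for major depression (MD), distinguishing criteria
endorsed **inside** a temporally clustered syndrome that meets the MD count
rule ("IN") from criteria endorsed **outside** any such syndrome ("OUT").
The statistical machinery is the classical twin design: monozygotic (MZ)
pairs share all additive genetic variation, dizygotic (DZ) pairs half of it
on average, so the pattern of MZ vs DZ resemblance identifies additive
genetic (A), shared-environment (C), and unique-environment (E) variance in
a latent liability.

## Symptom processing

The interview-level data structure holds, per twin, 14 binary disaggregated
symptom items (weight decrease/increase, appetite decrease/increase,
insomnia/hypersomnia, agitation/retardation, plus the six single-item
criteria), 14 parallel illness/medication attribution flags, and up to two
temporal syndromes given as sets of item indices. Processing order:

1. **Somatic filter** — endorsed items attributed to illness or medication
   are zeroed and removed from syndrome sets before anything else.
2. **Aggregation** — the disaggregated weight/appetite, sleep, and
   psychomotor items collapse by logical OR into single criteria, yielding
   the nine official DSM criteria.
3. **Diagnosis** — a syndrome algorithmically meets MD criteria when it
   contains ≥ 5 of the nine criteria including at least one cardinal
   criterion (depressed mood or loss of interest). The two-week duration,
   impairment, and exclusion clauses of the full DSM definition are not
   representable in a symptom-set data structure and are deliberately not
   modeled; only the count rule is computable here.
4. **IN/OUT assignment** — criteria inside a diagnosing syndrome are IN.
   Criteria endorsed in a sub-threshold syndrome, or via an item grouped
   into no syndrome at all, are OUT. The same criterion can be both (e.g.
   sleep problems inside a diagnosing episode and again in a separate
   sub-threshold cluster). Coverage is judged at the item level: an
   endorsed item outside any syndrome marks its criterion OUT even when a
   sibling item of the same criterion sits inside a diagnosing syndrome,
   because that occurrence was, by construction, not part of a diagnosing
   clustering. If both reported syndromes independently diagnose, criteria
   in either are IN.
5. **Censoring sensitivity analysis** — a sub-threshold cluster of exactly
   four aggregated criteria (one short of a diagnosis) has the OUT status
   of its criteria set to *unknown*; IN statuses are untouched. "Exactly
   four" is the operative reading since five or more would already
   diagnose, and the count is of aggregated criteria, not disaggregated
   items. Unknown statuses are excluded pairwise downstream and serialized
   as empty cells, never imputed.

## Liability-threshold model

A binary criterion is modeled as a standard-normal liability dichotomized
at threshold τ = Φ⁻¹(1 − prevalence). For a twin pair, the two liabilities
are bivariate normal with correlation r; the 2×2 cross-twin table is
multinomial with cell probabilities given by the bivariate normal CDF
Φ₂(·,·; r), computed in closed form via Owen's T function (absolute
accuracy ≈ 1e−15; the ±1 limits are handled analytically).

**Tetrachoric correlations.** Tables are double-entered (each pair counted
in both twin orders), the standard symmetrization in twin analysis; in–out
cross tables enter as (twin1-IN × twin2-OUT) plus (twin2-IN × twin1-OUT).
The likelihood is maximized jointly in (ρ, τ_row, τ_col) by Nelder–Mead
from three starting correlations (−0.5, 0, 0.5), tolerance 1e−8 on the
log-likelihood, ties broken toward the smaller |ρ|. Because double entry
duplicates information, all likelihood-based inference is scaled to the raw
pair count (a factor 1/2 for double-entered tables), which keeps confidence
intervals from being anti-conservative. 95% CIs are profile-likelihood
intervals (2·Δ log L = 3.84), robust at the ±1 boundary where perfectly
concordant tables are reported with a one-sided interval. Thresholds are
estimated per table rather than fixed from pooled margins: the per-table
model is then saturated and each table self-contained. Twins whose co-twin
is missing contribute Bernoulli margin (threshold) terms only, never joint
cells; pairs with an unknown status on either member are dropped from that
criterion's table.

**Univariate ACE models.** The model implies r_MZ = a² + c² and
r_DZ = ½a² + c²; the likelihood is the per-zygosity multinomial over the
four cells with a single threshold equated across twin order and zygosity
(the parsimonious convention, which also makes fits comparable across
zygosity), equivalent to full-information ML on these data but much faster
to evaluate. In the full ACE model the two free components are *unbounded*
— estimates may go negative — which avoids the boundary bias that implicit
non-negativity constraints induce; e² absorbs the remainder so the
standardized proportions sum to one by construction. Implied twin
correlations outside (−1, 1) are penalized rather than raised. Sub-models
AE, CE, E fix the omitted components at zero. Fits use Nelder–Mead from
five starting points; 95% CIs per standardized component are
profile-likelihood based. Model selection uses AIC = −2 log L + 2k with k
counting free parameters including the threshold; AIC ties go to fewer
parameters, then to the fixed order ACE > AE > CE > E.

**Bivariate IN/OUT models.** The four liabilities (IN₁, OUT₁, IN₂, OUT₂)
have block covariance [[W, B], [B, W]] with W the within-twin 2×2 block and
B = k·A + C the cross-twin block (k = 1 for MZ, ½ for DZ; C fully shared; E
within-twin only). Free parameters are the component (co)variances of the
chosen model (ACE, AE, or CE), the unique-environment cross-covariance, and
the two thresholds; within-trait totals are fixed at 1. The genetic
correlation is r_g = A₁₂ / √(A₁₁·A₂₂), with a profile-likelihood CI
obtained by refitting under the constraint A₁₂ = r_g√(A₁₁A₂₂).

The 16 joint cell probabilities are computed by a conditioning
decomposition rather than generic numerical integration: writing each
twin's liability pair as L_j = S + U_j with Cov(S) = B and Cov(U_j) = W − B,
the twins are conditionally independent given the shared factor S, so every
cell probability is a 2-D Gauss–Hermite integral (24 nodes per dimension)
over S of a product of two bivariate-normal quadrant probabilities. The
quadrature is deterministic, agrees with an independent quasi-Monte-Carlo
rectangle integrator (`mvn_orthant`, fixed internal seed, absolute
tolerance 1e−6) to ≈ 1e−8 in the tests, and makes likelihoods exactly
reproducible. One consequence: the decomposition requires B to be positive
semi-definite, so unlike the univariate model the bivariate component
matrices are constrained to valid covariance structures; additive variances
can reach the zero boundary but not go negative, and r_g is reported as
undefined (with an explanatory note) when a within-trait additive variance
estimate is numerically zero (≤ 1e−6). With identical IN and OUT data the
maximum sits on the boundary ridge where the within-twin cross-correlation
approaches 1; the fit then correctly reports r_g at the +1 boundary, but
individual components along the ridge are weakly identified and should not
be over-interpreted.

## Summaries

Across-criterion means of correlations are computed on the Fisher-z
(arctanh) scale and back-transformed, with a t-based 95% CI (df = 8) from
the between-criterion spread — the source analyses do not state how the
means-of-nine CIs were formed, so this documented convention is adopted;
variance-component means use the arithmetic mean with a t-based CI on the
proportion scale. The IN vs OUT comparison of two correlation sets is a
two-sided paired t test on the per-criterion Fisher-z differences (df = 8);
a zero-spread nonzero difference is reported as an infinite statistic with
p = 0. Significance elsewhere follows the conservative non-overlapping-CI
convention, with no multiple-testing correction.

## Synthetic data generators

The study's interview data are not deposited, so the package ships two
generators that define the conditions under which everything is tested.

**Liability-level generator.** Draws ACE-structured 4-variate normal
liabilities per pair (A shared ×1 MZ / ×0.5 DZ-and-opposite-sex, C shared,
E independent; rg/rc/re correlate the IN and OUT components within the
standard decomposition) and dichotomizes at prevalence-implied thresholds.
Defaults follow the study design: 1,461 complete MZ, 1,079 complete
same-sex DZ, and 1,411 opposite-sex pairs with 285/338/476 incomplete
twins (made by deleting one member of extra pairs at random); components
a² = 0.31/c² = 0.04 (IN) and a² = 0.15/c² = 0.05 (OUT), rg = 0.07.
Per-criterion prevalences (IN ≈ 2–6%, OUT ≈ 3–22%) are documented,
overridable defaults chosen to reproduce the qualitative descriptive
pattern (every criterion more common OUT than IN; thoughts of death
rarest); they are stand-ins, not published values. Opposite-sex pairs are
DZ and pooled with same-sex DZ by default (a config switch), since the
analyses report only MZ/DZ correlations.

**Episode-level generator.** Emulates the interview itself: an
ACE-structured episode liability (a² = 0.35, c² = 0.05, last-year episode
probability 7.5%) decides whether a twin had an episode; within-episode
items are endorsed with item-specific probabilities (cardinal symptoms
near-universal) and grouped into one temporal syndrome; stray symptoms
occur independently at item-specific annual rates and either stay
ungrouped or, with probability 0.35, form a further (usually
sub-threshold) cluster; endorsed symptoms are flagged as
illness/medication-related at rate 0.04. This generator deliberately omits
age, sex, cohort, and interviewer effects, longitudinal structure, and any
genetic correlation between episode liability and stray symptoms; passing
tests therefore demonstrate that the classification and modeling stages
behave correctly under the assumed liability structure, not that the
generator reproduces every feature of real interview data.

An exact-cell-probability oracle (`expected_cell_probabilities`) computes
the infinite-data multinomial cells implied by any parameter set, and is
used both to validate the simulators (chi-square goodness of fit at
n = 100,000 pairs) and to check the fitters against Falconer moment
inversion (a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ) on expected-count
tables.

## Numerical choices and problem sizes

- Bivariate-normal CDF: Owen's T closed form; inputs clipped at |z| = 8.5
  (mass beyond < 1e−17); |ρ| ≥ 1 − 1e−12 routed to the comonotone limits.
- Cell probabilities clipped at 1e−300 before logs; invalid parameter
  regions penalized at −1e12 so simplex optimization never crashes.
- Profile-likelihood CI endpoints by bisection (tetrachoric to 1e−6 in ρ,
  components to 1e−4, r_g to 2e−3).
- Recovery simulations in the test suite and acceptance script use the
  study's sample sizes (1,461 MZ / 1,079 DZ pairs) with 50 replicates × 9
  criteria for correlations and 20 × 9 for univariate fits; bivariate
  genetic-correlation recovery uses 5 replicates × 9 criteria at 3,000
  pairs per zygosity, a size chosen to keep a single-CPU run comfortably
  inside a coffee break while still pinning the mean to ±0.03.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; a pipeline run writes a manifest (config echo,
  seed, version) and reproduces byte-identical artifacts.

## Known limitations

- No sex-limitation or dominance (D) components; no Cholesky
  parameterization; binary traits only (no ordinal extension).
- The per-criterion IN prevalences are low enough that individual
  tetrachoric estimates at the study's sample sizes are occasionally
  extreme (a rare criterion can yield an empty concordant cell); the
  across-criterion Fisher-z mean inherits that volatility. This mirrors the
  real design's information limits rather than an estimation defect.
- The bivariate parameter space constrains component matrices to be PSD
  (see above), a slightly tighter space than the unbounded univariate
  parameterization.
- DSM diagnosis is the A-criterion count rule only; hierarchy/exclusion
  rules (bereavement, bipolarity) and lifetime diagnoses are out of scope.
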