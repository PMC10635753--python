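# Methods

## The model

Observed case (or death) counts per area are modelled as

    O_i ~ Poisson(E_i · θ_i),        log θ_i = α + u_i + v_i

where `E_i` is the internally standardized expected count, `θ_i` the
relative risk of area *i* against the state average, `α` the log baseline,
`u` a spatially structured random effect and `v` an unstructured one — the
BYM (Besag–York–Mollié) convolution model. The structured effect carries an
intrinsic CAR (ICAR) prior with unnormalized log-kernel

    −(τ_u / 2) · Σ_{i∼j} (u_i − u_j)²

over the rook-contiguity graph with binary weights (the pairwise-difference
form, with no rescaling by graph structure), equivalent to
`u_i | u_−i ~ N(mean of neighbours, 1 / (τ_u m_i))` with `m_i` the
neighbour count. The unstructured effect is `v_i ~ N(0, 1/τ_v)`. The ICAR
kernel is improper (invariant to constant shifts), so `u` is recentred to
sum to zero after every sweep and `α` absorbs the mean; `α` itself has a
flat prior.

**Hyperpriors.** `τ_u, τ_v ~ Gamma(shape 0.5, rate 0.0005)` — the
conventional weakly-informative disease-mapping default; both are
configurable, and either precision can be fixed (used by the validation
oracle below).

**Expected counts.** Internal standardization on the population aged 15+:
the crude rate `r = ΣO / Σ(pop over populated areas)` gives
`E_i = r · pop_i`. All cases count toward `r`, including any registered to
areas with zero recorded population, so the populated areas' expectations
carry the full observed total (`Σ E_populated = Σ O_all`). Zero-population
areas cannot carry an informative expectation; they receive `E_i = r` (a
notional population of one person — small, positive, essentially
information-free) and are flagged `uninformative`, excluded from the
conservation identity. Age–sex stratified standardization is deliberately
not the default: the expected counts here are crude internal ones on the
15+ base.

**Significance and bands.** Per area we report the posterior median of
`θ_i` and the equal-tailed 95% credible interval (2.5th/97.5th percentiles
of kept draws). An area is *significantly high* iff the lower limit
exceeds 1 and *significantly low* iff the upper limit is below 1. (A rule
based on the lower limit alone cannot identify low-risk areas, so the low
side uses the upper limit; this asymmetry is deliberate and documented.)
Median risks are additionally banded: ≤ 1 at/below average; (1, 2] within
100% above average; > 2 more than 100% above (risk more than doubled).

## The sampler

Single-chain Metropolis-within-Gibbs (multiple chains are available but the
single-chain Geweke gate is the default convergence check):

- `τ_u`, `τ_v`: conjugate Gamma full conditionals
  (`Gamma(a + rank/2, b + Q(u))` with `Q` the ICAR quadratic and rank the
  Laplacian rank `n − #components`; `Gamma(a + n/2, b + Σv²/2)`).
- `α`, each `u_i`, each `v_i`: univariate random-walk Metropolis. The
  proposal sd is a dimensionless multiplier divided by the square root of
  the parameter's current conditional curvature (prior precision plus an
  `O_i + 1` likelihood-information proxy). Multipliers are adapted every
  100 sweeps during burn-in toward a 30–50% acceptance rate and frozen
  afterwards, preserving detailed balance post burn-in. Curvature scaling
  matters: with a frozen *absolute* step width, excursions of `τ_u` to
  large values made `u`-moves nearly always reject, freezing the field and
  locking the precision high — a quasi-absorbing state. The scaled
  proposal is still a symmetric walk (its width depends only on the
  precisions and the data, never on the coordinate being updated).
- `u`-updates sweep the graph one colour class at a time (greedy
  colouring; two colours on a lattice). Within a class no two areas are
  adjacent, so their full conditionals are mutually independent given the
  rest and can be accepted/rejected simultaneously without changing the
  invariant distribution — this is an ordinary fixed-scan Gibbs ordering,
  vectorized.
- One auxiliary **field-rescaling move** per field per sweep:
  `(u, τ_u) → (c·u, τ_u/c²)` with `log c ~ N(0, 0.2²)` (likewise for
  `(v, τ_v)`). The ICAR and Normal kernels are invariant under the pair,
  so the Metropolis ratio involves only the likelihood, the hyperprior and
  the Jacobian. This targets the slowest direction of the BYM posterior —
  field scale against precision — without which the precision chains mix
  too slowly for single-chain diagnostics to be meaningful.

**Schedule.** Default 500,000 iterations, burn-in fraction 0.6, thinning
20, i.e. exactly 10,000 kept draws; configurations keeping fewer than 100
draws are rejected before sampling. Initialization: `α = log(ΣO/ΣE)` (zero
under internal standardization), `u = v = 0`, `τ_u = τ_v = 1`. Identical
seed and config give bit-identical kept draws.

**Islands.** The rook builder never links islands automatically — the
analyst repairs them explicitly via `apply_manual_links`, and the fitter
refuses to run while unrepaired islands remain. Under the explicit
`allow_islands` escape hatch an island's structured effect gets a proper
`N(0, 1/τ_u)` prior (neighbour count treated as one, mean zero); this is a
documented fallback only.

**Diagnostics.** Geweke z compares the first 10% with the last 50% of each
monitored chain (α, the free precisions, three randomly chosen `θ_i`);
each segment's variance of the mean is a Bartlett-kernel (Newey–West)
long-run variance with bandwidth `⌊4(n/100)^{1/4}⌋`. |z| < 1.96 is flagged
"converged". Trace, density and autocorrelation plots plus CSVs are
exported per monitored scalar. Acceptance rates are logged so a mistuned
run is visible without opening plots.

## Moran statistics

Global Moran's I uses the standard cross-product form with row-standardized
weights; its permutation test reassigns values to areas uniformly
(`n_perm` = 99,999 by default) with a one-sided pseudo p-value
`(#extreme + 1)/(n_perm + 1)` toward the observed deviation from
`E[I] = −1/(n−1)`. Local Moran `I_i = (z_i/m2)·Σ_j w_ij z_j` is tested by
conditional permutation (hold `z_i`, permute the rest over the other
areas), with quadrant from the signs of `z_i` and its spatial lag; a zero
deviation or lag counts as "high" (a measure-zero tie rule). Labels attach
only when `p_i ≤ α` (default 0.05, no multiple-testing correction — `α` is
exposed rather than silently adjusted). Islands have zero lag, so their
local statistic carries no evidence: they are always `not_significant`,
never NaN. By default islands are included in the mean/variance used for
`z` (an `exclude_islands` pre-filter is unnecessary when, as in the
intended workflow, all islands were repaired before analysis). The
statistics are computed on the posterior **median smoothed** ratios; both
global and local implementations are validated against naive double-loop
oracles to 1e-12. All conditional permutations draw from one seeded
generator in fixed area order, so results are reproducible.

## Synthetic data

The generator emulates the structure of a state cancer registry crossed
with census geography: an `nx×ny` unit-square lattice (plus optional
detached island cells and an exact count of zero-population areas;
populations jittered ±20% around a base), a true risk surface
`log θ = α + u + v` with `u` an *exact* ICAR draw — sampled by
eigendecomposition of the graph Laplacian's pseudo-inverse, sharing no code
with the MCMC fitter so generator bugs cannot mask fitter bugs — and `v`
iid normal; Poisson counts `O_i ~ Poisson(E_i θ_i)`; and patient rows with
the marginal mix of a large published oral/oropharyngeal cohort profile
(71.5% male; age bands 2.9/40.8/56.3%; site split 52.1/46.3/1.6%; 59.3%
dead; a ~2-per-10,000 under-15 mass to exercise the exclusion rule; grade
five-level categorical). Survival months (death and censoring alike) come
from a geometric distribution with `p = 0.0115` (median ≈ 60 months)
truncated at 478 — chosen to match the cohort's overall median survival
and observed range; it does not reproduce the exact early/late death split
of real registries. Survival is independent of area: spatial mortality
signal belongs in `θ`, not in patient rows. Every generator is a pure
function of its spec and seed.

What passing tests on these fixtures do *not* show: real geographies have
irregular polygons, highly variable neighbour counts and populations
spanning orders of magnitude; real registries have informative censoring,
coding drift (grade criteria especially) and geocoding error. The fixtures
validate the algorithms, not those data pathologies.

## Problem sizes and numerical choices

Test and validation runs use deliberately reduced, stated sizes chosen as
desk-scale defaults: the sampler-vs-quadrature check fixes
`τ_u = τ_v = 4` on 2–3 areas (60,000 iterations); parameter recovery uses a
10×10 lattice with `E = 50`, `σ_u = 0.5`, `σ_v = 0.1` and 40,000
iterations; the flat-truth coverage suite runs 50 seeded 4×4 replicates at
8,000 iterations each; the demo convergence fit uses 100,000 iterations at
the production schedule's proportions (60% burn-in, thin 20). The
production default remains 500,000/20/0.6.

The quadrature oracle integrates the exact posterior over
`(α, sum-to-zero u-coordinates, v)` on dense grids (α: 64 points over ±3.5
around `log(ΣO/ΣE)`; u, v ranges ±(4/√τ + 1)), exploiting that the `v_i`
factorize per area given `(α, u)`; per-area quantiles come from a
4,000-bin histogram of `log θ_i`. Grid truncation and bin width contribute
errors well below the 0.05 comparison tolerance on 2–3 areas.

Degenerate inputs: all-zero observed counts fall back to a positive
pseudo-rate (`1/Σpop`) so the Poisson model stays defined; constant chains
make Geweke undefined and raise rather than return NaN; Moran statistics
refuse constant fields and `n < 3`.

## Known limitations

- Alternative spatial priors (Leroux, BYM2, proper CAR), spatio-temporal
  models and covariates are out of scope.
- No external/reference-population or age-standardized expecteds by
  default (a stratified option exists at the API level but is off).
- Only rook first-order contiguity is built from geometry; queen,
  higher-order, distance-band and k-nearest weights are not.
- Planar coordinates are assumed throughout; no geodesic computation or
  CRS handling.
- LISA p-values are raw per-area values; the multiple-testing burden over
  thousands of areas is the analyst's to weigh.
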