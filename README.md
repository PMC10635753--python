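# bymap — Bayesian small-area disease mapping

`bymap` is a Python library for mapping disease risk over small
administrative areas from registry-style case data: cancer registry
epidemiologists and spatial biostatisticians can go from patient rows and
area polygons to smoothed risk maps, credible-interval significance calls
and cluster/outlier detection in a single reproducible pipeline.

It implements, end to end:

- **Rook contiguity weights** from polygon geometry (two areas are
  neighbours iff their boundaries share a segment of positive length),
  explicit manual repair of islands, GAL file round-tripping;
- **Cohort descriptives** for oral/oropharyngeal cancer registries: subsite
  → site-class dictionaries (oral cavity vs oropharynx), the under-15
  exclusion, one-decimal summary tables, and month-granular 3-year/5-year
  mortality strata;
- **Internal standardization**: expected counts `E_i = r · pop_i` from the
  state-wide crude rate over the population aged 15+, raw `SIR_i = O_i/E_i`,
  and flagged "uninformative" expectations for zero-population areas;
- **BYM smoothing** (Besag–York–Mollié): `O_i ~ Poisson(E_i θ_i)` with
  `log θ_i = α + u_i + v_i`, an intrinsic CAR prior on the structured
  effect `u` (each `u_i | u_-i ~ N(mean of neighbours, 1/(τ_u m_i))`), an
  exchangeable `v_i ~ N(0, 1/τ_v)`, Gamma hyperpriors on the precisions,
  fitted by a single-chain Metropolis-within-Gibbs sampler (default
  schedule: 500,000 iterations, 60% burn-in, every 20th kept → 10,000
  draws), summarized by posterior medians with equal-tailed 95% credible
  intervals, Geweke and trace/density/autocorrelation diagnostics;
- **Spatial clustering**: global Moran's I with Monte-Carlo permutation
  p-values (99,999 permutations by default) and local Moran (LISA)
  high–high / low–low cluster and low–high / high–low outlier labels under
  conditional permutation;
- **Synthetic data**: lattice geographies with islands and zero-population
  areas, exact ICAR risk surfaces via the graph-Laplacian pseudo-inverse,
  Poisson counts, and patient-level registries with a configurable marginal
  mix — so every stage is testable without restricted registry data;
- a thin **CLI** (`bymap simulate|adjacency|cohort|fit|moran|lisa|map|all`)
  and GeoJSON/choropleth export.

## Worked example

`python examples/03_bym_smoothing.py` simulates a 6×6 geography with a
spatially structured true risk surface, fits the BYM model on a reduced
20,000-iteration demo schedule and prints:

```
kept 2500 draws | acceptance: alpha 0.38, u 0.40, v 0.40
variance of raw ratios:   0.1972
variance of smoothed RRs: 0.1600
correlation(true log-risk, smoothed log-risk): 0.937

highest-risk areas:
 area_id  median_rr  ci_low  ci_high significance                   risk_band
cell_5_0       2.57    2.18     3.03         high                above_100pct
cell_1_4       1.60    1.31     1.94         high above_average_within_100pct
cell_2_4       1.60    1.30     1.95         high above_average_within_100pct
```

Smoothing reduces the across-area variance (0.197 → 0.160) while the
smoothed medians track the true surface (correlation 0.937). `cell_5_0` is
"significantly high" because its whole 95% credible interval lies above the
state average of 1, and its median risk of 2.57 — more than double the
average — places it in the top risk band. Continuing with
`examples/04_moran_and_lisa.py` on the same fit:

```
global Moran's I = 0.301 (expectation under no clustering -0.029), pseudo p = 0.0036
5 of 36 areas in significant local clusters/outliers:
cell_0_1  0.658  ...  low_low
cell_4_0  1.255  ...  high_high
```

so the smoothed risks are more spatially clustered than chance (I = 0.301
against −0.029 expected), with named low–low and high–high cluster cores.

The other examples cover adjacency construction and island repair (`01`),
registry cohort descriptives (`02`), and the full CLI chain (`05`).

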