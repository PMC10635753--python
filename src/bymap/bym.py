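"""BYM hierarchical Poisson smoothing of area-level disease risk.

The model (Besag–York–Mollié):

    O_i ~ Poisson(E_i * theta_i),      log theta_i = alpha + u_i + v_i

with ``u`` a spatially structured effect under an intrinsic CAR (ICAR) prior
— each u_i conditionally Normal around the mean of its neighbours with
precision tau_u * m_i — and ``v`` an exchangeable Normal(0, 1/tau_v) effect.
The improper ICAR kernel is identified by recentering u to sum to zero every
sweep, alpha absorbing the mean.  Precisions get Gamma hyperpriors
(shape 0.5, rate 0.0005 by default, the conventional disease-mapping choice).

Sampling is Metropolis-within-Gibbs: the precisions have conjugate Gamma full
conditionals; alpha, u and v move by univariate random-walk Metropolis with
step sizes adapted toward a 30–50% acceptance rate during burn-in and frozen
afterwards.  The u-updates sweep the areas one graph-colour class at a time:
within a class no two areas are adjacent, so their full conditionals are
mutually independent given the rest of the field and can be accepted or
rejected simultaneously without changing the target distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .geography import SpatialWeights, WeightStyle
from .standardization import CountData, raw_ratio

__all__ = [
    "MCMCConfig",
    "BYMState",
    "BYMPosterior",
    "PosteriorSummary",
    "Significance",
    "RiskBand",
    "log_posterior",
    "gibbs_sweep",
    "draw_tau_u",
    "draw_tau_v",
    "fit_bym",
    "classify_significance",
    "risk_band",
]


class Significance(str, Enum):
    high = "high"
    low = "low"
    none = "none"


class RiskBand(str, Enum):
    at_or_below_average = "at_or_below_average"
    above_average_within_100pct = "above_average_within_100pct"
    above_100pct = "above_100pct"


@dataclass(frozen=True)
class MCMCConfig:
    """Single-chain MCMC schedule and priors.

    Defaults follow the long conservative schedule standard in small-area
    disease mapping: 500,000 iterations, the first 60% discarded as burn-in,
    every 20th of the remainder kept — 10,000 retained draws.
    """

    n_iter: int = 500_000
    thin: int = 20
    burn_in_fraction: float = 0.6
    n_chains: int = 1
    seed: int = 0
    tau_u_prior: tuple[float, float] = (0.5, 0.0005)  # Gamma(shape, rate)
    tau_v_prior: tuple[float, float] = (0.5, 0.0005)
    fixed_tau_u: float | None = None
    fixed_tau_v: float | None = None
    allow_islands: bool = False
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("n_iter, thin and n_chains must be positive")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in (0, 1)")

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_fraction)

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin

    def validate_schedule(self) -> None:
        if self.n_kept < 100:
            raise ValueError(
                f"schedule keeps only {self.n_kept} samples (< 100); "
                "increase n_iter or reduce thinning/burn-in"
            )


@dataclass
class BYMState:
    """Current parameter values of the sampler."""

    alpha: float
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions must be positive")

    @property
    def theta(self) -> np.ndarray:
        """Per-area relative risk exp(alpha + u + v)."""
        return np.exp(self.alpha + self.u + self.v)


# ---------------------------------------------------------------------------
# workspace: precomputed graph structure
# ---------------------------------------------------------------------------

class _Workspace:
    def __init__(self, counts: CountData, weights: SpatialWeights,
                 allow_islands: bool):
        if weights.style != WeightStyle.binary:
            raise ValueError("BYM requires binary (unstandardized) weights")
        if list(weights.area_ids) != list(counts.area_ids):
            raise ValueError("counts and weights area orderings differ")
        islands = weights.islands
        if islands and not allow_islands:
            names = [weights.area_ids[i] for i in islands]
            raise ValueError(
                f"areas with no neighbors present: {names}; link them with "
                "apply_manual_links (or pass allow_islands=True to accept a "
                "zero-mean prior for their structured effect)"
            )
        self.O = counts.observed.astype(float)
        self.O_sum = float(self.O.sum())
        self.E = counts.expected.astype(float)
        self.n = counts.n
        self.W = weights.to_sparse()
        edges = weights.edge_list()
        self.edge_i = np.array([e[0] for e in edges], dtype=np.intp)
        self.edge_j = np.array([e[1] for e in edges], dtype=np.intp)
        m = weights.cardinalities.astype(float)
        self.is_island = m == 0
        self.m_eff = np.where(self.is_island, 1.0, m)  # islands: N(0, 1/tau_u)
        self.colors = _greedy_coloring(weights)
        self.color_classes = [np.flatnonzero(self.colors == c)
                              for c in range(self.colors.max() + 1)]
        # rank of the structured-precision matrix: n - #components for the
        # ICAR part, plus one per island under the proper zero-mean fallback
        self.rank_u = (self.n - _n_components(weights)) + int(self.is_island.sum())

    def icar_quad(self, u: np.ndarray) -> float:
        """0.5 * sum over links of (u_i - u_j)^2, plus island u_i^2 terms."""
        d = u[self.edge_i] - u[self.edge_j]
        q = 0.5 * float(d @ d)
        if self.is_island.any():
            q += 0.5 * float(u[self.is_island] @ u[self.is_island])
        return q


def _greedy_coloring(weights: SpatialWeights) -> np.ndarray:
    colors = np.full(weights.n, -1, dtype=np.intp)
    for i in range(weights.n):
        used = {colors[j] for j in weights.neighbors[i] if colors[j] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return colors


def _n_components(weights: SpatialWeights) -> int:
    seen = np.zeros(weights.n, dtype=bool)
    n_comp = 0
    for s in range(weights.n):
        if seen[s]:
            continue
        n_comp += 1
        stack = [s]
        seen[s] = True
        while stack:
            i = stack.pop()
            for j in weights.neighbors[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
    return n_comp


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def log_posterior(
    state: BYMState,
    counts: CountData,
    weights: SpatialWeights,
    tau_u_prior: tuple[float, float] = (0.5, 0.0005),
    tau_v_prior: tuple[float, float] = (0.5, 0.0005),
    allow_islands: bool = False,
) -> float:
    """Log of the unnormalized joint density of all BYM parameters."""
    ws = _Workspace(counts, weights, allow_islands)
    mu = ws.E * state.theta
    loglik = float(np.sum(ws.O * np.log(mu) - mu - gammaln(ws.O + 1.0)))
    lp_u = 0.5 * ws.rank_u * math.log(state.tau_u) - state.tau_u * ws.icar_quad(state.u)
    lp_v = 0.5 * ws.n * math.log(state.tau_v) \
        - 0.5 * state.tau_v * float(state.v @ state.v)
    a_u, b_u = tau_u_prior
    a_v, b_v = tau_v_prior
    lp_tau = (a_u - 1) * math.log(state.tau_u) - b_u * state.tau_u \
        + (a_v - 1) * math.log(state.tau_v) - b_v * state.tau_v
    return loglik + lp_u + lp_v + lp_tau


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class _StepSizes:
    """Dimensionless random-walk multipliers, adapted during burn-in.

    The proposal standard deviation for each parameter is the multiplier
    divided by the square root of that parameter's current full-conditional
    curvature (prior precision plus an O+1 likelihood-information proxy), so
    proposals stay well scaled however far the precisions move after the
    multipliers are frozen.  The scale depends only on the precisions and the
    data — never on the parameter being updated — so the walk stays symmetric.
    """

    alpha: float
    u: np.ndarray
    v: np.ndarray
    # acceptance bookkeeping for adaptation
    acc_alpha: int = 0
    acc_u: np.ndarray | None = None
    acc_v: np.ndarray | None = None
    n_sweeps: int = 0


def _new_steps(n: int) -> _StepSizes:
    return _StepSizes(alpha=2.4, u=np.full(n, 2.4), v=np.full(n, 2.4),
                      acc_u=np.zeros(n), acc_v=np.zeros(n))


def draw_tau_u(u: np.ndarray, edge_i: np.ndarray, edge_j: np.ndarray,
               rank: int, prior: tuple[float, float], rng: np.random.Generator,
               island_mask: np.ndarray | None = None) -> float:
    """Conjugate Gamma draw of the structured precision given the field:
    tau_u ~ Gamma(a + rank/2, b + 0.5 * sum over links of (u_i - u_j)^2)."""
    a, b = prior
    d = u[edge_i] - u[edge_j]
    quad = 0.5 * float(d @ d)
    if island_mask is not None and island_mask.any():
        quad += 0.5 * float(u[island_mask] @ u[island_mask])
    return float(rng.gamma(a + 0.5 * rank, 1.0 / (b + quad)))


def draw_tau_v(v: np.ndarray, prior: tuple[float, float],
               rng: np.random.Generator) -> float:
    """Conjugate Gamma draw of the unstructured precision given the field:
    tau_v ~ Gamma(a + n/2, b + 0.5 * sum v_i^2)."""
    a, b = prior
    return float(rng.gamma(a + 0.5 * v.size, 1.0 / (b + 0.5 * float(v @ v))))


def _sweep(state: BYMState, ws: _Workspace, cfg: MCMCConfig,
           rng: np.random.Generator, steps: _StepSizes, adapt: bool) -> BYMState:
    O, E, n = ws.O, ws.E, ws.n
    u, v = state.u, state.v
    alpha, tau_u, tau_v = state.alpha, state.tau_u, state.tau_v
    a_u, b_u = cfg.tau_u_prior
    a_v, b_v = cfg.tau_v_prior

    # conjugate precision updates
    if cfg.fixed_tau_u is None:
        tau_u = draw_tau_u(u, ws.edge_i, ws.edge_j, ws.rank_u, cfg.tau_u_prior,
                           rng, island_mask=ws.is_island)
    else:
        tau_u = cfg.fixed_tau_u
    if cfg.fixed_tau_v is None:
        tau_v = draw_tau_v(v, cfg.tau_v_prior, rng)
    else:
        tau_v = cfg.fixed_tau_v

    # alpha: scalar random-walk Metropolis (flat prior)
    euv = np.exp(u + v)
    s_eff = float(E @ euv)
    da = steps.alpha / math.sqrt(ws.O_sum + 1.0) * rng.standard_normal()
    dlp = float(O.sum()) * da - (math.exp(alpha + da) - math.exp(alpha)) * s_eff
    if math.log(rng.random()) < dlp:
        alpha += da
        steps.acc_alpha += 1

    # u: colour class by colour class (conditionally independent within class)
    base = E * np.exp(alpha + v)
    sd_u = steps.u / np.sqrt(tau_u * ws.m_eff + ws.O + 1.0)
    for idx in ws.color_classes:
        nbr_sum = ws.W @ u
        nbr_mean = np.where(ws.is_island, 0.0, nbr_sum / ws.m_eff)
        du = sd_u[idx] * rng.standard_normal(idx.size)
        u_new = u[idx] + du
        dlp = (
            O[idx] * du
            - base[idx] * (np.exp(u_new) - np.exp(u[idx]))
            - 0.5 * tau_u * ws.m_eff[idx]
            * ((u_new - nbr_mean[idx]) ** 2 - (u[idx] - nbr_mean[idx]) ** 2)
        )
        accept = np.log(rng.random(idx.size)) < dlp
        u[idx[accept]] = u_new[accept]
        steps.acc_u[idx[accept]] += 1

    # v: all areas at once (conditionally independent given u, alpha)
    base = E * np.exp(alpha + u)
    dv = steps.v / np.sqrt(tau_v + ws.O + 1.0) * rng.standard_normal(n)
    v_new = v + dv
    dlp = O * dv - base * (np.exp(v_new) - np.exp(v)) \
        - 0.5 * tau_v * (v_new ** 2 - v ** 2)
    accept = np.log(rng.random(n)) < dlp
    v[accept] = v_new[accept]
    steps.acc_v[accept] += 1

    # joint field-rescaling moves: (x, tau) -> (c x, tau / c^2) with c = e^eps.
    # The ICAR (resp. Normal) kernel is invariant under the pair, so the move
    # trades field scale against precision directly — the slowly mixing
    # direction of the BYM posterior — while targeting the same density.
    if cfg.fixed_tau_u is None:
        eps = 0.2 * rng.standard_normal()
        c = math.exp(eps)
        lam = E * np.exp(alpha + v)
        dlp = (
            float(O @ (c * u - u)) - float(lam @ (np.exp(c * u) - np.exp(u)))
            + (n - 1 - ws.rank_u - 2 * a_u) * eps
            - b_u * tau_u * (math.exp(-2 * eps) - 1.0)
        )
        if math.log(rng.random()) < dlp:
            u *= c
            tau_u /= c * c
    if cfg.fixed_tau_v is None:
        eps = 0.2 * rng.standard_normal()
        c = math.exp(eps)
        lam = E * np.exp(alpha + u)
        dlp = (
            float(O @ (c * v - v)) - float(lam @ (np.exp(c * v) - np.exp(v)))
            - 2.0 * a_v * eps
            - b_v * tau_v * (math.exp(-2 * eps) - 1.0)
        )
        if math.log(rng.random()) < dlp:
            v *= c
            tau_v /= c * c

    # identifiability: recenter u, alpha absorbs the mean
    shift = float(u.mean())
    u -= shift
    alpha += shift

    steps.n_sweeps += 1
    if adapt and steps.n_sweeps % cfg.adapt_interval == 0:
        k = cfg.adapt_interval
        for arr, acc in ((steps.u, steps.acc_u), (steps.v, steps.acc_v)):
            rate = acc / k
            arr *= np.exp(0.6 * (rate - 0.4))
            np.clip(arr, 1e-3, 10.0, out=arr)
            acc[:] = 0
        rate_a = steps.acc_alpha / k
        steps.alpha = float(np.clip(steps.alpha * math.exp(0.6 * (rate_a - 0.4)),
                                    1e-4, 10.0))
        steps.acc_alpha = 0

    return BYMState(alpha=alpha, u=u, v=v, tau_u=tau_u, tau_v=tau_v)


def gibbs_sweep(
    state: BYMState,
    counts: CountData,
    weights: SpatialWeights,
    rng: np.random.Generator,
    config: MCMCConfig | None = None,
) -> BYMState:
    """One full Metropolis-within-Gibbs update of every parameter.

    Convenience wrapper around the sweep used by :func:`fit_bym`; step sizes
    are fixed at their initial values (no adaptation across single calls).
    """
    cfg = config or MCMCConfig()
    ws = _Workspace(counts, weights, cfg.allow_islands)
    st = BYMState(alpha=state.alpha, u=state.u.copy(), v=state.v.copy(),
                  tau_u=state.tau_u, tau_v=state.tau_v)
    return _sweep(st, ws, cfg, rng, _new_steps(ws.n), adapt=False)


@dataclass
class BYMPosterior:
    """Kept posterior draws from a single chain."""

    area_ids: list[str]
    theta: np.ndarray       # (n_kept, n_areas)
    alpha: np.ndarray       # (n_kept,)
    tau_u: np.ndarray
    tau_v: np.ndarray
    config: MCMCConfig

    @property
    def n_kept(self) -> int:
        return self.theta.shape[0]


@dataclass
class PosteriorSummary:
    """Per-area posterior median relative risk, 95% credible interval,
    significance class and risk band."""

    frame: pd.DataFrame  # area_id, median_rr, ci_low, ci_high, significance, risk_band

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def classify_significance(ci_low: float, ci_high: float) -> Significance:
    """Credible-interval rule: significantly high when the interval lies
    wholly above 1, significantly low when wholly below 1."""
    if ci_low > 1.0:
        return Significance.high
    if ci_high < 1.0:
        return Significance.low
    return Significance.none


def risk_band(median_rr: float) -> RiskBand:
    """Band relative to the state average: at/below average, 1–100% above,
    or more than 100% above (risk more than doubled)."""
    if median_rr <= 0:
        raise ValueError("median relative risk must be positive")
    if median_rr <= 1.0:
        return RiskBand.at_or_below_average
    if median_rr <= 2.0:
        return RiskBand.above_average_within_100pct
    return RiskBand.above_100pct


def summarize_posterior(post: BYMPosterior) -> PosteriorSummary:
    med = np.median(post.theta, axis=0)
    lo = np.percentile(post.theta, 2.5, axis=0)
    hi = np.percentile(post.theta, 97.5, axis=0)
    frame = pd.DataFrame(
        {
            "area_id": post.area_ids,
            "median_rr": med,
            "ci_low": lo,
            "ci_high": hi,
            "significance": [classify_significance(a, b).value
                             for a, b in zip(lo, hi)],
            "risk_band": [risk_band(m).value for m in med],
        }
    )
    return PosteriorSummary(frame=frame)


def fit_bym(
    counts: CountData,
    weights: SpatialWeights,
    config: MCMCConfig | None = None,
    monitor_thetas: int = 3,
) -> tuple[BYMPosterior, PosteriorSummary, dict]:
    """Run the single-chain sampler and summarize the smoothed risks.

    Returns the kept draws, the per-area summary (median, 95% credible
    interval, significance, risk band) and a diagnostics report with Geweke
    z-scores for alpha, the precisions and ``monitor_thetas`` randomly chosen
    area risks, plus final acceptance rates.  Deterministic given
    ``config.seed``.
    """
    from .diagnostics import geweke_diagnostic

    cfg = config or MCMCConfig()
    cfg.validate_schedule()
    ws = _Workspace(counts, weights, cfg.allow_islands)
    rng = np.random.default_rng(cfg.seed)

    state = BYMState(
        alpha=math.log(max(ws.O.sum(), 0.5) / ws.E.sum()),
        u=np.zeros(ws.n),
        v=np.zeros(ws.n),
        tau_u=cfg.fixed_tau_u or 1.0,
        tau_v=cfg.fixed_tau_v or 1.0,
    )
    steps = _new_steps(ws.n)

    n_burn, thin = cfg.n_burn, cfg.thin
    theta_draws = np.empty((cfg.n_kept, ws.n))
    alpha_draws = np.empty(cfg.n_kept)
    tau_u_draws = np.empty(cfg.n_kept)
    tau_v_draws = np.empty(cfg.n_kept)
    k = 0
    for t in range(1, cfg.n_iter + 1):
        state = _sweep(state, ws, cfg, rng, steps, adapt=t <= n_burn)
        if t == n_burn:  # steps frozen from here; count post-burn-in acceptance
            steps.acc_alpha = 0
            steps.acc_u[:] = 0
            steps.acc_v[:] = 0
        if t > n_burn and (t - n_burn) % thin == 0:
            theta_draws[k] = state.theta
            alpha_draws[k] = state.alpha
            tau_u_draws[k] = state.tau_u
            tau_v_draws[k] = state.tau_v
            k += 1
    assert k == cfg.n_kept

    post = BYMPosterior(
        area_ids=list(counts.area_ids),
        theta=theta_draws,
        alpha=alpha_draws,
        tau_u=tau_u_draws,
        tau_v=tau_v_draws,
        config=cfg,
    )
    summary = summarize_posterior(post)

    monitored: dict[str, np.ndarray] = {"alpha": alpha_draws}
    if cfg.fixed_tau_u is None:
        monitored["tau_u"] = tau_u_draws
    if cfg.fixed_tau_v is None:
        monitored["tau_v"] = tau_v_draws
    pick = rng.choice(ws.n, size=min(monitor_thetas, ws.n), replace=False)
    for i in sorted(pick):
        monitored[f"theta[{counts.area_ids[i]}]"] = theta_draws[:, i]
    geweke = {}
    for name, chain in monitored.items():
        try:
            z = geweke_diagnostic(chain)
        except ValueError:
            z = float("nan")  # constant chain (e.g. perfectly mixed corner case)
        geweke[name] = {"z": z, "converged": bool(abs(z) < 1.96)}

    n_post = cfg.n_iter - n_burn
    diagnostics = {
        "geweke": geweke,
        "acceptance": {
            "alpha": steps.acc_alpha / n_post,
            "u_mean": float(np.mean(steps.acc_u)) / n_post,
            "v_mean": float(np.mean(steps.acc_v)) / n_post,
        },
        "n_kept": cfg.n_kept,
        "seed": cfg.seed,
        "smoothing_variance_ratio": float(
            np.var(summary.frame["median_rr"]) / max(np.var(raw_ratio(counts)), 1e-300)
        ),
    }
    return post, summary, diagnostics
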