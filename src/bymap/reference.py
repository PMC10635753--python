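"""Deterministic quadrature of the exact BYM posterior on tiny graphs.

For two or three areas with *fixed* precisions, the joint posterior over
(alpha, u, v) is low-dimensional enough to integrate on a dense grid.  The
structured effect is parameterized in an orthonormal basis of the sum-to-zero
subspace; the unstructured effects factorize per area given (alpha, u), so
they are integrated by one-dimensional quadrature and the per-area posterior
of log theta_i is accumulated into a fine histogram, from which any quantile
is read off.  This shares no code with the MCMC sampler and serves as its
validation oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["exact_posterior_quantiles"]


def _sum_zero_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace (n x (n-1))."""
    full = np.eye(n) - np.full((n, n), 1.0 / n)
    _, s, vt = np.linalg.svd(full)
    return vt[: n - 1].T  # columns orthonormal, each sums to zero


def exact_posterior_quantiles(
    observed: np.ndarray,
    expected: np.ndarray,
    edges: list[tuple[int, int]],
    tau_u: float,
    tau_v: float,
    quantiles: tuple[float, ...] = (0.025, 0.5, 0.975),
    n_alpha: int = 64,
    n_s: int = 48,
    n_v: int = 400,
    n_bins: int = 4000,
) -> np.ndarray:
    """Quantiles of each area's posterior relative risk theta_i.

    Model: O_i ~ Poisson(E_i exp(alpha + u_i + v_i)), flat prior on alpha,
    ICAR kernel exp(-tau_u/2 * sum_edges (u_i-u_j)^2) on the sum-to-zero
    subspace, v_i ~ Normal(0, 1/tau_v).  Returns an array of shape
    (n_areas, len(quantiles)).
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    n = O.size
    if n < 2 or n > 3:
        raise ValueError("quadrature oracle supports 2 or 3 areas only")
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])

    a0 = np.log((O.sum() + 0.5) / E.sum())
    alpha_grid = np.linspace(a0 - 3.5, a0 + 3.5, n_alpha)
    s_half = 4.0 / np.sqrt(tau_u) + 1.0
    v_half = 4.0 / np.sqrt(tau_v) + 1.0
    s_grid = np.linspace(-s_half, s_half, n_s)
    v_grid = np.linspace(-v_half, v_half, n_v)

    Q = _sum_zero_basis(n)
    # combo grid over (alpha, s_1[, s_2])
    mesh = np.meshgrid(alpha_grid, *([s_grid] * (n - 1)), indexing="ij")
    alpha = mesh[0].ravel()
    s = np.stack([m.ravel() for m in mesh[1:]], axis=1)  # (n_combo, n-1)
    u = s @ Q.T                                          # (n_combo, n)

    quad = 0.5 * np.sum((u[:, ei] - u[:, ej]) ** 2, axis=1)
    base = (O * (alpha[:, None] + u)).sum(axis=1) - tau_u * quad

    # per-area 1-D integrals over v and log-theta histogram accumulation
    lo = alpha_grid[0] + u.min() + v_grid[0] - 1e-9
    hi = alpha_grid[-1] + u.max() + v_grid[-1] + 1e-9
    bin_edges = np.linspace(lo, hi, n_bins + 1)
    hists = np.zeros((n, n_bins))

    chunk = max(1, 20_000_000 // (n_v * n))
    n_combo = alpha.size
    # first pass: total log-weight per combo, for a stable normalizer
    Z = np.empty((n_combo, n))
    for start in range(0, n_combo, chunk):
        sl = slice(start, min(start + chunk, n_combo))
        lam = E * np.exp(alpha[sl, None] + u[sl])        # (c, n)
        for i in range(n):
            g = (O[i] * v_grid[None, :]
                 - lam[:, i:i + 1] * np.exp(v_grid)[None, :]
                 - 0.5 * tau_v * v_grid[None, :] ** 2)
            Z[sl, i] = logsumexp(g, axis=1)
    tot = base + Z.sum(axis=1)
    shift = tot.max()

    for start in range(0, n_combo, chunk):
        sl = slice(start, min(start + chunk, n_combo))
        lam = E * np.exp(alpha[sl, None] + u[sl])
        for i in range(n):
            g = (O[i] * v_grid[None, :]
                 - lam[:, i:i + 1] * np.exp(v_grid)[None, :]
                 - 0.5 * tau_v * v_grid[None, :] ** 2)
            w = np.exp((tot[sl] - Z[sl, i] - shift)[:, None] + g)
            logtheta = alpha[sl, None] + u[sl, i:i + 1] + v_grid[None, :]
            idx = np.clip(
                np.searchsorted(bin_edges, logtheta.ravel()) - 1, 0, n_bins - 1
            )
            np.add.at(hists[i], idx, w.ravel())

    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    out = np.empty((n, len(quantiles)))
    for i in range(n):
        cdf = np.cumsum(hists[i])
        cdf /= cdf[-1]
        for qi, q in enumerate(quantiles):
            out[i, qi] = np.exp(centers[np.searchsorted(cdf, q)])
    return out
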