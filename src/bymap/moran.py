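"""Global Moran's I and local (LISA) spatial autocorrelation statistics.

The global statistic

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

measures whole-map clustering of a per-area variable (expectation -1/(n-1)
under no autocorrelation); its significance is assessed by Monte-Carlo
randomization of the values over the areas.  The local statistics
I_i = (z_i / m2) * sum_j w_ij z_j decompose it area by area; each area is
placed in a Moran-scatter quadrant (high-high, low-low, low-high, high-low)
and labelled a cluster/outlier when its conditional-permutation pseudo
p-value falls below alpha.  These are typically computed on the posterior
median smoothed risk surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .geography import SpatialWeights

__all__ = [
    "MoranResult",
    "LISAResult",
    "Quadrant",
    "global_moran",
    "moran_permutation_test",
    "local_moran",
    "lisa_significance",
]


class Quadrant(str, Enum):
    HH = "HH"
    LL = "LL"
    LH = "LH"
    HL = "HL"


_LABELS = {
    Quadrant.HH: "high_high",
    Quadrant.LL: "low_low",
    Quadrant.LH: "low_high",
    Quadrant.HL: "high_low",
}


@dataclass
class MoranResult:
    I: float
    expected_I: float
    n_perm: int
    p_perm: float
    seed: int | None = None
    permuted_Is: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"I": self.I, "expected_I": self.expected_I,
              "n_perm": self.n_perm, "p_perm": self.p_perm, "seed": self.seed}]
        )


@dataclass
class LISAResult:
    frame: pd.DataFrame  # area_id, value, z, lag, I_local, p_local, quadrant, label
    alpha: float
    n_perm: int
    seed: int | None = None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _check(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size != weights.n:
        raise ValueError("values must be one per area")
    if values.size < 3:
        raise ValueError("Moran statistics need at least 3 areas")
    if np.ptp(values) == 0:
        raise ValueError("values have zero variance; Moran's I is undefined")
    return values


def global_moran(values: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I of a per-area variable."""
    values = _check(values, weights)
    z = values - values.mean()
    W = weights.to_sparse()
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("weights have no links")
    return float(values.size / s0 * (z @ (W @ z)) / (z @ z))


def moran_permutation_test(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 99_999,
    seed: int | None = None,
    keep_permutations: bool = False,
) -> MoranResult:
    """Monte-Carlo randomization test for global Moran's I.

    Values are randomly reassigned to areas ``n_perm`` times; the pseudo
    p-value is one-sided toward the observed deviation from the expectation
    -1/(n-1): p = (#{permuted I at least as extreme} + 1) / (n_perm + 1).
    """
    values = _check(values, weights)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    n = values.size
    I_obs = global_moran(values, weights)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    W = weights.to_sparse()
    s0 = W.sum()
    z = values - values.mean()
    zz = float(z @ z)

    perm_I = np.empty(n_perm)
    batch = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        Z = z[order]
        perm_I[done:done + b] = n / s0 * np.einsum(
            "ij,ij->i", Z, (W @ Z.T).T) / zz
        done += b

    if I_obs >= expected:
        extreme = int(np.sum(perm_I >= I_obs))
    else:
        extreme = int(np.sum(perm_I <= I_obs))
    p = (extreme + 1) / (n_perm + 1)
    return MoranResult(
        I=I_obs, expected_I=expected, n_perm=n_perm, p_perm=p, seed=seed,
        permuted_Is=perm_I if keep_permutations else None,
    )


def _zlag(values: np.ndarray, weights: SpatialWeights):
    z = values - values.mean()
    lag = weights.to_sparse() @ z
    m2 = float(z @ z) / values.size
    return z, lag, m2


def _quadrant(zi: float, lagi: float) -> Quadrant:
    # tie rule: a zero deviation or zero lag counts as "high"
    if zi >= 0:
        return Quadrant.HH if lagi >= 0 else Quadrant.HL
    return Quadrant.LH if lagi >= 0 else Quadrant.LL


def local_moran(
    values: np.ndarray, weights: SpatialWeights
) -> tuple[np.ndarray, list[Quadrant]]:
    """Local Moran statistics I_i and Moran-scatter quadrants.

    With row-standardized weights and no islands, mean(I_i) equals the
    global I.
    """
    values = _check(values, weights)
    z, lag, m2 = _zlag(values, weights)
    I_local = z / m2 * lag
    quadrants = [_quadrant(zi, li) for zi, li in zip(z, lag)]
    return I_local, quadrants


def lisa_significance(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 99_999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> LISAResult:
    """Conditional-permutation significance of each local Moran statistic.

    For each area the remaining values are permuted over the other areas
    while the area's own value is held fixed; p_i is one-sided toward the
    sign of the observed I_i.  Areas with p_i <= alpha keep their quadrant
    label (high_high, low_low, low_high, high_low); the rest — and islands,
    whose lag is identically zero — are not_significant.
    """
    values = _check(values, weights)
    n = values.size
    z, lag, m2 = _zlag(values, weights)
    I_local = z / m2 * lag
    quadrants = [_quadrant(zi, li) for zi, li in zip(z, lag)]

    rng = np.random.default_rng(seed)
    card = weights.cardinalities
    p_local = np.ones(n)
    for i in range(n):  # fixed area order: reproducible under one seed
        k = card[i]
        if k == 0:
            p_local[i] = 1.0
            continue
        others = np.delete(z, i)
        picks = np.argsort(rng.random((n_perm, others.size)), axis=1)[:, :k]
        wrow = np.asarray(weights.weights[i], dtype=float)
        perm_lag = others[picks] @ wrow
        perm_I = z[i] / m2 * perm_lag
        if I_local[i] >= 0:
            extreme = int(np.sum(perm_I >= I_local[i]))
        else:
            extreme = int(np.sum(perm_I <= I_local[i]))
        p_local[i] = (extreme + 1) / (n_perm + 1)

    labels = []
    for i, q in enumerate(quadrants):
        if card[i] == 0 or p_local[i] > alpha:
            labels.append("not_significant")
        else:
            labels.append(_LABELS[q])
    frame = pd.DataFrame(
        {
            "area_id": weights.area_ids,
            "value": values,
            "z": z,
            "lag": lag,
            "I_local": I_local,
            "p_local": p_local,
            "quadrant": [q.value for q in quadrants],
            "label": labels,
        }
    )
    return LISAResult(frame=frame, alpha=alpha, n_perm=n_perm, seed=seed)
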