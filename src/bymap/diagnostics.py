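"""Single-chain MCMC convergence diagnostics.

With one chain, convergence is judged by the Geweke test — comparing the mean
of an early chain segment with a late one, scaled by spectral estimates of
each segment's long-run variance — together with visual trace, density and
autocorrelation plots.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["geweke_diagnostic", "autocorrelation", "trace_density_export"]


def _spectral_var_of_mean(x: np.ndarray) -> float:
    """Long-run variance of the segment mean: Bartlett-kernel (Newey–West)
    estimate of the spectral density at frequency zero, divided by n."""
    n = x.size
    xc = x - x.mean()
    lag_max = min(int(4 * (n / 100.0) ** 0.25), n - 1)
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for k in range(1, lag_max + 1):
        gamma_k = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (lag_max + 1.0)) * gamma_k
    return max(s, 0.0) / n


def geweke_diagnostic(
    chain: np.ndarray, frac_first: float = 0.1, frac_last: float = 0.5
) -> float:
    """Geweke z-score comparing the first ``frac_first`` of the chain with
    the last ``frac_last``; |z| < 1.96 is the conventional convergence gate.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.size < 100:
        raise ValueError(f"chain too short for Geweke ({chain.size} < 100)")
    if np.ptp(chain) == 0:
        raise ValueError("constant chain: Geweke variance is zero")
    first = chain[: int(frac_first * chain.size)]
    last = chain[int((1 - frac_last) * chain.size):]
    var = _spectral_var_of_mean(first) + _spectral_var_of_mean(last)
    if var == 0:
        raise ValueError("zero spectral variance in both segments")
    return float((first.mean() - last.mean()) / math.sqrt(var))


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (lag 0 is exactly 1)."""
    from statsmodels.tsa.stattools import acf

    chain = np.asarray(chain, dtype=float)
    if max_lag >= chain.size:
        raise ValueError("max_lag must be smaller than the chain length")
    return acf(chain, nlags=max_lag, fft=True)


def trace_density_export(
    draws: dict[str, np.ndarray], path_prefix, max_lag: int = 50
) -> list[str]:
    """Write trace/autocorrelation CSVs and a trace+density+acf figure per
    monitored scalar.  Returns the paths written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    csv_path = f"{path_prefix}_draws.csv"
    pd.DataFrame(draws).to_csv(csv_path, index=False)
    written.append(csv_path)
    acf_frame = {
        name: autocorrelation(chain, min(max_lag, len(chain) - 1))
        for name, chain in draws.items()
    }
    acf_path = f"{path_prefix}_acf.csv"
    pd.DataFrame(acf_frame).to_csv(acf_path, index_label="lag")
    written.append(acf_path)

    n = len(draws)
    fig, axes = plt.subplots(n, 3, figsize=(11, 2.4 * n), squeeze=False)
    for row, (name, chain) in enumerate(draws.items()):
        axes[row][0].plot(chain, lw=0.4)
        axes[row][0].set_ylabel(name)
        axes[row][1].hist(chain, bins=40, density=True)
        axes[row][2].bar(range(len(acf_frame[name])), acf_frame[name], width=0.8)
    axes[0][0].set_title("trace")
    axes[0][1].set_title("density")
    axes[0][2].set_title("autocorrelation")
    fig.tight_layout()
    png_path = f"{path_prefix}_diagnostics.png"
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    written.append(png_path)
    return written
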