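"""Expected counts by internal standardization and raw SIR/SMR.

Expected counts E_i are obtained by spreading the state-wide crude rate over
each area's population aged 15+, so that the state aggregate has ratio 1 by
construction (internal standardization).  Areas with zero recorded population
cannot carry an informative expectation; they receive a small positive
"uninformative" value (the overall rate times a notional population of one
person), are flagged, and are excluded from the conservation identity
sum(E) = sum(O).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountData", "compute_expected", "raw_ratio"]


@dataclass
class CountData:
    """Per-area observed counts O_i and expected counts E_i."""

    area_ids: list[str]
    observed: np.ndarray
    expected: np.ndarray
    uninformative_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.uninformative_flags is None:
            self.uninformative_flags = np.zeros(len(self.area_ids), dtype=bool)
        self.uninformative_flags = np.asarray(self.uninformative_flags, dtype=bool)
        n = len(self.area_ids)
        if not (self.observed.shape == self.expected.shape
                == self.uninformative_flags.shape == (n,)):
            raise ValueError("observed/expected/flags must match area_ids length")
        if np.any(self.observed < 0) or np.any(self.observed != np.round(self.observed)):
            raise ValueError("observed counts must be non-negative integers")
        if np.any(self.expected <= 0):
            raise ValueError("expected counts must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": self.area_ids,
                "observed": self.observed.astype(int),
                "expected": self.expected,
                "raw_ratio": raw_ratio(self),
                "uninformative_flag": self.uninformative_flags,
            }
        )


def compute_expected(
    observed: np.ndarray,
    population: np.ndarray,
    area_ids: list[str] | None = None,
) -> CountData:
    """Internally standardized expected counts from 15+ populations.

    The crude rate r = sum(O) / sum(population over populated areas) gives
    E_i = r * population_i.  Zero-population areas get E_i = r (a notional
    single person) and are flagged uninformative.
    """
    observed = np.asarray(observed, dtype=float)
    population = np.asarray(population, dtype=float)
    if observed.shape != population.shape:
        raise ValueError("observed and population must have the same length")
    if np.any(observed < 0):
        raise ValueError("negative observed counts")
    if np.any(population < 0):
        raise ValueError("negative populations")
    populated = population > 0
    if not populated.any():
        raise ValueError("all areas have zero population; no rate can be formed")
    if area_ids is None:
        area_ids = [str(i) for i in range(len(observed))]

    # Internal standardization: every case counts toward the state rate, even
    # those registered to zero-population areas, so sum(E) over populated
    # areas reproduces the full observed total.
    rate = observed.sum() / population[populated].sum()
    if rate <= 0:
        # degenerate all-zero-count input: keep E positive so Poisson defined
        rate = 1.0 / population[populated].sum()
    expected = np.where(populated, rate * population, rate)
    return CountData(
        area_ids=list(area_ids),
        observed=observed,
        expected=expected,
        uninformative_flags=~populated,
    )


def raw_ratio(counts: CountData) -> np.ndarray:
    """Unsmoothed SIR/SMR: O_i / E_i, with 1.0 the state average."""
    return counts.observed / counts.expected
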