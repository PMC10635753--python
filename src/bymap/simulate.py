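"""Synthetic geographies, risk surfaces, counts and registry cohorts.

Real cancer-registry extracts and census population tables are restricted
data; these generators emulate their structure so the whole mapping pipeline
is exercised end to end.  A geography is a rectangular lattice of unit
squares plus optional detached "island" cells (areas with no contiguous
neighbour) and a configurable fraction of zero-population areas.  The true
log-relative-risk surface is an exact ICAR draw (spatially structured) plus
independent Gaussian noise, counts are Poisson around E_i * theta_i, and the
patient-level registry generator reproduces the marginal mix of a large oral
and oropharyngeal cancer cohort: ~71.5% male, ~56% aged 65+, roughly half
oral-cavity tumours, ~59% deceased, survival times from a geometric-like
distribution truncated at 478 months.

The ICAR draw is exact (eigendecomposition of the graph Laplacian), so the
generator shares no code path with the MCMC fitter — a generator bug cannot
mask a fitter bug, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .cohort import (
    DEFAULT_SUBSITE_MAP,
    RegistryRecord,
    Sex,
    SiteClass,
    VitalStatus,
)
from .geography import AreaUnit, SpatialWeights, write_areas_geojson

__all__ = [
    "SimulationSpec",
    "RegistryMarginals",
    "simulate_geography",
    "simulate_icar_field",
    "simulate_counts",
    "simulate_registry",
    "demo_dataset",
]

SURVIVAL_MAX_MONTHS = 478  # longest follow-up a registry of this span can hold


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth configuration of a synthetic study region."""

    nx: int = 10
    ny: int = 10
    n_islands: int = 0
    zero_pop_fraction: float = 0.0
    base_population: int = 10_000
    alpha_true: float = 0.0
    sigma_u: float = 0.5
    sigma_v: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx * self.ny < 4:
            raise ValueError("lattice must have at least 4 cells")
        if not 0.0 <= self.zero_pop_fraction < 1.0:
            raise ValueError("zero_pop_fraction must lie in [0, 1)")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise ValueError("sigma_u and sigma_v must be non-negative")


def simulate_geography(spec: SimulationSpec, geojson_path=None) -> list[AreaUnit]:
    """Unit-square lattice plus detached island cells, with populations.

    Exactly ``floor(zero_pop_fraction * n_areas)`` areas get population 0;
    the rest get ``base_population`` with ±20% seeded jitter.
    """
    rng = np.random.default_rng(spec.seed)
    areas: list[AreaUnit] = []
    for r in range(spec.ny):
        for c in range(spec.nx):
            areas.append(
                AreaUnit(
                    area_id=f"cell_{r}_{c}",
                    name=f"Lattice cell ({r},{c})",
                    geometry=box(c, r, c + 1, r + 1),
                )
            )
    for k in range(spec.n_islands):
        x0 = spec.nx + 2 + 2 * k  # gap of 1 unit: no shared boundary with anything
        areas.append(
            AreaUnit(
                area_id=f"island_{k}",
                name=f"Island {k}",
                geometry=box(x0, 0, x0 + 1, 1),
            )
        )
    n = len(areas)
    n_zero = int(spec.zero_pop_fraction * n)
    zero_idx = set(rng.choice(n, size=n_zero, replace=False).tolist())
    jitter = rng.uniform(0.8, 1.2, size=n)
    for i, a in enumerate(areas):
        a.population_15plus = 0 if i in zero_idx else max(
            1, int(round(spec.base_population * jitter[i]))
        )
    if geojson_path is not None:
        write_areas_geojson(areas, geojson_path)
    return areas


def simulate_icar_field(
    weights: SpatialWeights, sigma_u: float, seed: int | None = None
) -> np.ndarray:
    """Exact draw of a sum-to-zero ICAR field with scale ``sigma_u``.

    The covariance is sigma_u^2 times the Moore–Penrose pseudo-inverse of the
    graph Laplacian D - W, sampled through its eigendecomposition.  Requires
    a connected graph (repair islands first).
    """
    n = weights.n
    if sigma_u == 0:
        return np.zeros(n)
    W = weights.to_sparse().toarray()
    lap = np.diag(W.sum(axis=1)) - W
    evals, evecs = np.linalg.eigh(lap)
    null = evals < 1e-10
    if null.sum() != 1:
        raise ValueError(
            "graph is disconnected; link islands before simulating an ICAR field"
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    keep = ~null
    u = evecs[:, keep] @ (z[keep] / np.sqrt(evals[keep])) * sigma_u
    return u - u.mean()  # exact draws already sum to zero; guard rounding


def simulate_counts(
    expected: np.ndarray, theta_true: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """Poisson observed counts O_i ~ Poisson(E_i * theta_i)."""
    expected = np.asarray(expected, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.poisson(expected * theta_true)


def demo_dataset(seed: int = 0, nx: int = 6, ny: int = 6,
                 base_expected: float = 50.0):
    """Small self-contained mapping problem: a 6x6 lattice with a BYM-true
    risk surface (sigma_u = 0.5, sigma_v = 0.1) and internally standardized
    expected counts.  Returns (areas, weights, counts, theta_true)."""
    from .geography import build_rook_adjacency
    from .standardization import CountData

    spec = SimulationSpec(nx=nx, ny=ny, sigma_u=0.5, sigma_v=0.1, seed=seed)
    areas = simulate_geography(spec)
    weights = build_rook_adjacency(areas)
    n = len(areas)
    u = simulate_icar_field(weights, spec.sigma_u, seed=seed + 1)
    v = np.random.default_rng(seed + 2).standard_normal(n) * spec.sigma_v
    theta = np.exp(spec.alpha_true + u + v)
    E = np.full(n, base_expected)
    O = simulate_counts(E, theta, seed=seed + 3)
    E_std = E * O.sum() / E.sum()  # internal standardization
    counts = CountData(area_ids=[a.area_id for a in areas],
                       observed=O, expected=E_std)
    return areas, weights, counts, theta


# ---------------------------------------------------------------------------
# registry records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryMarginals:
    """Marginal mix of the generated cohort.

    Defaults reproduce the published descriptive profile of a 1982–2018
    state-wide oral/oropharyngeal cancer cohort; the small under-15 mass
    exercises the adult-cohort exclusion rule.
    """

    p_male: float = 0.715
    # age bands <40 / 40-64 / >=65 among included patients
    p_age_bands: tuple[float, float, float] = (0.029, 0.408, 0.563)
    p_under15: float = 0.0002
    # oral_cavity / oropharynx / not_specified
    p_site: tuple[float, float, float] = (0.521, 0.463, 0.016)
    p_dead: float = 0.593
    grade_levels: tuple[str, ...] = (
        "well_differentiated", "moderately_differentiated",
        "poorly_differentiated", "undifferentiated", "unknown",
    )
    p_grade: tuple[float, ...] = (0.115, 0.494, 0.239, 0.003, 0.149)
    # survival: geometric-like, month granular, median ~= 60 months
    survival_geometric_p: float = 0.0115


_SITE_LABELS = {
    SiteClass.oral_cavity: sorted(
        k for k, v in DEFAULT_SUBSITE_MAP.items() if v == SiteClass.oral_cavity
    ),
    SiteClass.oropharynx: sorted(
        k for k, v in DEFAULT_SUBSITE_MAP.items() if v == SiteClass.oropharynx
    ),
}

_AGE_RANGES = {0: (15, 39), 1: (40, 64), 2: (65, 95)}


def simulate_registry(
    n_patients: int,
    areas: list[AreaUnit],
    marginals: RegistryMarginals | None = None,
    seed: int | None = None,
) -> list[RegistryRecord]:
    """Draw patient-level records with the configured marginal mix.

    Residential areas are assigned proportional to area population; survival
    months (death or censoring time alike) come from a geometric-like
    distribution truncated at 478 months, independent of area — any spatial
    mortality signal belongs in the risk surface, not in patient rows.
    """
    m = marginals or RegistryMarginals()
    rng = np.random.default_rng(seed)
    if n_patients == 0:
        return []

    pops = np.array([a.population_15plus for a in areas], dtype=float)
    if pops.sum() <= 0:
        raise ValueError("all areas have zero population; cannot place patients")
    area_p = pops / pops.sum()
    area_idx = rng.choice(len(areas), size=n_patients, p=area_p)

    under15 = rng.random(n_patients) < m.p_under15
    bands = rng.choice(3, size=n_patients, p=np.asarray(m.p_age_bands))
    ages = np.empty(n_patients, dtype=int)
    for b, (lo, hi) in _AGE_RANGES.items():
        sel = bands == b
        ages[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))
    ages[under15] = rng.integers(0, 15, size=int(under15.sum()))

    male = rng.random(n_patients) < m.p_male
    sites = rng.choice(3, size=n_patients, p=np.asarray(m.p_site))
    dead = rng.random(n_patients) < m.p_dead
    grades = rng.choice(len(m.grade_levels), size=n_patients,
                        p=np.asarray(m.p_grade))
    survival = np.minimum(
        rng.geometric(m.survival_geometric_p, size=n_patients) - 1,
        SURVIVAL_MAX_MONTHS,
    )

    site_classes = [SiteClass.oral_cavity, SiteClass.oropharynx,
                    SiteClass.not_specified]
    records = []
    for k in range(n_patients):
        cls = site_classes[sites[k]]
        if cls is SiteClass.not_specified:
            subsite = "unspecified"
        else:
            labels = _SITE_LABELS[cls]
            subsite = labels[rng.integers(len(labels))]
        records.append(
            RegistryRecord(
                patient_id=f"P{k:06d}",
                age_at_diagnosis=int(ages[k]),
                sex=Sex.male if male[k] else Sex.female,
                subsite=subsite,
                area_id=areas[area_idx[k]].area_id,
                vital_status=VitalStatus.dead if dead[k] else VitalStatus.alive,
                survival_months=int(survival[k]),
                grade=m.grade_levels[grades[k]],
            )
        )
    return records
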