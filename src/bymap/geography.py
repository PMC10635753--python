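"""Spatial units, rook contiguity weights, and weights-file I/O.

Areas are planar polygons (an ``AreaUnit`` each); the neighbour structure is a
:class:`SpatialWeights` object holding, for every area, the list of contiguous
areas and their weights.  Rook contiguity links two areas only when their
boundaries share a linear segment of strictly positive length — touching at a
corner point does not count.  Areas with no contiguous neighbour ("islands",
e.g. actual offshore islands in a coastal geography) are flagged rather than
silently linked; the analyst repairs them explicitly with
:func:`apply_manual_links`, mirroring how disease-mapping studies handle them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from shapely import set_precision
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "AreaLevel",
    "AreaUnit",
    "WeightStyle",
    "SpatialWeights",
    "build_rook_adjacency",
    "apply_manual_links",
    "row_standardize",
    "read_weights_gal",
    "write_weights_gal",
    "read_areas_geojson",
    "write_areas_geojson",
]


class AreaLevel(str, Enum):
    """Granularity of a spatial unit: coarse (LGA-like) or fine (suburb-like)."""

    coarse = "coarse"
    fine = "fine"


@dataclass
class AreaUnit:
    """One small area: identifier, polygon geometry and 15+ population."""

    area_id: str
    geometry: BaseGeometry
    name: str = ""
    level: AreaLevel = AreaLevel.coarse
    population_15plus: int = 0

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError(f"area {self.area_id!r}: empty geometry")
        if self.population_15plus < 0:
            raise ValueError(f"area {self.area_id!r}: negative population")


class WeightStyle(str, Enum):
    binary = "binary"
    row_standardized = "row_standardized"


@dataclass
class SpatialWeights:
    """Neighbour lists and weights over an ordered set of areas.

    ``neighbors[i]`` holds indices of the areas contiguous to area ``i`` and
    ``weights[i]`` the matching non-negative weights (1.0 under the binary
    style; 1/m_i after row standardisation, m_i the neighbour count).
    """

    area_ids: list[str]
    neighbors: list[list[int]]
    weights: list[list[float]]
    style: WeightStyle = WeightStyle.binary
    manual_links: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if not (len(self.neighbors) == len(self.weights) == n):
            raise ValueError("area_ids, neighbors and weights must align")
        for i, (nbrs, wts) in enumerate(zip(self.neighbors, self.weights)):
            if len(nbrs) != len(wts):
                raise ValueError(f"row {i}: neighbor/weight length mismatch")
            if i in nbrs:
                raise ValueError(f"area {self.area_ids[i]!r} is its own neighbor")
        if self.style == WeightStyle.binary:
            sets = [set(nb) for nb in self.neighbors]
            for i, nbrs in enumerate(sets):
                for j in nbrs:
                    if i not in sets[j]:
                        raise ValueError(
                            f"binary adjacency not symmetric: "
                            f"{self.area_ids[i]!r}~{self.area_ids[j]!r}"
                        )

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def islands(self) -> list[int]:
        """Indices of areas with no neighbour."""
        return [i for i, nb in enumerate(self.neighbors) if not nb]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.intp)

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area_id {area_id!r}") from None

    def to_sparse(self):
        """Weights as a scipy CSR matrix (rows in area order)."""
        from scipy.sparse import csr_matrix

        indptr = np.cumsum([0] + [len(nb) for nb in self.neighbors])
        indices = np.concatenate([np.asarray(nb, dtype=np.intp) for nb in self.neighbors]
                                 ) if indptr[-1] else np.empty(0, dtype=np.intp)
        data = np.concatenate([np.asarray(w, dtype=float) for w in self.weights]
                              ) if indptr[-1] else np.empty(0, dtype=float)
        return csr_matrix((data, indices, indptr), shape=(self.n, self.n))

    def edge_list(self) -> list[tuple[int, int]]:
        """Each symmetric link once, as (i, j) with i < j."""
        return [(i, j) for i, nbrs in enumerate(self.neighbors) for j in nbrs if i < j]

    def copy(self) -> "SpatialWeights":
        return SpatialWeights(
            area_ids=list(self.area_ids),
            neighbors=[list(nb) for nb in self.neighbors],
            weights=[list(w) for w in self.weights],
            style=self.style,
            manual_links=list(self.manual_links),
        )


def build_rook_adjacency(
    areas: Sequence[AreaUnit], snap_grid: float = 1e-9
) -> SpatialWeights:
    """Rook first-order contiguity from polygon geometry.

    Two areas are neighbours iff their boundaries share a segment of strictly
    positive length; point contact is ignored.  Coordinates are snapped to a
    ``snap_grid`` lattice first so that sub-tolerance slivers in digitised
    boundaries do not break contiguity.
    """
    ids = [a.area_id for a in areas]
    seen: set[str] = set()
    for aid in ids:
        if aid in seen:
            raise ValueError(f"duplicate area_id {aid!r}")
        seen.add(aid)
    geoms = []
    for a in areas:
        g = a.geometry
        if not g.is_valid:
            raise ValueError(f"invalid geometry for area {a.area_id!r}")
        geoms.append(set_precision(g, snap_grid) if snap_grid > 0 else g)

    n = len(areas)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if inter.length > 0:  # rook: requires shared length, not points
                neighbors[i].append(j)
                neighbors[j].append(i)
    for nb in neighbors:
        nb.sort()
    weights = [[1.0] * len(nb) for nb in neighbors]
    return SpatialWeights(area_ids=ids, neighbors=neighbors, weights=weights)


def apply_manual_links(
    weights: SpatialWeights, links: Iterable[tuple[str, str]]
) -> SpatialWeights:
    """Add symmetric binary links by area id (island repair).

    Idempotent: a link already present is recorded but not duplicated.
    """
    w = weights.copy()
    for a, b in links:
        ia, ib = w.index_of(a), w.index_of(b)
        if ia == ib:
            raise ValueError(f"cannot link area {a!r} to itself")
        if (a, b) not in w.manual_links and (b, a) not in w.manual_links:
            w.manual_links.append((a, b))
        if ib not in w.neighbors[ia]:
            w.neighbors[ia].append(ib)
            w.weights[ia].append(1.0)
            w.neighbors[ib].append(ia)
            w.weights[ib].append(1.0)
    for nb, wt in zip(w.neighbors, w.weights):
        order = np.argsort(nb, kind="stable")
        nb[:] = [nb[k] for k in order]
        wt[:] = [wt[k] for k in order]
    return w


def row_standardize(weights: SpatialWeights) -> SpatialWeights:
    """Divide each non-island row by its neighbour count so rows sum to 1."""
    if weights.style == WeightStyle.row_standardized:
        raise ValueError("weights are already row-standardized")
    w = weights.copy()
    for i, nbrs in enumerate(w.neighbors):
        if nbrs:
            w.weights[i] = [1.0 / len(nbrs)] * len(nbrs)
    w.style = WeightStyle.row_standardized
    return w


# ---------------------------------------------------------------------------
# GAL weights files
# ---------------------------------------------------------------------------

def write_weights_gal(weights: SpatialWeights, path) -> None:
    """Write contiguity structure as a GAL file.

    Dialect: first line the area count; then, per area, a line ``id k``
    followed by a line of the k neighbour ids (blank line when k = 0).
    """
    with open(path, "w") as fh:
        fh.write(f"{weights.n}\n")
        for i, aid in enumerate(weights.area_ids):
            nbrs = weights.neighbors[i]
            fh.write(f"{aid} {len(nbrs)}\n")
            fh.write(" ".join(weights.area_ids[j] for j in nbrs) + "\n")


def read_weights_gal(path) -> SpatialWeights:
    """Read a GAL contiguity file written by :func:`write_weights_gal`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty or missing header (line 1)")
    try:
        n = int(lines[0].split()[-1])
    except ValueError:
        raise ValueError(f"{path}: malformed header (line 1)") from None
    ids: list[str] = []
    raw_nbrs: list[list[str]] = []
    ln = 1
    for _ in range(n):
        if ln >= len(lines):
            raise ValueError(f"{path}: truncated file (line {ln + 1})")
        head = lines[ln].split()
        if len(head) != 2:
            raise ValueError(f"{path}: malformed area header (line {ln + 1})")
        aid, k_str = head
        try:
            k = int(k_str)
        except ValueError:
            raise ValueError(f"{path}: bad neighbor count (line {ln + 1})") from None
        nbr_line = lines[ln + 1].split() if ln + 1 < len(lines) else []
        if len(nbr_line) != k:
            raise ValueError(
                f"{path}: expected {k} neighbor ids, got {len(nbr_line)} "
                f"(line {ln + 2})"
            )
        ids.append(aid)
        raw_nbrs.append(nbr_line)
        ln += 2
    index = {aid: i for i, aid in enumerate(ids)}
    neighbors: list[list[int]] = []
    for row_no, nbr_ids in enumerate(raw_nbrs):
        row = []
        for nid in nbr_ids:
            if nid not in index:
                raise ValueError(
                    f"{path}: dangling neighbor id {nid!r} (line {2 * row_no + 3})"
                )
            row.append(index[nid])
        neighbors.append(sorted(row))
    weights = [[1.0] * len(nb) for nb in neighbors]
    return SpatialWeights(area_ids=ids, neighbors=neighbors, weights=weights)


# ---------------------------------------------------------------------------
# GeoJSON areas
# ---------------------------------------------------------------------------

def read_areas_geojson(
    path,
    id_property: str = "area_id",
    population_property: str = "population_15plus",
) -> list[AreaUnit]:
    """Load areas from a GeoJSON FeatureCollection (one feature per area)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    areas = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"{path}: feature {k} lacks property {id_property!r}")
        level = props.get("level", "coarse")
        areas.append(
            AreaUnit(
                area_id=str(props[id_property]),
                name=str(props.get("name", "")),
                level=AreaLevel(level),
                geometry=shapely_shape(feat["geometry"]),
                population_15plus=int(props.get(population_property, 0)),
            )
        )
    return areas


def write_areas_geojson(
    areas: Sequence[AreaUnit],
    path,
    extra_properties: dict[str, dict] | None = None,
) -> None:
    """Write areas (plus optional per-area property dicts) as GeoJSON."""
    features = []
    for a in areas:
        props = {
            "area_id": a.area_id,
            "name": a.name,
            "level": a.level.value,
            "population_15plus": int(a.population_15plus),
        }
        if extra_properties and a.area_id in extra_properties:
            props.update(extra_properties[a.area_id])
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": shapely_mapping(a.geometry),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
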