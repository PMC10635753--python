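import numpy as np
import pytest
from shapely.geometry import box

from bymap import AreaUnit, SimulationSpec, build_rook_adjacency, simulate_geography


def lattice_areas(nx: int, ny: int) -> list[AreaUnit]:
    return [
        AreaUnit(area_id=f"cell_{r}_{c}", geometry=box(c, r, c + 1, r + 1))
        for r in range(ny)
        for c in range(nx)
    ]


@pytest.fixture(scope="session")
def grid3():
    """3x3 lattice of unit squares with its rook weights."""
    areas = lattice_areas(3, 3)
    return areas, build_rook_adjacency(areas)


@pytest.fixture(scope="session")
def grid5_weights():
    return build_rook_adjacency(lattice_areas(5, 5))


@pytest.fixture(scope="session")
def grid4_weights():
    return build_rook_adjacency(lattice_areas(4, 4))
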