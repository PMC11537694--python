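import numpy as np
import pytest

from priormap.geodata import CategoricalLayer, ContinuousLayer, Grid


@pytest.fixture
def grid5() -> Grid:
    """5x5 grid of 100 m cells with origin at (0, 500)."""
    return Grid(n_rows=5, n_cols=5, cell_size=100.0, origin_x=0.0, origin_y=500.0)


@pytest.fixture
def grid30() -> Grid:
    return Grid(n_rows=30, n_cols=30, cell_size=100.0, origin_x=0.0, origin_y=3000.0)


def make_continuous(grid: Grid, values) -> ContinuousLayer:
    return ContinuousLayer(grid, np.asarray(values, dtype=float))


def make_categorical(grid: Grid, values) -> CategoricalLayer:
    return CategoricalLayer(grid, np.asarray(values))
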