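import numpy as np
import pytest

from gridpatterns.grid import GridSpec, build_adjacency
from gridpatterns.io import SliceView


@pytest.fixture(scope="session")
def default_spec():
    return GridSpec()


@pytest.fixture(scope="session")
def default_adjacency(default_spec):
    return build_adjacency(default_spec)


@pytest.fixture(scope="session")
def plain_spec():
    """Default-size grid with no severed interfaces."""
    return GridSpec(discrepancy_interfaces=())


def make_slice(rows, gene="g", timepoint="E11.5"):
    """Build a SliceView from a list of DV-rows of values (None = missing).

    ``rows[j][i]`` is the value at (ap=i+1, dv=j+1).
    """
    n_dv = len(rows)
    n_ap = len(rows[0])
    values = np.full((n_ap, n_dv), np.nan)
    for j, row in enumerate(rows):
        for i, v in enumerate(row):
            if v is not None:
                values[i, j] = v
    return SliceView(gene, timepoint, values)


def make_line_slice(values, gene="g", timepoint="E11.5"):
    """1-D slice: one DV layer, values along the AP axis."""
    return make_slice([list(values)], gene=gene, timepoint=timepoint)


@pytest.fixture
def line7():
    """The worked 1-D profile whose sweep has runs 1 / 2 / 1."""
    return make_line_slice([0.1, 0.5, 0.6, 0.1, 0.7, 0.8, 0.1])
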