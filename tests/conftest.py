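import numpy as np
import pytest

from termite_transport import (
    BehaviorParams,
    IrregularityLayout,
    WorldState,
    build_tunnel,
)


@pytest.fixture
def default_tunnel():
    return build_tunnel()


@pytest.fixture
def small_tunnel():
    """101-site fixture tunnel with one short curvature zone."""
    return build_tunnel(length_cells=101, curvature_zones=((30, 40),))


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def make_world(
    tunnel,
    positions,
    directions,
    cargo=None,
    params=None,
    irregular_sites=(),
    k3=1,
    k4=1,
):
    """Hand-built world for scripted scenarios."""
    n = len(positions)
    layout = IrregularityLayout(sites=frozenset(irregular_sites), k3=k3, k4=k4)
    return WorldState(
        tunnel=tunnel,
        layout=layout,
        params=params or BehaviorParams(),
        pos=np.asarray(positions, dtype=np.int64),
        dirn=np.asarray(directions, dtype=np.int64),
        cargo=np.asarray(
            cargo if cargo is not None else [-1] * n, dtype=np.int64
        ),
        state=np.zeros(n, dtype=np.uint8),
        timer=np.zeros(n, dtype=np.int64),
    )
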