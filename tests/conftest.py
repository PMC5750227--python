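import numpy as np
import pandas as pd
import pytest

from netspread.atlas import ParcelAtlas, VertexSurface
from netspread.synthkit import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig.small(seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One desk-scale synthetic study shared across tests."""
    return generate_dataset(small_config)


def make_atlas(cortical_xyz, subcortical_xyz=(), names=None):
    """Hand-built atlas: cortical parcels (hemisphere from sign of x), then
    subcortical ones (hemisphere M unless named with _L/_R)."""
    rows = []
    pid = 1
    for x, y, z in cortical_xyz:
        rows.append(dict(parcel_id=pid, hemisphere="L" if x < 0 else "R",
                         tissue="cortical", x=x, y=y, z=z, network=pd.NA,
                         name=f"c{pid}"))
        pid += 1
    for k, (x, y, z) in enumerate(subcortical_xyz):
        name = names[k] if names else f"s{pid}"
        hemi = "L" if name.endswith("_L") else "R" if name.endswith("_R") else "M"
        rows.append(dict(parcel_id=pid, hemisphere=hemi, tissue="subcortical",
                         x=x, y=y, z=z, network=pd.NA, name=name))
        pid += 1
    return ParcelAtlas(pd.DataFrame(rows))


def make_surface(positions, hemispheres, edges=()):
    v = pd.DataFrame(dict(
        vertex_id=np.arange(1, len(positions) + 1),
        x=[p[0] for p in positions],
        y=[p[1] for p in positions],
        z=[p[2] for p in positions],
        hemisphere=list(hemispheres),
    ))
    return VertexSurface(v, np.array(list(edges), dtype=int).reshape(-1, 2))
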