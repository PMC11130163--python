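import dataclasses

import pytest

from spineclust.core_io import Dendrite, SpineDataset, SpineRecord
from spineclust.synthetic_data import (
    SimulationConfig,
    UE_PRESET,
    VPA_PRESET,
    generate_spine_dataset,
)


def make_dataset(dendrites, spines, **kwargs) -> SpineDataset:
    """Compact builder: dendrites as (id, length), spines as
    (id, dendrite_id, position, present[, volume])."""
    ds = [Dendrite(d_id, length) for d_id, length in dendrites]
    ss = []
    for row in spines:
        vol = row[4] if len(row) > 4 else None
        ss.append(SpineRecord(row[0], row[1], row[2], tuple(row[3]), vol))
    return SpineDataset(ds, ss, **kwargs)


@pytest.fixture(scope="session")
def ue_dataset():
    return generate_spine_dataset(dataclasses.replace(UE_PRESET, n_dendrites=14, seed=3))


@pytest.fixture(scope="session")
def vpa_dataset():
    return generate_spine_dataset(dataclasses.replace(VPA_PRESET, n_dendrites=12, seed=3))


@pytest.fixture(scope="session")
def clustered_dataset():
    cfg = dataclasses.replace(
        VPA_PRESET, n_dendrites=12, cluster_bias=0.8, cluster_scale_um=3.0, seed=11
    )
    return generate_spine_dataset(cfg)
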