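import numpy as np
import pytest

from occtile.genome import GenomeSpec, ProbeGrid, build_probe_grid
from occtile.occupancy import CHANNEL, RATIO, OccupancyTrack


def make_grid(n_probes: int, circular: bool = False, probe_length: int = 60,
              period: int = 105) -> ProbeGrid:
    """A grid of exactly n_probes probes on a matching genome."""
    length = n_probes * period
    grid = build_probe_grid(GenomeSpec(length, circular), probe_length, period)
    assert grid.count == n_probes
    return grid


def ratio_track(values, circular: bool = False) -> OccupancyTrack:
    values = np.asarray(values, dtype=float)
    return OccupancyTrack(make_grid(len(values), circular), values, RATIO)


def channel_track(grid: ProbeGrid, values) -> OccupancyTrack:
    return OccupancyTrack(grid, np.asarray(values, dtype=float), CHANNEL)


@pytest.fixture
def grid10() -> ProbeGrid:
    return make_grid(10)
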