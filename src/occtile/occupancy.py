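"""Per-probe occupancy tracks: channel normalization and mutant/WT ratios.

A two-color hybridization yields one fluorescence value per probe per
channel (wild type = Cy3, mutant = Cy5). The quantity analysed downstream
is the per-probe mutant/wild-type ratio, oriented so that a value above 1
means increased mutant occupancy. Ratios are kept linear, not log2, because
the screening cutoffs (5 on the increased side, 0.2 on the decreased side)
are linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ProbeGrid

CHANNEL = "channel"
RATIO = "ratio"

#: Default pseudocount (fluorescence units) guarding ratios at background probes.
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True, eq=False)
class OccupancyTrack:
    """One value per probe: a fluorescence channel or a dimensionless ratio."""

    grid: ProbeGrid
    values: np.ndarray
    kind: str = CHANNEL

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.kind not in (CHANNEL, RATIO):
            raise ValueError(f"kind must be {CHANNEL!r} or {RATIO!r}")
        if self.values.shape != (self.grid.count,):
            raise ValueError(
                f"track has {self.values.shape} values for {self.grid.count} probes"
            )
        if self.kind == CHANNEL and np.any(self.values < 0):
            raise ValueError("channel intensities must be >= 0")
        if self.kind == RATIO and np.any(self.values <= 0):
            raise ValueError("ratio values must be > 0")

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "OccupancyTrack":
        return OccupancyTrack(self.grid, values, kind or self.kind)


def normalize_channels(
    wt: OccupancyTrack, mut: OccupancyTrack, method: str = "median-ratio"
) -> tuple[OccupancyTrack, OccupancyTrack]:
    """Rescale the mutant channel against wild type.

    ``median-ratio`` divides the mutant channel by the genome-wide median of
    mut/wt so that the bulk of probes (assumed unchanged) sit at ratio 1;
    differential regions covering a small minority of probes leave the
    median essentially untouched. ``none`` is the identity.
    """
    if wt.grid is not mut.grid and wt.grid != mut.grid:
        raise ValueError("channel tracks must share a probe grid")
    if wt.kind != CHANNEL or mut.kind != CHANNEL:
        raise ValueError("normalize_channels expects channel tracks")
    if method == "none":
        return wt, mut
    if method != "median-ratio":
        raise ValueError(f"unknown normalization method {method!r}")
    if np.all(wt.values == 0) or np.all(mut.values == 0):
        raise ValueError("cannot median-normalize an all-zero channel")
    ok = (wt.values > 0) & (mut.values > 0)
    if not ok.any():
        raise ValueError("no probe has positive intensity in both channels")
    factor = float(np.median(mut.values[ok] / wt.values[ok]))
    if factor == 0:
        raise ValueError("median mut/wt ratio is zero; cannot rescale")
    return wt, mut.with_values(mut.values / factor)


def probe_ratio(
    mut: OccupancyTrack,
    wt: OccupancyTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> OccupancyTrack:
    """Per-probe (mut + pc) / (wt + pc) ratio track.

    Oriented mutant/wild-type: values above 1 mark probes where the mutant
    polymerase accumulates relative to wild type.
    """
    if wt.grid is not mut.grid and wt.grid != mut.grid:
        raise ValueError("tracks must share a probe grid")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = wt.values + pseudocount
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise ZeroDivisionError(
            f"wild-type intensity + pseudocount is zero at probe {bad[0]}"
        )
    return OccupancyTrack(wt.grid, (mut.values + pseudocount) / denom, RATIO)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def tracks_to_tsv(wt: OccupancyTrack, mut: OccupancyTrack, path: str | Path) -> None:
    """Write paired channel tracks as `probe_index start end wt_intensity mut_intensity`."""
    grid = wt.grid
    df = pd.DataFrame(
        {
            "probe_index": np.arange(grid.count),
            "start": list(grid.starts),
            "end": [s + grid.probe_length for s in grid.starts],
            "wt_intensity": wt.values,
            "mut_intensity": mut.values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def tracks_from_tsv(path: str | Path, grid: ProbeGrid) -> tuple[OccupancyTrack, OccupancyTrack]:
    df = pd.read_csv(path, sep="\t")
    if len(df) != grid.count:
        raise ValueError(f"{path}: {len(df)} rows for a {grid.count}-probe grid")
    wt = OccupancyTrack(grid, df["wt_intensity"].to_numpy(), CHANNEL)
    mut = OccupancyTrack(grid, df["mut_intensity"].to_numpy(), CHANNEL)
    return wt, mut


def ratio_to_tsv(ratio: OccupancyTrack, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_index": np.arange(ratio.grid.count), "ratio": ratio.values}
    ).to_csv(path, sep="\t", index=False)


def ratio_from_tsv(path: str | Path, grid: ProbeGrid) -> OccupancyTrack:
    df = pd.read_csv(path, sep="\t")
    return OccupancyTrack(grid, df["ratio"].to_numpy(), RATIO)
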