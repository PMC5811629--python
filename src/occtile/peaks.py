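"""Peak calling and quantification on a mutant/WT ratio track.

A peak is a maximal run of consecutive probes whose ratio clears a
threshold — at least 5 on the increased side by default, at most 0.2 on the
decreased side. Runs of a single probe are discarded: an immunoprecipitated
fragment of ~250 bp must hybridize to two or more probes of a 60-bp/105-bp
grid, so an isolated one-probe signal is background. Each peak is then
quantified by combining the fluorescence of its probes into one level, the
ranking statistic of the increased/decreased gene tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .occupancy import RATIO, OccupancyTrack

INCREASED = "increased"
DECREASED = "decreased"

DEFAULT_CUTOFF_UP = 5.0
DEFAULT_CUTOFF_DOWN = 0.2
DEFAULT_MIN_PROBES = 2


@dataclass(frozen=True)
class Peak:
    """A maximal run of above/below-threshold probes with a combined level.

    ``probe_indices`` are in genomic run order; for a peak wrapping the
    circular origin they jump from the last grid index back to 0 and
    ``wraps_origin`` is set. ``level`` is filled by :func:`quantify_peak`.
    """

    probe_indices: tuple[int, ...]
    start: int
    end: int
    direction: str
    per_probe_ratios: tuple[float, ...]
    level: Optional[float] = None
    method: Optional[str] = None
    wraps_origin: bool = False

    @property
    def n_probes(self) -> int:
        return len(self.probe_indices)

    @property
    def first_probe(self) -> int:
        return self.probe_indices[0]

    @property
    def last_probe(self) -> int:
        return self.probe_indices[-1]

    def midpoint(self, genome_length: Optional[int] = None) -> int:
        if not self.wraps_origin:
            return (self.start + self.end) // 2
        if genome_length is None:
            raise ValueError("genome_length required for a wrapped peak midpoint")
        span = (self.end + genome_length) - self.start
        return (self.start + span // 2) % genome_length


def _qualifying_runs(
    qualifies: np.ndarray, max_gap: int
) -> list[tuple[int, int]]:
    """Maximal (first, last) index runs of True, tolerating gaps <= max_gap.

    Run endpoints always qualify; interior sub-threshold probes are absorbed
    only when the gap between qualifying probes is at most ``max_gap``.
    """
    idx = np.flatnonzero(qualifies)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    runs = []
    lo = 0
    for b in breaks:
        runs.append((int(idx[lo]), int(idx[b])))
        lo = b + 1
    runs.append((int(idx[lo]), int(idx[-1])))
    return runs


def call_peaks(
    ratio: OccupancyTrack,
    cutoff_up: float = DEFAULT_CUTOFF_UP,
    cutoff_down: float = DEFAULT_CUTOFF_DOWN,
    min_probes: int = DEFAULT_MIN_PROBES,
    max_gap: int = 0,
) -> list[Peak]:
    """Call increased and decreased peaks from a ratio track.

    Thresholds are inclusive (>= cutoff_up, <= cutoff_down). Runs shorter
    than ``min_probes`` are dropped as background. On a circular genome a
    run touching both ends of the probe array is merged across the origin.
    Returned peaks are sorted by genomic start within each direction and
    never overlap within a direction.
    """
    if ratio.kind != RATIO:
        raise ValueError("call_peaks expects a ratio track")
    if not (cutoff_up > 1 > cutoff_down > 0):
        raise ValueError("need cutoff_up > 1 > cutoff_down > 0")
    values = ratio.values
    grid = ratio.grid
    circular = grid.genome.circular
    peaks: list[Peak] = []
    for direction, qualifies in (
        (INCREASED, values >= cutoff_up),
        (DECREASED, values <= cutoff_down),
    ):
        runs = _qualifying_runs(qualifies, max_gap)
        wrapped = False
        if circular and len(runs) >= 2:
            # merge across the origin when the inter-run gap (mod count) is small
            gap = (runs[0][0] + grid.count) - runs[-1][1] - 1
            if gap <= max_gap:
                first, last = runs.pop(0), runs.pop(-1)
                runs.append((last[0], first[1]))  # (start near end, end near 0)
                wrapped = True
        for first, last in runs:
            if wrapped and first > last:
                indices = tuple(range(first, grid.count)) + tuple(range(0, last + 1))
                wraps = True
            else:
                indices = tuple(range(first, last + 1))
                wraps = False
            if len(indices) < min_probes:
                continue
            start = grid.starts[indices[0]]
            end = grid.starts[indices[-1]] + grid.probe_length
            if wraps:
                end = end % grid.genome.length
            peaks.append(
                Peak(
                    probe_indices=indices,
                    start=start,
                    end=min(end, grid.genome.length) if not wraps else end,
                    direction=direction,
                    per_probe_ratios=tuple(float(values[i]) for i in indices),
                    wraps_origin=wraps,
                )
            )
    peaks.sort(key=lambda p: (p.direction, p.start))
    return peaks


def quantify_peak(
    peak: Peak,
    wt: OccupancyTrack,
    mut: OccupancyTrack,
    method: str = "ratio-of-sums",
    pseudocount: float = 0.0,
) -> Peak:
    """Combine the fluorescence of a peak's probes into one level.

    ``ratio-of-sums`` (default) pools intensity first: sum(mut)/sum(wt) over
    the peak's probes — the closest reading of combining the hybridized
    fluorescence per peak. ``sum-ratio`` instead averages the per-probe
    ratios; the two disagree when wild-type intensity varies across the
    peak, so the method name is recorded on the peak.
    """
    idx = list(peak.probe_indices)
    if method == "ratio-of-sums":
        wsum = float(np.sum(wt.values[idx])) + pseudocount
        msum = float(np.sum(mut.values[idx])) + pseudocount
        if wsum == 0:
            raise ZeroDivisionError(
                f"wild-type intensity sums to zero over probes {idx}"
            )
        level = msum / wsum
    elif method == "sum-ratio":
        level = float(
            np.mean((mut.values[idx] + pseudocount) / (wt.values[idx] + pseudocount))
        )
    else:
        raise ValueError(f"unknown quantification method {method!r}")
    return replace(peak, level=level, method=method)


def rank_peaks(peaks: Sequence[Peak], direction: str) -> list[Peak]:
    """Order quantified peaks the way the result tables list them.

    Increased peaks descend by level (largest enrichment first); decreased
    peaks ascend (deepest depletion first). Ties break by genomic start.
    """
    if direction not in (INCREASED, DECREASED):
        raise ValueError(f"unknown direction {direction!r}")
    sel = [p for p in peaks if p.direction == direction]
    if any(p.level is None for p in sel):
        raise ValueError("rank_peaks requires quantified peaks")
    reverse = direction == INCREASED
    return sorted(
        sel, key=lambda p: (-p.level if reverse else p.level, p.start)
    )


def peaks_to_tsv(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = [
        {
            "peak_id": i,
            "start": p.start,
            "end": p.end,
            "direction": p.direction,
            "n_probes": p.n_probes,
            "level": p.level if p.level is not None else "",
            "method": p.method or "",
        }
        for i, p in enumerate(peaks)
    ]
    pd.DataFrame(
        rows,
        columns=["peak_id", "start", "end", "direction", "n_probes", "level", "method"],
    ).to_csv(path, sep="\t", index=False)
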