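"""Seeded generators for every input the pipeline consumes.

The array simulator emulates a two-color tiling-array co-hybridization:
each probe reports a wild-type (Cy3) and a mutant (Cy5) fluorescence
intensity. Expected wild-type intensity is a flat baseline; inside planted
differential regions the expected mutant intensity is baseline times the
planted fold (mutant/wild-type occupancy ratio). Observed intensities are
expectation times an optional channel dye bias times mean-preserving
multiplicative log-normal noise, the standard noise model for two-color
arrays. The qPCR simulator writes replicated Ct tables in which a planted
expression fold shifts the mutant Ct by -log_efficiency(fold) cycles.

Defaults are desk-scale: a 500-kb circular genome with 400 genes and 3
prophage intervals at the same probe density (60-bp probes every 105 bp)
as a genome-wide bacterial tiling array. All randomness flows from the
config seed; outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome import (
    Gene,
    GenomeAnnotation,
    GenomeSpec,
    ProbeGrid,
    ProphageInterval,
)
from .occupancy import CHANNEL, OccupancyTrack
from .qpcr import (
    DEFAULT_EFFICIENCY,
    DEFAULT_REFERENCE,
    MUTANT,
    WILD_TYPE,
    QpcrTable,
)

import pandas as pd


@dataclass(frozen=True)
class PlantedRegion:
    """Ground truth for one differential-occupancy region."""

    start: int
    end: int
    fold: float  # mutant/wild-type occupancy ratio
    probe_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("planted fold must be > 0")
        if self.start >= self.end:
            raise ValueError("planted region is empty")


@dataclass(frozen=True)
class SimConfig:
    """Array-simulation conditions."""

    genome_length: int = 500_000
    circular: bool = True
    n_genes: int = 400
    n_prophages: int = 3
    planted_effects: tuple[PlantedRegion, ...] = ()
    baseline_intensity: float = 1000.0
    noise_cv: float = 0.1
    dye_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.baseline_intensity <= 0 or self.dye_bias <= 0:
            raise ValueError("baseline_intensity and dye_bias must be > 0")
        for r in self.planted_effects:
            if not (0 <= r.start < r.end <= self.genome_length):
                raise ValueError(
                    f"planted region [{r.start}, {r.end}) outside genome"
                )

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec(self.genome_length, self.circular)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _covered_probes(grid: ProbeGrid, start: int, end: int) -> tuple[int, ...]:
    out = []
    for i, s in enumerate(grid.starts):
        if s < end and start < s + grid.probe_length:
            out.append(i)
    return tuple(out)


def simulate_tracks(
    config: SimConfig, grid: ProbeGrid
) -> tuple[OccupancyTrack, OccupancyTrack, list[PlantedRegion]]:
    """Generate paired wild-type/mutant channel tracks plus ground truth.

    A planted region is applied to every probe it overlaps by >= 1 bp
    (boundary probes included); a region overlapping no probe at all is an
    error, since no analysis could ever see it.
    """
    rng = np.random.default_rng(config.seed)
    n = grid.count
    expected_wt = np.full(n, config.baseline_intensity)
    expected_mut = np.full(n, config.baseline_intensity)
    truth = []
    for region in config.planted_effects:
        covered = _covered_probes(grid, region.start, region.end)
        if not covered:
            raise ValueError(
                f"planted region [{region.start}, {region.end}) overlaps no probe"
            )
        expected_mut[list(covered)] = config.baseline_intensity * region.fold
        truth.append(replace(region, probe_indices=covered))
    sigma = _lognormal_sigma(config.noise_cv)
    if sigma > 0:
        noise_wt = np.exp(rng.normal(-sigma**2 / 2, sigma, n))
        noise_mut = np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    else:
        noise_wt = noise_mut = np.ones(n)
    wt = OccupancyTrack(grid, expected_wt * noise_wt, CHANNEL)
    mut = OccupancyTrack(grid, expected_mut * config.dye_bias * noise_mut, CHANNEL)
    return wt, mut, truth


def plant_random_regions(
    grid: ProbeGrid,
    n_regions: int,
    folds: Sequence[float],
    rng: np.random.Generator,
    min_probes: int = 3,
    max_probes: int = 6,
    separation_probes: int = 4,
) -> tuple[PlantedRegion, ...]:
    """Place non-adjacent probe-aligned regions with folds cycled from ``folds``.

    Each region spans ``min_probes``..``max_probes`` whole probes; regions
    are separated by at least ``separation_probes`` probes so that calls
    cannot merge.
    """
    placed: list[tuple[int, int]] = []  # probe-index spans
    regions = []
    n = grid.count
    attempts = 0
    while len(regions) < n_regions:
        attempts += 1
        if attempts > 1000 * n_regions:
            raise RuntimeError("could not place requested regions; genome too dense")
        k = int(rng.integers(min_probes, max_probes + 1))
        i = int(rng.integers(0, n - k))
        if any(
            i - separation_probes < hi and lo < i + k + separation_probes
            for lo, hi in placed
        ):
            continue
        fold = float(folds[len(regions) % len(folds)])
        start = grid.starts[i]
        end = grid.starts[i + k - 1] + grid.probe_length
        regions.append(PlantedRegion(start, end, fold))
        placed.append((i, i + k))
    regions.sort(key=lambda r: r.start)
    return tuple(regions)


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Deterministic schematic annotation for the synthetic genome.

    Prophages are evenly spaced 20-kb intervals named P1..Pn; genes are
    ~900-bp ORFs laid head-to-tail on alternating strands with short
    spacers, skipping nothing — a caricature of a gene-dense bacterial
    chromosome, sufficient for exercising assignment and summarisation.
    """
    genome = config.genome
    prophages = []
    if config.n_prophages:
        spacing = config.genome_length // config.n_prophages
        size = min(20_000, max(spacing // 4, 1_000))
        for i in range(config.n_prophages):
            start = i * spacing + spacing // 3
            prophages.append(ProphageInterval(f"P{i + 1}", start, start + size))
    genes = []
    if config.n_genes:
        pitch = config.genome_length // config.n_genes
        glen = max(int(pitch * 0.75), 60)
        for i in range(config.n_genes):
            start = i * pitch
            end = min(start + glen, config.genome_length)
            strand = "+" if i % 2 == 0 else "-"
            genes.append(Gene(f"g{i + 1:04d}", start, end, strand))
    from .genome import _link_prophages

    return GenomeAnnotation(genome, _link_prophages(genes, prophages), prophages)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSimConfig:
    """qPCR-simulation conditions: true folds, replication, and Ct noise."""

    genes: tuple[tuple[str, float], ...]  # (name, true mutant/WT fold)
    replicates: int = 3
    ct_noise_sd: float = 0.3
    reference_gene: str = DEFAULT_REFERENCE
    efficiency: float = DEFAULT_EFFICIENCY
    base_ct: float = 20.0
    reference_base_ct: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.efficiency <= 1:
            raise ValueError("efficiency must exceed 1")
        for name, fold in self.genes:
            if fold <= 0:
                raise ValueError(f"gene {name}: fold must be > 0")
            if name == self.reference_gene and fold != 1.0:
                raise ValueError("reference gene must have fold 1")


def simulate_qpcr(config: QpcrSimConfig) -> QpcrTable:
    """Replicated Ct table with planted expression folds.

    Ct(gene, strain, rep) = base_ct - log_eff(expression multiplier)
    + N(0, ct_noise_sd); the mutant's multiplier is the planted fold, the
    wild type's is 1. The reference gene (fold 1, lower base Ct as befits
    rRNA abundance) is always included.
    """
    rng = np.random.default_rng(config.seed)
    log_eff = math.log(config.efficiency)
    genes = list(config.genes)
    if all(name != config.reference_gene for name, _ in genes):
        genes.append((config.reference_gene, 1.0))
    rows = []
    for name, fold in genes:
        base = (
            config.reference_base_ct
            if name == config.reference_gene
            else config.base_ct
        )
        for strain in (WILD_TYPE, MUTANT):
            mult = fold if strain == MUTANT else 1.0
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                ct = base - math.log(mult) / log_eff + noise
                rows.append(
                    {"gene": name, "strain": strain, "replicate": rep, "ct": ct}
                )
    return QpcrTable(pd.DataFrame(rows), config.reference_gene)
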