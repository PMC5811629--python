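"""Seeded recovery benchmarks: how well the pipeline finds what was planted.

Two studies, both driven entirely by the synthetic generators:

Array recovery
    Repeatedly simulate a desk-scale genome (500 kb, 60-bp probes every
    105 bp) carrying probe-aligned differential regions of fold 5, 10, and
    36 under multiplicative log-normal noise, run the ratio/peak-calling
    chain, and score sensitivity (planted regions hit by a called peak of
    the right direction) and false discovery (called peaks hitting no
    planted region). Detection in the benchmark uses a threshold *below*
    the smallest planted fold (2.5 against a smallest fold of 5): with
    symmetric multiplicative noise, a detector thresholded exactly at the
    planted fold has ~50% per-probe power by construction, so thresholding
    at the effect size would measure the noise model, not the caller. The
    screening default of 5 is unchanged elsewhere.

Quantification accuracy is scored separately on the same simulations:
the fraction of planted regions whose combined level lands within a
stated relative tolerance of the planted fold.

qPCR round trip
    Repeatedly simulate replicated Ct tables over a grid of true folds,
    estimate each fold by the ddCt method, and report the worst-gene
    deviation of the median recovered ratio from truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeSpec, build_probe_grid
from .occupancy import normalize_channels, probe_ratio
from .peaks import INCREASED, call_peaks, quantify_peak
from .qpcr import delta_delta_ct
from .synthetic import (
    PlantedRegion,
    QpcrSimConfig,
    SimConfig,
    plant_random_regions,
    simulate_qpcr,
    simulate_tracks,
)

#: Benchmark detection thresholds: below the smallest planted fold (5) and
#: above its reciprocal, for the reason given in the module docstring.
BENCH_CUTOFF_UP = 2.5
BENCH_CUTOFF_DOWN = 0.4

DEFAULT_FOLDS = (5.0, 10.0, 36.0)


@dataclass(frozen=True)
class RecoveryResult:
    sensitivity: float
    fdr: float
    n_planted: int
    n_detected: int
    n_called: int
    n_false: int
    level_within_tol: float  # fraction of detected regions quantified within tol
    n_sims: int


def _overlaps(peak_start: int, peak_end: int, region: PlantedRegion) -> bool:
    return peak_start < region.end and region.start < peak_end


def recovery_benchmark(
    n_sims: int = 200,
    seed: int = 0,
    genome_length: int = 500_000,
    noise_cv: float = 0.1,
    folds: tuple[float, ...] = DEFAULT_FOLDS,
    regions_per_sim: int = 6,
    min_probes: int = 3,
    max_probes: int = 6,
    level_tol: float = 0.2,
    cutoff_up: float = BENCH_CUTOFF_UP,
    cutoff_down: float = BENCH_CUTOFF_DOWN,
) -> RecoveryResult:
    """Run the planted-region recovery study and score it."""
    genome = GenomeSpec(genome_length, circular=True)
    grid = build_probe_grid(genome)
    ss = np.random.SeedSequence(seed)
    n_planted = n_detected = n_called = n_false = 0
    n_quant = n_quant_ok = 0
    for child in ss.spawn(n_sims):
        sim_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        rng = np.random.default_rng(sim_seed)
        regions = plant_random_regions(
            grid, regions_per_sim, folds, rng,
            min_probes=min_probes, max_probes=max_probes,
        )
        config = SimConfig(
            genome_length=genome_length,
            planted_effects=regions,
            noise_cv=noise_cv,
            seed=sim_seed,
        )
        wt, mut, truth = simulate_tracks(config, grid)
        wt_n, mut_n = normalize_channels(wt, mut)
        track = probe_ratio(mut_n, wt_n)
        called = [
            quantify_peak(p, wt_n, mut_n)
            for p in call_peaks(track, cutoff_up=cutoff_up, cutoff_down=cutoff_down)
            if p.direction == INCREASED
        ]
        n_planted += len(truth)
        n_called += len(called)
        for region in truth:
            hits = [p for p in called if _overlaps(p.start, p.end, region)]
            if hits:
                n_detected += 1
                # quantify against the planted fold using the widest hit
                best = max(hits, key=lambda p: p.n_probes)
                n_quant += 1
                if abs(best.level - region.fold) <= level_tol * region.fold:
                    n_quant_ok += 1
        for p in called:
            if not any(_overlaps(p.start, p.end, r) for r in truth):
                n_false += 1
    return RecoveryResult(
        sensitivity=n_detected / n_planted if n_planted else float("nan"),
        fdr=n_false / n_called if n_called else 0.0,
        n_planted=n_planted,
        n_detected=n_detected,
        n_called=n_called,
        n_false=n_false,
        level_within_tol=n_quant_ok / n_quant if n_quant else float("nan"),
        n_sims=n_sims,
    )


def qpcr_roundtrip_benchmark(
    n_sims: int = 200,
    seed: int = 0,
    folds: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 4.69, 10.0),
    replicates: int = 3,
    ct_noise_sd: float = 0.3,
) -> dict:
    """Median ddCt recovery across seeded qPCR simulations.

    Returns the per-gene median recovered ratios and the worst-gene
    relative deviation of that median from the planted fold.
    """
    genes = tuple((f"g{i}", f) for i, f in enumerate(folds))
    ss = np.random.SeedSequence(seed)
    recovered: dict[str, list[float]] = {name: [] for name, _ in genes}
    for child in ss.spawn(n_sims):
        sim_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        table = simulate_qpcr(
            QpcrSimConfig(
                genes=genes,
                replicates=replicates,
                ct_noise_sd=ct_noise_sd,
                seed=sim_seed,
            )
        )
        for r in delta_delta_ct(table):
            recovered[r.gene].append(r.ratio)
    medians = {name: float(np.median(v)) for name, v in recovered.items()}
    truth = dict(genes)
    rel_err = {
        name: abs(medians[name] - truth[name]) / truth[name] for name in medians
    }
    return {
        "medians": medians,
        "truth": truth,
        "max_median_rel_err": max(rel_err.values()),
        "n_sims": n_sims,
    }
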