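"""The array and qPCR simulators: noise-free limits, reproducibility."""

import math

import numpy as np
import pytest

from occtile.genome import build_probe_grid
from occtile.occupancy import probe_ratio
from occtile.qpcr import MUTANT, WILD_TYPE, delta_delta_ct
from occtile.synthetic import (
    PlantedRegion,
    QpcrSimConfig,
    SimConfig,
    plant_random_regions,
    simulate_annotation,
    simulate_qpcr,
    simulate_tracks,
)


def small_sim(**kw):
    defaults = dict(genome_length=10_500, n_genes=10, n_prophages=1, seed=3)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateTracks:
    def test_noise_free_planted_fold_exact(self):
        cfg = small_sim(
            noise_cv=0.0,
            planted_effects=(PlantedRegion(1050, 1470, 5.0),),
        )
        grid = build_probe_grid(cfg.genome)
        wt, mut, truth = simulate_tracks(cfg, grid)
        ratios = mut.values / wt.values
        covered = list(truth[0].probe_indices)
        assert np.allclose(ratios[covered], 5.0)
        others = [i for i in range(grid.count) if i not in covered]
        assert np.allclose(ratios[others], 1.0)

    def test_noise_free_no_effects_flat(self):
        cfg = small_sim(noise_cv=0.0)
        grid = build_probe_grid(cfg.genome)
        wt, mut, _ = simulate_tracks(cfg, grid)
        assert np.allclose(mut.values / wt.values, 1.0)

    def test_boundary_probes_included(self):
        # region [1000, 1200) clips probe [945,1005) by 5 bp and [1155,1215) by 45 bp
        cfg = small_sim(noise_cv=0.0, planted_effects=(PlantedRegion(1000, 1200, 10.0),))
        grid = build_probe_grid(cfg.genome)
        _, _, truth = simulate_tracks(cfg, grid)
        assert truth[0].probe_indices == (9, 10, 11)

    def test_region_in_probe_gap_rejected(self):
        # [60, 105) falls entirely between probe 0 and probe 1
        cfg = small_sim(noise_cv=0.0, planted_effects=(PlantedRegion(60, 105, 10.0),))
        grid = build_probe_grid(cfg.genome)
        with pytest.raises(ValueError, match="overlaps no probe"):
            simulate_tracks(cfg, grid)

    def test_seeded_reproducibility(self):
        cfg = small_sim(noise_cv=0.2, seed=11)
        grid = build_probe_grid(cfg.genome)
        a = simulate_tracks(cfg, grid)
        b = simulate_tracks(cfg, grid)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_noisy_ratios_near_truth(self):
        cfg = small_sim(
            noise_cv=0.1,
            seed=0,
            planted_effects=(PlantedRegion(2100, 2520, 10.0),),
        )
        grid = build_probe_grid(cfg.genome)
        wt, mut, truth = simulate_tracks(cfg, grid)
        ratios = probe_ratio(mut, wt, pseudocount=0).values
        covered = list(truth[0].probe_indices)
        assert len(covered) >= 4
        assert all(8.0 <= r <= 12.0 for r in ratios[covered])

    def test_dye_bias_scales_mutant_channel(self):
        grid = build_probe_grid(small_sim().genome)
        cfg = small_sim(noise_cv=0.0, dye_bias=1.5)
        _, mut, _ = simulate_tracks(cfg, grid)
        assert np.allclose(mut.values, 1000.0 * 1.5)

    def test_mean_preserving_noise(self):
        cfg = SimConfig(genome_length=2_100_000, noise_cv=0.2, seed=9)
        grid = build_probe_grid(cfg.genome)
        wt, _, _ = simulate_tracks(cfg, grid)
        assert np.mean(wt.values) == pytest.approx(1000.0, rel=0.005)
        assert np.std(wt.values) / np.mean(wt.values) == pytest.approx(0.2, rel=0.05)


class TestPlantRandomRegions:
    def test_regions_are_probe_aligned_and_separated(self):
        grid = build_probe_grid(SimConfig().genome)
        rng = np.random.default_rng(0)
        regions = plant_random_regions(grid, 8, (5.0, 10.0, 36.0), rng)
        assert len(regions) == 8
        for r in regions:
            assert r.start in grid.starts
            n = sum(1 for s in grid.starts if r.start <= s < r.end)
            assert 3 <= n <= 6
        for a, b in zip(regions, regions[1:]):
            assert b.start - a.end >= 105  # at least one clear probe between


class TestSimulateAnnotation:
    def test_counts_and_linking(self):
        ann = simulate_annotation(SimConfig())
        assert len(ann.genes) == 400
        assert len(ann.prophages) == 3
        assert any(g.prophage for g in ann.genes)
        in_p = [g for g in ann.genes if g.prophage]
        for g in in_p[:5]:
            p = ann.prophage_of(g.prophage)
            assert g.start < p.end and p.start < g.end


class TestSimulateQpcr:
    def test_fold_two_shifts_one_cycle(self):
        cfg = QpcrSimConfig(genes=(("gA", 2.0),), ct_noise_sd=0.0, seed=0)
        table = simulate_qpcr(cfg)
        df = table.data
        wt_ct = df[(df.gene == "gA") & (df.strain == WILD_TYPE)]["ct"].unique()
        mut_ct = df[(df.gene == "gA") & (df.strain == MUTANT)]["ct"].unique()
        assert wt_ct.item() - mut_ct.item() == pytest.approx(1.0)

    def test_reference_identical_across_strains(self):
        cfg = QpcrSimConfig(genes=(("gA", 3.0),), ct_noise_sd=0.0, seed=0)
        df = simulate_qpcr(cfg).data
        ref = df[df.gene == "16S"]
        assert ref.groupby("strain")["ct"].mean().nunique() == 1

    def test_planted_fold_in_ddct_units(self):
        cfg = QpcrSimConfig(genes=(("paaE_like", 4.69),), ct_noise_sd=0.0, seed=0)
        df = simulate_qpcr(cfg).data
        wt = df[(df.gene == "paaE_like") & (df.strain == WILD_TYPE)]["ct"].mean()
        mut = df[(df.gene == "paaE_like") & (df.strain == MUTANT)]["ct"].mean()
        assert mut - wt == pytest.approx(-math.log2(4.69))

    def test_reference_with_nonunit_fold_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            QpcrSimConfig(genes=(("16S", 2.0),))

    def test_noise_free_round_trip_through_estimator(self):
        cfg = QpcrSimConfig(
            genes=(("a", 4.69), ("b", 0.1), ("c", 1.0)), ct_noise_sd=0.0, seed=0
        )
        ratios = {r.gene: r.ratio for r in delta_delta_ct(simulate_qpcr(cfg))}
        assert ratios["a"] == pytest.approx(4.69)
        assert ratios["b"] == pytest.approx(0.1)
        assert ratios["c"] == pytest.approx(1.0)


class TestParameterRecovery:
    def test_strong_folds_quantified_within_20pct(self):
        # at noise_cv 0.1 and folds >= 10 over >= 3 probes, the combined
        # level lands within 20% of the planted fold in >= 95% of replicates
        from occtile.benchmark import recovery_benchmark

        res = recovery_benchmark(n_sims=200, seed=3, folds=(10.0, 36.0))
        assert res.sensitivity == 1.0
        assert res.level_within_tol >= 0.95
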