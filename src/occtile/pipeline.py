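"""End-to-end runs: simulate (or load) -> ratio -> peaks -> annotate -> qPCR.

A run is driven by a single :class:`RunConfig` (optionally parsed from a
YAML file) and writes every result table plus a manifest recording the
seed, a hash of the configuration, package versions, and a checksum of
each output. Re-running with the same configuration reproduces every
output byte for byte.

Two modes:

``simulate``
    Generate a synthetic genome, annotation, and two-channel tracks with
    planted differential regions; then normalize, compute per-probe
    mutant/WT ratios, call and quantify peaks, assign them to genes and
    prophages, rank the increased/decreased tables, summarize prophage
    membership, and run a matched qPCR simulation through the ddCt
    estimator.

``fixtures``
    Skip signal processing and run the reporting half on already-ranked
    gene tables and qPCR ratio tables (defaults: the bundled reference
    tables), reproducing the headline summary numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets
from .annotate import annotate_peaks, annotated_peaks_to_tsv, summarize_prophages, summary_to_json
from .genome import build_probe_grid, write_annotation
from .occupancy import normalize_channels, probe_ratio, ratio_to_tsv, tracks_to_tsv
from .peaks import (
    DECREASED,
    INCREASED,
    call_peaks,
    peaks_to_tsv,
    quantify_peak,
    rank_peaks,
)
from .qpcr import classify_folds, delta_delta_ct, ratios_to_tsv
from .synthetic import PlantedRegion, QpcrSimConfig, SimConfig, simulate_annotation, simulate_qpcr, simulate_tracks


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the input."""


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"  # "simulate" or "fixtures"
    sim: Optional[SimConfig] = None
    qpcr_sim: Optional[QpcrSimConfig] = None
    # fixture-mode inputs; None means the bundled reference tables
    increased_table: Optional[str] = None
    decreased_table: Optional[str] = None
    increased_qpcr_table: Optional[str] = None
    decreased_qpcr_table: Optional[str] = None
    # analysis parameters (defaults are the screening conditions)
    cutoff_up: float = 5.0
    cutoff_down: float = 0.2
    min_probes: int = 2
    max_gap: int = 0
    quantify_method: str = "ratio-of-sums"
    pseudocount: float = 1.0
    normalization: str = "median-ratio"
    fold_thresholds: tuple[float, float] = (2.0, 4.0)
    top_n: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fixtures"):
            raise ValueError(f"unknown mode {self.mode!r}")
        has_paths = any(
            p is not None
            for p in (
                self.increased_table,
                self.decreased_table,
                self.increased_qpcr_table,
                self.decreased_qpcr_table,
            )
        )
        if self.mode == "simulate" and has_paths:
            raise ValueError("simulate mode takes a SimConfig, not input tables")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            sim["planted_effects"] = tuple(
                PlantedRegion(int(r["start"]), int(r["end"]), float(r["fold"]))
                for r in sim.get("planted_effects", [])
            )
            raw["sim"] = SimConfig(**sim)
        if "qpcr_sim" in raw and raw["qpcr_sim"] is not None:
            q = dict(raw["qpcr_sim"])
            q["genes"] = tuple((str(n), float(f)) for n, f in q.get("genes", []))
            raw["qpcr_sim"] = QpcrSimConfig(**q)
        if "fold_thresholds" in raw:
            raw["fold_thresholds"] = tuple(raw["fold_thresholds"])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Wrap a stage so failures abort with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute a full run and return the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    summary: dict = {}

    if config.mode == "simulate":
        sim = config.sim or SimConfig(seed=config.seed)
        with _stage("simulate"):
            grid = build_probe_grid(sim.genome)
            ann = simulate_annotation(sim)
            wt, mut, truth = simulate_tracks(sim, grid)
            write_annotation(ann, out / "genes.tsv", out / "prophages.bed")
            tracks_to_tsv(wt, mut, out / "intensities.tsv")
            outputs += [out / "genes.tsv", out / "prophages.bed", out / "intensities.tsv"]
        with _stage("ratio"):
            wt_n, mut_n = normalize_channels(wt, mut, config.normalization)
            ratio = probe_ratio(mut_n, wt_n, config.pseudocount)
            ratio_to_tsv(ratio, out / "ratios.tsv")
            outputs.append(out / "ratios.tsv")
        with _stage("peaks"):
            called = call_peaks(
                ratio,
                cutoff_up=config.cutoff_up,
                cutoff_down=config.cutoff_down,
                min_probes=config.min_probes,
                max_gap=config.max_gap,
            )
            called = [
                quantify_peak(p, wt_n, mut_n, config.quantify_method) for p in called
            ]
            peaks_to_tsv(called, out / "peaks.tsv")
            outputs.append(out / "peaks.tsv")
        with _stage("annotate"):
            annotated = annotate_peaks(called, ann)
            annotated_peaks_to_tsv(annotated, out / "annotated_peaks.tsv")
            outputs.append(out / "annotated_peaks.tsv")
            by_peak = {id(a.peak): a for a in annotated}
            tables = {}
            for direction, fname in (
                (INCREASED, "increased_ranked.tsv"),
                (DECREASED, "decreased_ranked.tsv"),
            ):
                ranked = rank_peaks(called, direction)
                rows = [
                    {
                        "gene": (by_peak[id(p)].gene.name if by_peak[id(p)].gene else ""),
                        "level": p.level,
                        "location_class": by_peak[id(p)].location_class,
                        "prophage": by_peak[id(p)].prophage or "",
                    }
                    for p in ranked
                ]
                df = pd.DataFrame(
                    rows, columns=["gene", "level", "location_class", "prophage"]
                )
                df.to_csv(out / fname, sep="\t", index=False)
                outputs.append(out / fname)
                tables[direction] = df
        with _stage("summarize"):
            inc = tables[INCREASED]
            top_n = min(config.top_n, len(inc))
            if top_n:
                psum = summarize_prophages(inc, top_n)
                summary_to_json(psum, out / "prophage_summary.json")
                outputs.append(out / "prophage_summary.json")
                summary["prophage_fraction"] = psum.prophage_fraction
                summary["per_prophage_counts"] = psum.per_prophage_counts
            summary["n_increased_peaks"] = len(tables[INCREASED])
            summary["n_decreased_peaks"] = len(tables[DECREASED])
            summary["truth_regions"] = len(truth)
        with _stage("qpcr"):
            qconf = config.qpcr_sim
            if qconf is None:
                genes = tuple(
                    (f"q{i + 1:02d}", r.fold) for i, r in enumerate(truth[:12])
                )
                qconf = QpcrSimConfig(genes=genes, seed=sim.seed + 1)
            table = simulate_qpcr(qconf)
            table.to_tsv(out / "qpcr_ct.tsv")
            ratios = delta_delta_ct(table, qconf.efficiency)
            ratios_to_tsv(ratios, out / "qpcr_ratios.tsv")
            outputs += [out / "qpcr_ct.tsv", out / "qpcr_ratios.tsv"]
            summary["fold_classes"] = classify_folds(ratios, config.fold_thresholds)
    else:
        with _stage("fixtures"):
            inc = (
                pd.read_csv(config.increased_table, sep="\t")
                if config.increased_table
                else datasets.load_increased_genes()
            )
            dec = (
                pd.read_csv(config.decreased_table, sep="\t")
                if config.decreased_table
                else datasets.load_decreased_genes()
            )
            inc_q = (
                pd.read_csv(config.increased_qpcr_table, sep="\t")
                if config.increased_qpcr_table
                else datasets.load_increased_qpcr()
            )
            dec_q = (
                pd.read_csv(config.decreased_qpcr_table, sep="\t")
                if config.decreased_qpcr_table
                else datasets.load_decreased_qpcr()
            )
        with _stage("summarize"):
            top_n = min(config.top_n, len(inc))
            psum = summarize_prophages(inc, top_n)
            summary_to_json(psum, out / "prophage_summary.json")
            outputs.append(out / "prophage_summary.json")
            summary["prophage_fraction"] = psum.prophage_fraction
            summary["per_prophage_counts"] = psum.per_prophage_counts
            summary["max_increased_level"] = float(inc["level"].max())
            summary["min_decreased_level"] = float(dec["level"].min())
        with _stage("qpcr"):
            summary["fold_classes"] = classify_folds(
                inc_q["ratio"].tolist(), config.fold_thresholds
            )
            summary["qpcr_prophage_genes"] = int(
                inc_q["prophage"].fillna("").astype(str).str.strip().ne("").sum()
            )
            recip = dec_q.assign(
                recomputed_reciprocal=(1.0 / dec_q["ratio"]).round(4)
            )
            recip.to_csv(out / "reciprocal_check.tsv", sep="\t", index=False)
            outputs.append(out / "reciprocal_check.tsv")

    with _stage("manifest"):
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        outputs.append(out / "summary.json")
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": {
                "occtile": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": {p.name: _sha256(p) for p in outputs},
            "summary": summary,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
    return manifest
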