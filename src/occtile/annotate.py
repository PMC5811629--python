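"""Peak-to-gene assignment, prophage classification, and site overlap.

Peaks are classified as ORF-internal when their genomic midpoint falls
inside an annotated ORF, and as spacer (intergenic) peaks otherwise, in
which case the nearest gene within a configurable distance is reported.
Ranked gene tables are summarized per prophage — the headline statistic
being the percentage of top-ranked genes that lie inside cryptic
prophages — and externally supplied site tracks (constitutive promoters,
H-NS silencer sites) are overlapped with the prophage intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .genome import Gene, GenomeAnnotation, ProphageInterval, SiteTrack
from .peaks import Peak

ORF_INTERNAL = "ORF-internal"
SPACER = "spacer"

#: How far (bp) a spacer peak may sit from the nearest gene and still name it.
DEFAULT_SPACER_DISTANCE = 1000


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    gene: Optional[Gene]
    location_class: str
    prophage: Optional[str]
    #: other genes the peak span overlaps, by decreasing bp overlap
    secondary_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProphageSummary:
    """Per-prophage gene counts and the prophage-resident share of a ranked list."""

    per_prophage_counts: dict[str, int]
    prophage_fraction: int  # integer percent of top_n rows inside any prophage
    total_genes: int


def _circular_distance(a: int, b: int, length: int, circular: bool) -> int:
    d = abs(a - b)
    return min(d, length - d) if circular else d


def assign_peak(
    peak: Peak,
    ann: GenomeAnnotation,
    max_spacer_distance: int = DEFAULT_SPACER_DISTANCE,
) -> AnnotatedPeak:
    """Attach a gene, a location class, and a prophage to one peak.

    The gene containing the peak midpoint makes the peak ORF-internal.
    Failing that the peak is a spacer peak and the nearest gene within
    ``max_spacer_distance`` bp (edge-to-midpoint) is reported, or no gene at
    all. The prophage is assigned from >= 1 bp overlap of the full peak span.
    """
    genome = ann.genome
    mid = peak.midpoint(genome.length)
    containing = ann.genes_at(mid)
    spans = _peak_spans(peak, genome.length)

    overlap_by_gene: dict[str, int] = {}
    for s, e in spans:
        for g in ann.genes_overlapping(s, e):
            ov = min(e, g.end) - max(s, g.start)
            overlap_by_gene[g.name] = overlap_by_gene.get(g.name, 0) + ov

    if containing:
        # among genes containing the midpoint prefer maximal span overlap
        gene = max(containing, key=lambda g: overlap_by_gene.get(g.name, 0))
        location = ORF_INTERNAL
    else:
        gene = None
        location = SPACER
        best = None
        for g in ann.genes:
            d = min(
                _circular_distance(mid, g.start, genome.length, genome.circular),
                _circular_distance(mid, g.end, genome.length, genome.circular),
            )
            if d <= max_spacer_distance and (best is None or d < best[0]):
                best = (d, g)
        if best is not None:
            gene = best[1]

    prophage = None
    best_ov = 0
    for s, e in spans:
        for p in ann.prophages_overlapping(s, e):
            ov = min(e, p.end) - max(s, p.start)
            if ov > best_ov:
                prophage, best_ov = p.name, ov

    secondary = tuple(
        name
        for name, _ in sorted(overlap_by_gene.items(), key=lambda kv: -kv[1])
        if gene is None or name != gene.name
    )
    return AnnotatedPeak(peak, gene, location, prophage, secondary)


def _peak_spans(peak: Peak, genome_length: int) -> list[tuple[int, int]]:
    if not peak.wraps_origin:
        return [(peak.start, peak.end)]
    return [(peak.start, genome_length), (0, peak.end)]


def annotate_peaks(
    peaks: Sequence[Peak],
    ann: GenomeAnnotation,
    max_spacer_distance: int = DEFAULT_SPACER_DISTANCE,
) -> list[AnnotatedPeak]:
    return [assign_peak(p, ann, max_spacer_distance) for p in peaks]


def summarize_prophages(ranked: pd.DataFrame, top_n: int) -> ProphageSummary:
    """Count prophage-resident genes among the top ``top_n`` ranked rows.

    ``ranked`` needs a ``prophage`` column (empty/NaN = host genome). The
    fraction is reported as an integer percent, matching how such shares are
    quoted ("almost half").
    """
    if len(ranked) < top_n:
        raise ValueError(f"table has {len(ranked)} rows, need >= {top_n}")
    head = ranked.head(top_n)
    prophage = head["prophage"].fillna("").astype(str).str.strip()
    in_prophage = prophage != ""
    counts = prophage[in_prophage].value_counts().to_dict()
    fraction = round(100.0 * int(in_prophage.sum()) / top_n)
    return ProphageSummary(
        per_prophage_counts={str(k): int(v) for k, v in counts.items()},
        prophage_fraction=int(fraction),
        total_genes=top_n,
    )


def overlap_sites(
    track: SiteTrack, prophages: Sequence[ProphageInterval]
) -> dict[str, int]:
    """Count sites overlapping (>= 1 bp) each prophage.

    A site spanning two adjacent prophages is counted once in each.
    """
    counts = {p.name: 0 for p in prophages}
    for start, end, _score in track.sites:
        for p in prophages:
            if start < p.end and p.start < end:
                counts[p.name] += 1
    return counts


def annotated_peaks_to_tsv(
    annotated: Sequence[AnnotatedPeak], path: str | Path
) -> None:
    rows = [
        {
            "start": a.peak.start,
            "end": a.peak.end,
            "direction": a.peak.direction,
            "n_probes": a.peak.n_probes,
            "level": a.peak.level if a.peak.level is not None else "",
            "gene": a.gene.name if a.gene else "",
            "location_class": a.location_class,
            "prophage": a.prophage or "",
        }
        for a in annotated
    ]
    pd.DataFrame(
        rows,
        columns=[
            "start", "end", "direction", "n_probes",
            "level", "gene", "location_class", "prophage",
        ],
    ).to_csv(path, sep="\t", index=False)


def summary_to_json(summary: ProphageSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "prophage_fraction": summary.prophage_fraction,
                "total_genes": summary.total_genes,
                "per_prophage_counts": summary.per_prophage_counts,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
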