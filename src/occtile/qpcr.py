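"""Relative expression from qPCR threshold cycles (ddCt method).

Each gene's Ct is normalized replicate-by-replicate against a reference
gene (16S rRNA by default): dCt = Ct_gene - Ct_reference. The strain
contrast ddCt = mean dCt(mutant) - mean dCt(wild type) converts to a
relative mRNA level of efficiency^(-ddCt), with efficiency fixed at 2
(perfect doubling per cycle). Ratios are oriented mutant/wild-type; the
companion reciprocal column (1/ratio) mirrors how depletion tables pair
the two.

The dispersion attached to each ratio is a standard deviation propagated
by the delta method on the log-efficiency scale:

    sd(ratio) = ln(eff) * ratio * sd(ddCt),
    var(ddCt) = var(dCt_mut)/n_mut + var(dCt_wt)/n_wt

with sample variances across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

WILD_TYPE = "wild-type"
MUTANT = "mutant"
STRAINS = (WILD_TYPE, MUTANT)

DEFAULT_REFERENCE = "16S"
DEFAULT_EFFICIENCY = 2.0
DEFAULT_THRESHOLDS = (2.0, 4.0)


class QpcrError(ValueError):
    pass


@dataclass
class QpcrTable:
    """Replicated Ct measurements: one row per (gene, strain, replicate)."""

    data: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        required = {"gene", "strain", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise QpcrError(f"Ct table missing columns {sorted(missing)}")
        bad = set(self.data["strain"]) - set(STRAINS)
        if bad:
            raise QpcrError(f"unknown strain labels {sorted(bad)}; use {STRAINS}")
        if (self.data["ct"] <= 0).any():
            raise QpcrError("Ct values must be > 0")
        for strain in STRAINS:
            sub = self.data[
                (self.data["gene"] == self.reference_gene)
                & (self.data["strain"] == strain)
            ]
            if sub.empty:
                raise QpcrError(
                    f"reference gene {self.reference_gene!r} missing for {strain}"
                )

    @property
    def genes(self) -> list[str]:
        names = [g for g in self.data["gene"].unique() if g != self.reference_gene]
        return list(names)

    @classmethod
    def from_tsv(cls, path: str | Path, reference_gene: str = DEFAULT_REFERENCE) -> "QpcrTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExpressionRatio:
    """Relative mRNA level of one gene, mutant over wild type."""

    gene: str
    ratio: float
    sd: float
    single_replicate: bool = False

    @property
    def reciprocal(self) -> float:
        return 1.0 / self.ratio


def _delta_ct(table: QpcrTable, gene: str, strain: str) -> np.ndarray:
    df = table.data
    g = df[(df["gene"] == gene) & (df["strain"] == strain)].set_index("replicate")["ct"]
    r = df[(df["gene"] == table.reference_gene) & (df["strain"] == strain)].set_index(
        "replicate"
    )["ct"]
    common = g.index.intersection(r.index)
    if common.empty:
        raise QpcrError(
            f"no replicate-matched Ct for gene {gene!r} / reference in {strain}"
        )
    return (g.loc[common] - r.loc[common]).to_numpy(dtype=float)


def delta_delta_ct(
    table: QpcrTable, efficiency: float = DEFAULT_EFFICIENCY
) -> list[ExpressionRatio]:
    """Per-gene mutant/wild-type relative expression via the ddCt contrast."""
    if efficiency <= 1:
        raise QpcrError(f"amplification efficiency must exceed 1, got {efficiency}")
    out = []
    for gene in table.genes:
        dct_wt = _delta_ct(table, gene, WILD_TYPE)
        dct_mut = _delta_ct(table, gene, MUTANT)
        ddct = float(dct_mut.mean() - dct_wt.mean())
        ratio = efficiency ** (-ddct)
        single = len(dct_wt) < 2 or len(dct_mut) < 2
        if single:
            sd = 0.0
        else:
            var = dct_mut.var(ddof=1) / len(dct_mut) + dct_wt.var(ddof=1) / len(dct_wt)
            sd = math.log(efficiency) * ratio * math.sqrt(var)
        out.append(ExpressionRatio(gene, ratio, float(sd), single))
    return out


def classify_folds(
    ratios: Sequence[ExpressionRatio] | Sequence[float],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> dict[str, int]:
    """Partition ratios into >4-fold, (2,4]-fold and <=2-fold classes.

    Boundaries are strict on the upper side ("more than 4-fold" means > 4),
    so a ratio of exactly 4 counts in the middle class.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be ascending")
    vals = [r.ratio if isinstance(r, ExpressionRatio) else float(r) for r in ratios]
    gt_hi = sum(v > hi for v in vals)
    gt_lo = sum(lo < v <= hi for v in vals)
    return {"gt4": gt_hi, "gt2_le4": gt_lo, "le2": len(vals) - gt_hi - gt_lo}


def reciprocal_table(
    ratios: Sequence[ExpressionRatio], decimals: int = 4
) -> pd.DataFrame:
    """Paired mutant/WT ratio and rounded reciprocal columns."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "sd": [r.sd for r in ratios],
            "reciprocal": [round(1.0 / r.ratio, decimals) for r in ratios],
        }
    )


def ratios_to_tsv(ratios: Sequence[ExpressionRatio], path: str | Path) -> None:
    reciprocal_table(ratios).to_csv(path, sep="\t", index=False)
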