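"""Bundled reference tables from the RpoZ-defective RNAP occupancy screen.

Four small TSVs transcribe the printed result tables of a genome-wide
ChIP-chip comparison of wild-type and omega-subunit-deficient (RpoZ-)
RNA polymerase in E. coli K-12, plus the companion RT-qPCR measurements:

- ``increased_occupancy_genes``: top 30 genes ranked by decreasing
  mutant/WT occupancy level (max 82.5, the CP4-44 prophage gene flu).
- ``decreased_occupancy_genes``: top 31 genes ranked by increasing level
  (min 0.012, the CP4-6 prophage gene yagM).
- ``increased_occupancy_qpcr``: mutant/WT mRNA ratios (with SD) for 17
  genes picked from the increased list.
- ``decreased_occupancy_qpcr``: mutant/WT mRNA ratios, their reciprocals,
  and control rows for genes picked from the decreased list.

Empty ``prophage`` cells mean the gene sits on the host genome outside any
cryptic prophage. The ranked tables keep their published row order,
including one out-of-order pair and a duplicated gene symbol.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "increased_occupancy_genes": "increased_occupancy_genes.tsv",
    "decreased_occupancy_genes": "decreased_occupancy_genes.tsv",
    "increased_occupancy_qpcr": "increased_occupancy_qpcr.tsv",
    "decreased_occupancy_qpcr": "decreased_occupancy_qpcr.tsv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load one bundled reference table by name (see module docstring)."""
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown table {name!r}; available: {sorted(_FILES)}"
        ) from None
    ref = resources.files("occtile.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"designation": str})


def load_increased_genes() -> pd.DataFrame:
    return load_table("increased_occupancy_genes")


def load_decreased_genes() -> pd.DataFrame:
    return load_table("decreased_occupancy_genes")


def load_increased_qpcr() -> pd.DataFrame:
    return load_table("increased_occupancy_qpcr")


def load_decreased_qpcr() -> pd.DataFrame:
    return load_table("decreased_occupancy_qpcr")
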