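"""Loaders for the published summary tables shipped with the package.

These are the printed per-strain totals, per-chromosome percentage
distributions, and the query-strain filter-cascade counts from the original
16-strain Chlamydomonas panel.  They are inputs for arithmetic checks (union
identities, concentration sums, ledger conservation) — the sequencing data
behind them is not redistributed and not needed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

QUERY_STRAIN = "imp3"
CONCENTRATED_CHROMOSOMES = ["3", "6", "12", "16", "17"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("strainsift.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})


def strain_totals() -> pd.DataFrame:
    """Per-strain change totals and floored unique percentages, with the
    library-wide union rows 'Total' and 'Total_exclude_imp3'."""
    return _read("published_strain_totals.tsv")


def chromosome_distribution() -> pd.DataFrame:
    """Percentage of each wild-type strain's changes per chromosome."""
    return _read("published_chromosome_distribution.tsv")


def query_filter_counts() -> pd.DataFrame:
    """Per-chromosome filter-cascade counts for the query strain:
    total → unique → coding → non-synonymous retained."""
    return _read("published_query_filter_counts.tsv")
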