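"""Multi-strain SNP/indel library: union, subtraction, summaries, windows.

The library is a mapping from normalized variant identity to the set of
strains carrying it.  "Total" counts are union semantics — each distinct
change counted once no matter how many strains carry it — which is the
arithmetic that makes (library total) − (total excluding strain s) equal
strain s's private count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import StrainCallSet, Variant, VariantKey

__all__ = [
    "VariantLibrary",
    "LibrarySummary",
    "build_library",
    "subtract",
    "union_size",
    "shared_between",
    "chromosome_distribution",
    "window_profile",
    "library_summary",
]

SCAFFOLD_BUCKET = "scaffolds"


class LibraryLookupError(KeyError):
    """Unknown strain or sequence name."""


@dataclass
class VariantLibrary:
    """Key → strain-set mapping plus per-strain back-references."""

    key_to_strains: dict[VariantKey, set[str]]
    callsets: dict[str, StrainCallSet]
    roster: list[str]

    def strain_keys(self, strain: str) -> set[VariantKey]:
        if strain not in self.callsets:
            raise LibraryLookupError(f"unknown strain {strain!r}")
        return self.callsets[strain].keys()

    def unique_count(self, strain: str) -> int:
        mine = self.strain_keys(strain)
        return sum(1 for k in mine if self.key_to_strains[k] == {strain})


@dataclass
class LibrarySummary:
    """Per-strain totals and union totals, Table-1 style."""

    table: pd.DataFrame  # columns: strain, total, unique, unique_pct, unique_pct_floor
    union_total: int
    union_excluding: dict[str, int]

    def to_tsv(self) -> str:
        df = self.table.copy()
        lines = [df.to_csv(sep="\t", index=False).rstrip("\n")]
        lines.append(f"Total\t{self.union_total}\t\t\t")
        for s, n in self.union_excluding.items():
            lines.append(f"Total exclude {s}\t{n}\t\t\t")
        return "\n".join(lines) + "\n"


def build_library(callsets: Sequence[StrainCallSet]) -> VariantLibrary:
    """Index normalized per-strain call sets by variant identity."""
    roster = [cs.strain_name for cs in callsets]
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate strain names in panel")
    key_to_strains: dict[VariantKey, set[str]] = {}
    for cs in callsets:
        for v in cs.variants:
            key_to_strains.setdefault(v.key, set()).add(cs.strain_name)
    return VariantLibrary(key_to_strains, {cs.strain_name: cs for cs in callsets}, roster)


def subtract(
    library: VariantLibrary, query: str, panel: Iterable[str]
) -> StrainCallSet:
    """Query-strain variants whose keys occur in no panel strain.

    Raw record lines are preserved, so writing the result reproduces the
    original records minus the common changes.  Output sorted (chrom, pos).
    """
    panel = set(panel)
    if query not in library.callsets:
        raise LibraryLookupError(f"unknown query strain {query!r}")
    unknown = panel - set(library.roster)
    if unknown:
        raise LibraryLookupError(f"unknown panel strain(s): {sorted(unknown)}")
    if query in panel:
        raise ValueError("query strain must not be in the panel")
    panel_keys: set[VariantKey] = set()
    for s in panel:
        panel_keys |= library.strain_keys(s)
    src = library.callsets[query]
    kept = [v for v in src.variants if v.key not in panel_keys]
    out = StrainCallSet(src.strain_name, kept, list(src.header_lines), src.source_path)
    out.sort()
    return out


def union_size(library: VariantLibrary, excluded: Iterable[str] = ()) -> int:
    """Number of distinct keys carried by at least one non-excluded strain."""
    excluded = set(excluded)
    unknown = excluded - set(library.roster)
    if unknown:
        raise LibraryLookupError(f"unknown strain(s): {sorted(unknown)}")
    if not excluded:
        return len(library.key_to_strains)
    return sum(
        1 for strains in library.key_to_strains.values() if strains - excluded
    )


def shared_between(
    library: VariantLibrary, a: str, b: str, chrom: str | None = None
) -> int:
    """|keys(a) ∩ keys(b)|, optionally restricted to one sequence."""
    ka, kb = library.strain_keys(a), library.strain_keys(b)
    common = ka & kb if a != b else ka
    if chrom is not None:
        known = {v.chrom for cs in library.callsets.values() for v in cs.variants}
        if chrom not in known:
            raise LibraryLookupError(f"unknown sequence {chrom!r}")
        common = {k for k in common if k.chrom == chrom}
    return len(common)


def chromosome_distribution(
    callset: StrainCallSet, chromosome_roster: Sequence[str]
) -> pd.DataFrame:
    """Counts and percentages per chromosome, with one bucket for every
    sequence not in the roster (unplaced scaffolds).

    Percentages are exact fractions of the strain total; the conventional
    2-decimal display is applied by the caller/table writer.
    """
    counts = {c: 0 for c in chromosome_roster}
    counts[SCAFFOLD_BUCKET] = 0
    roster_set = set(chromosome_roster)
    for v in callset.variants:
        bucket = v.chrom if v.chrom in roster_set else SCAFFOLD_BUCKET
        counts[bucket] += 1
    total = len(callset.variants)
    rows = [
        {
            "sequence": name,
            "count": n,
            "percent": (100.0 * n / total) if total else 0.0,
        }
        for name, n in counts.items()
    ]
    return pd.DataFrame(rows)


def window_profile(
    callset: StrainCallSet,
    window_size: int = 100_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-chromosome variant counts in consecutive windows of ``window_size``
    bp; window k covers positions [k*W+1, (k+1)*W].  Zero-count windows are
    retained; the final window may be partial.  When ``chrom_lengths`` is
    given, profiles extend to the chromosome end even past the last variant.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    positions: dict[str, list[int]] = {}
    for v in callset.variants:
        positions.setdefault(v.chrom, []).append(v.pos)
    chroms = set(positions)
    if chrom_lengths is not None:
        chroms |= set(chrom_lengths)
    profiles: dict[str, np.ndarray] = {}
    for chrom in sorted(chroms):
        pos = positions.get(chrom, [])
        max_pos = max(pos) if pos else 0
        if chrom_lengths is not None and chrom in chrom_lengths:
            max_pos = max(max_pos, chrom_lengths[chrom])
        n_windows = max(1, math.ceil(max_pos / window_size))
        counts = np.zeros(n_windows, dtype=int)
        for p in pos:
            counts[(p - 1) // window_size] += 1
        profiles[chrom] = counts
    return profiles


def library_summary(library: VariantLibrary) -> LibrarySummary:
    """Table-1-style summary: per-strain total, unique count, unique share
    (one decimal and floored integer), and union totals with/without each
    strain."""
    rows = []
    union_total = union_size(library)
    union_excluding: dict[str, int] = {}
    for s in library.roster:
        total = len(library.callsets[s])
        uniq = library.unique_count(s)
        pct = 100.0 * uniq / total if total else 100.0
        rows.append(
            {
                "strain": s,
                "total": total,
                "unique": uniq,
                "unique_pct": round(pct, 1),
                "unique_pct_floor": math.floor(pct),
            }
        )
        union_excluding[s] = union_size(library, {s})
    return LibrarySummary(pd.DataFrame(rows), union_total, union_excluding)
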