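"""Tetrad segregation scoring, dCAPS genotyping, and two-point map distance.

A single nuclear mutation segregates 2:2 in every complete tetrad; linkage to
a marker is read from pooled progeny as the recombinant fraction, and
distance in centimorgans is 100 × R/(P+R) (a mapping function is deliberately
not applied at the short distances involved — a Haldane-corrected value is
reported alongside for reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Progeny",
    "Tetrad",
    "MarkerDef",
    "MapEstimate",
    "Interval",
    "segregation_test",
    "dcaps_call",
    "classify_progeny",
    "map_distance",
    "mapping_interval",
    "read_tetrad_table",
    "read_marker_table",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

MUTANT = "mutant"
WILD = "wild"
MISSING = "missing"


@dataclass
class Progeny:
    id: str
    phenotype: str  # "mutant" | "wild"
    markers: dict[str, str] = field(default_factory=dict)  # name -> allele or "missing"

    def allele(self, marker: str) -> str:
        return self.markers.get(marker, MISSING)


@dataclass
class Tetrad:
    id: str
    progeny: list[Progeny]

    def __post_init__(self) -> None:
        if len(self.progeny) != 4:
            raise ValueError(f"tetrad {self.id}: expected 4 progeny, got {len(self.progeny)}")


@dataclass(frozen=True)
class MarkerDef:
    name: str
    chrom: str
    pos: int
    site: str = ""  # dCAPS recognition site
    cut_allele: str = ""  # allele whose amplicon is cut


@dataclass(frozen=True)
class MapEstimate:
    marker: str
    parental: int
    recombinant: int
    distance_cm: float
    haldane_cm: float


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class NoIntervalError(ValueError):
    """No marker lies within the requested linkage threshold."""


class UndefinedEstimateError(ValueError):
    """Map distance requested with zero informative progeny."""


def segregation_test(tetrads: Iterable[Tetrad]) -> tuple[list[bool], int, int]:
    """Score each tetrad for 2 mutant : 2 wild segregation.

    Returns (per-tetrad pass flags, pass count, excluded-with-warning count);
    a tetrad with any missing phenotype is excluded, not failed.
    """
    results: list[bool] = []
    excluded = 0
    for t in tetrads:
        phenos = [p.phenotype for p in t.progeny]
        if any(ph not in (MUTANT, WILD) for ph in phenos):
            excluded += 1
            results.append(False)
            continue
        results.append(phenos.count(MUTANT) == 2)
    return results, sum(results), excluded


def dcaps_call(amplicon: str, marker: MarkerDef) -> str:
    """Genotype a dCAPS amplicon: the cut allele is called when the
    recognition site occurs on either strand, else the other allele."""
    if not marker.site:
        raise ValueError(f"marker {marker.name} has no recognition site")
    amp = amplicon.upper()
    site = marker.site.upper()
    rc = amp.translate(_COMPLEMENT)[::-1]
    cut = site in amp or site in rc
    other = "uncut" if marker.cut_allele != "uncut" else "cut"
    return marker.cut_allele if cut else other


def classify_progeny(
    progeny: Progeny, marker: str, mutant_parent_allele: str
) -> str:
    """'parental' when phenotype and marker allele co-segregate as in the
    parents, 'recombinant' otherwise, 'uninformative' when the call is
    missing."""
    allele = progeny.allele(marker)
    if allele == MISSING:
        return "uninformative"
    if (progeny.phenotype == MUTANT) == (allele == mutant_parent_allele):
        return "parental"
    return "recombinant"


def map_distance(parental: int, recombinant: int, marker: str = "") -> MapEstimate:
    """Two-point distance from pooled progeny: 100·R/(P+R) cM, plus the
    Haldane-corrected value −50·ln(1−2r)."""
    n = parental + recombinant
    if n < 1:
        raise UndefinedEstimateError("no informative progeny")
    r = recombinant / n
    haldane = math.inf if r >= 0.5 else -50.0 * math.log(1.0 - 2.0 * r)
    return MapEstimate(marker, parental, recombinant, 100.0 * r, haldane)


def pooled_map_distance(
    tetrads: Iterable[Tetrad], marker: str, mutant_parent_allele: str
) -> MapEstimate:
    """Classify every informative spore across tetrads and estimate distance."""
    p = r = 0
    for t in tetrads:
        for sp in t.progeny:
            cls = classify_progeny(sp, marker, mutant_parent_allele)
            if cls == "parental":
                p += 1
            elif cls == "recombinant":
                r += 1
    return map_distance(p, r, marker)


MIN_HALF_WIDTH_BP = 100_000  # floor so a 0-cM marker still yields an interval


def mapping_interval(
    estimates: Sequence[MapEstimate],
    markers: Mapping[str, MarkerDef],
    cm_per_mb: float = 1.0,
    max_cm: float = 10.0,
    chrom_lengths: Mapping[str, int] | None = None,
) -> Interval:
    """Genomic interval implied by the closest linked marker.

    Centered on the marker with the smallest distance at or below ``max_cm``;
    half-width = distance/cm_per_mb Mb (min 0.1 Mb), clipped to chromosome
    bounds.  Candidate variants outside this interval are excluded downstream.
    """
    linked = [e for e in estimates if e.distance_cm <= max_cm and e.marker in markers]
    if not linked:
        raise NoIntervalError(f"no marker within {max_cm} cM")
    best = min(linked, key=lambda e: (e.distance_cm, e.marker))
    m = markers[best.marker]
    half = max(int(round(best.distance_cm / cm_per_mb * 1e6)), MIN_HALF_WIDTH_BP)
    start = max(1, m.pos - half)
    end = m.pos + half
    if chrom_lengths and m.chrom in chrom_lengths:
        end = min(end, chrom_lengths[m.chrom])
    return Interval(m.chrom, start, end)


# ---------------------------------------------------------------------------
# Tab-separated I/O


def read_tetrad_table(text: str) -> list[Tetrad]:
    """Read a tetrad table: header 'tetrad_id  progeny_id  phenotype  <markers...>',
    one row per spore; marker cells are allele labels or '.' for missing."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    if header[:3] != ["tetrad_id", "progeny_id", "phenotype"]:
        raise ValueError("tetrad table must start with tetrad_id/progeny_id/phenotype")
    marker_names = header[3:]
    by_tetrad: dict[str, list[Progeny]] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        tid, pid, pheno = cells[:3]
        alleles = {
            name: (MISSING if cell in (".", "") else cell)
            for name, cell in zip(marker_names, cells[3:])
        }
        by_tetrad.setdefault(tid, []).append(Progeny(pid, pheno, alleles))
    return [Tetrad(tid, spores) for tid, spores in by_tetrad.items()]


def write_tetrad_table(tetrads: Sequence[Tetrad], marker_names: Sequence[str]) -> str:
    rows = ["\t".join(["tetrad_id", "progeny_id", "phenotype", *marker_names])]
    for t in tetrads:
        for sp in t.progeny:
            cells = [t.id, sp.id, sp.phenotype]
            cells += [sp.allele(m) if sp.allele(m) != MISSING else "." for m in marker_names]
            rows.append("\t".join(cells))
    return "\n".join(rows) + "\n"


def read_marker_table(text: str) -> dict[str, MarkerDef]:
    """Read marker definitions: name, chrom, pos, site, cut_allele."""
    markers: dict[str, MarkerDef] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines:
        if ln.startswith("name\t"):
            continue
        name, chrom, pos, site, cut = (ln.split("\t") + ["", ""])[:5]
        markers[name] = MarkerDef(name, chrom, int(pos), site, cut)
    return markers
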