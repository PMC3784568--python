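"""End-to-end candidate identification: subtraction → annotation → interval
restriction → cross-checking → evidence flags → ranking.

The cascade mirrors the forward-genetics triage this package implements:
start from every change in the query strain, keep the ones no panel strain
shares, keep coding/splice changes, drop synonymous ones, keep changes inside
the meiotic mapping interval, then demote (never delete) candidates that are
seen in external strains or carry weak read support.  The surviving, ranked
list plus the stage-by-stage ledger is the analysis product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .effects import (
    CODING_CLASSES,
    EffectClass,
    EffectRecord,
    FilterLedger,
    GeneModel,
    annotate,
)
from .library import VariantLibrary, subtract
from .mapping import Interval
from .variants import StrainCallSet, Variant, VariantKey

__all__ = [
    "Thresholds",
    "Candidate",
    "CandidateLedger",
    "cross_check",
    "evidence_flags",
    "run_pipeline",
]

LOW_DEPTH = "LOW_DEPTH"
LOW_QUAL = "LOW_QUAL"
HET_SKIPPED = "het_skipped"


@dataclass(frozen=True)
class Thresholds:
    """Evidence thresholds.  The triage contrast motivating the defaults is a
    5-read / Q16.9 call versus a 122-read / Q214 call; flags demote, never
    remove."""

    min_depth: int = 10
    min_qual: float = 30.0

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_qual <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class Candidate:
    variant: Variant
    effects: list[EffectRecord]
    flags: frozenset[str]
    cross_hits: tuple[str, ...]

    @property
    def demoted(self) -> bool:
        return bool(self.flags) or bool(self.cross_hits)


@dataclass
class CandidateLedger:
    """Stage counts plus the ranked candidate list."""

    stages: FilterLedger
    candidates: list[Candidate]
    het_skipped: int = 0
    status: str = "ok"

    def to_tsv(self) -> str:
        rows = [
            "rank\tchrom\tpos\tref\talt\tgene\teffect\tresidue_change\t"
            "depth\tqual\tflags\tcross_check_hits"
        ]
        for rank, c in enumerate(self.candidates, start=1):
            eff = _primary_effect(c.effects)
            change = (
                f"{eff.ref_residues}>{eff.alt_residues}"
                if (eff.ref_residues or eff.alt_residues)
                else "."
            )
            rows.append(
                "\t".join(
                    [
                        str(rank),
                        c.variant.chrom,
                        str(c.variant.pos),
                        c.variant.ref,
                        c.variant.alt,
                        eff.gene_id or ".",
                        eff.effect.value,
                        change,
                        str(c.variant.depth),
                        f"{c.variant.qual:g}",
                        ",".join(sorted(c.flags)) or ".",
                        ",".join(c.cross_hits) or ".",
                    ]
                )
            )
        return "\n".join(rows) + "\n"

    def log_text(self) -> str:
        lines = [f"status: {self.status}", "stage\tinput\tremoved\tretained"]
        for name, n_in, rem, ret in self.stages.stages:
            lines.append(f"{name}\t{n_in}\t{rem}\t{ret}")
        if self.het_skipped:
            lines.append(f"# heterozygous calls skipped at annotation: {self.het_skipped}")
        lines.append(f"# ranked candidates: {len(self.candidates)}")
        return "\n".join(lines) + "\n"


def run_synthetic_analysis(
    world,
    thresholds: "Thresholds | None" = None,
    external_callsets: Sequence[StrainCallSet] = (),
) -> CandidateLedger:
    """End-to-end analysis of a simulated world: subtraction, tetrad mapping
    of the linked marker, interval restriction, annotation, and triage.

    The mapping interval is centred on the marker at the pooled-progeny
    distance; at desk-scale chromosome lengths the minimum interval width
    spans the marker's whole chromosome, mirroring the coarse chromosome-level
    localization a first mapping pass gives."""
    from .library import build_library
    from .mapping import mapping_interval, pooled_map_distance

    cfg = world.config
    lib = build_library(world.callsets)
    panel = [s for s in lib.roster if s != cfg.query_strain]
    est = pooled_map_distance(world.tetrads, cfg.marker_name, "parentA")
    interval = mapping_interval(
        [est],
        {cfg.marker_name: world.marker},
        cm_per_mb=1.0,
        max_cm=50.0,
        chrom_lengths=cfg.chrom_lengths(),
    )
    return run_pipeline(
        lib,
        cfg.query_strain,
        panel,
        world.models,
        world.genome,
        interval=interval,
        external_callsets=external_callsets,
        thresholds=thresholds or Thresholds(),
    )


def cross_check(
    variant: Variant, external_callsets: Sequence[StrainCallSet]
) -> list[str]:
    """Names of external strains (not in the library) carrying the same key.
    A non-empty result demotes the candidate — a change shared with an
    unrelated mutant cannot be causative."""
    key = variant.key
    return [cs.strain_name for cs in external_callsets if key in cs.keys()]


def evidence_flags(
    variant: Variant, min_depth: int = 10, min_qual: float = 30.0
) -> set[str]:
    """LOW_DEPTH / LOW_QUAL flags under strict-inequality thresholds."""
    if min_depth <= 0 or min_qual <= 0:
        raise ValueError("thresholds must be positive")
    flags: set[str] = set()
    if variant.depth < min_depth:
        flags.add(LOW_DEPTH)
    if variant.qual < min_qual:
        flags.add(LOW_QUAL)
    return flags


def _primary_effect(effects: Sequence[EffectRecord]) -> EffectRecord:
    coding = [e for e in effects if e.effect in CODING_CLASSES]
    return coding[0] if coding else effects[0]


def run_pipeline(
    library: VariantLibrary,
    query: str,
    panel: Iterable[str],
    models: Sequence[GeneModel],
    genome: Mapping[str, object],
    interval: Interval | None = None,
    external_callsets: Sequence[StrainCallSet] = (),
    thresholds: Thresholds = Thresholds(),
    interval_first: bool = False,
    hard_filter_flagged: bool = False,
) -> CandidateLedger:
    """Full triage of one query strain against a panel.

    Ranking: unflagged before flagged, no cross-check hits before hits, then
    higher depth, higher qual, and (chrom, pos) ascending as the final
    tie-break.  ``interval_first`` applies the interval restriction before
    effect annotation; the surviving set is identical either way, only the
    ledger's intermediate counts differ.
    """
    ledger = FilterLedger()
    src = library.callsets[query]
    total = len(src)
    if total == 0:
        ledger.add("total", 0, 0)
        return CandidateLedger(ledger, [], status="empty query call set")

    uniq = subtract(library, query, panel)
    ledger.add("unique", total, total - len(uniq))

    def in_interval(v: Variant) -> bool:
        return interval is None or interval.contains(v.chrom, v.pos)

    working = list(uniq.variants)
    if interval_first and interval is not None:
        kept = [v for v in working if in_interval(v)]
        ledger.add("in_interval", len(working), len(working) - len(kept))
        working = kept

    het_skipped = sum(1 for v in working if v.zygosity != "hom_alt")
    hom = [v for v in working if v.zygosity == "hom_alt"]

    effects_by_key: dict[VariantKey, list[EffectRecord]] = {}
    for v in hom:
        effects_by_key[v.key] = annotate(v, models, genome)

    def classes(v: Variant) -> set[EffectClass]:
        return {r.effect for r in effects_by_key.get(v.key, [])}

    coding = [v for v in hom if classes(v) & CODING_CLASSES]
    ledger.add("coding_or_splice", len(working), len(working) - len(coding))

    nonsyn = [
        v for v in coding if classes(v) & (CODING_CLASSES - {EffectClass.SYNONYMOUS})
    ]
    ledger.add("non_synonymous", len(coding), len(coding) - len(nonsyn))

    if not interval_first and interval is not None:
        kept = [v for v in nonsyn if in_interval(v)]
        ledger.add("in_interval", len(nonsyn), len(nonsyn) - len(kept))
        nonsyn = kept

    candidates = [
        Candidate(
            variant=v,
            effects=effects_by_key[v.key],
            flags=frozenset(
                evidence_flags(v, thresholds.min_depth, thresholds.min_qual)
            ),
            cross_hits=tuple(cross_check(v, external_callsets)),
        )
        for v in nonsyn
    ]
    clean = [c for c in candidates if not c.cross_hits]
    ledger.add("after_cross_check", len(candidates), len(candidates) - len(clean))

    if hard_filter_flagged:
        candidates = [c for c in candidates if not c.demoted]

    candidates.sort(
        key=lambda c: (
            bool(c.flags),
            bool(c.cross_hits),
            -c.variant.depth,
            -c.variant.qual,
            c.variant.chrom,
            c.variant.pos,
        )
    )
    status = "ok" if candidates else "no candidate survived"
    return CandidateLedger(ledger, candidates, het_skipped=het_skipped, status=status)
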