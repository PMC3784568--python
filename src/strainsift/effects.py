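"""Coding-effect annotation of variants against gene models.

Reproduces the effect-class semantics of a coding-only annotator run
(no upstream/downstream/intergenic/intron/UTR calls, homozygous calls only):
a variant is coding iff its changed bases intersect a CDS interval or the
2-bp intronic window flanking a CDS boundary; everything else is
``noncoding`` and is dropped by the downstream filter ledger.

Substitutions are classified by comparing the translated reference CDS with
the translated mutated CDS; in-frame indel residue changes are likewise
computed by whole-CDS translate-and-diff rather than local codon arithmetic,
which keeps edits spanning codon boundaries (like a deletion of the last
three residues before the stop) correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_mw

from .variants import ReferenceMismatchError, Variant, VariantKey, ref_slice

__all__ = [
    "GeneModel",
    "EffectClass",
    "EffectRecord",
    "FilterLedger",
    "load_gene_models",
    "translate",
    "molecular_weight",
    "annotate",
    "apply_filters",
]

SPLICE_WINDOW = 2  # intronic bases on each side of a CDS boundary

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class EffectClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    FRAMESHIFT = "frameshift"
    SPLICE_BOUNDARY = "splice_boundary"
    NONCODING = "noncoding"


CODING_CLASSES = frozenset(EffectClass) - {EffectClass.NONCODING}


@dataclass
class GeneModel:
    """Strand-aware CDS interval set for one transcript.

    ``cds_intervals`` are 1-based closed genomic intervals in ascending
    genomic order; extraction reverse-complements for minus-strand genes so
    the returned CDS always reads 5'→3' in transcript orientation.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_intervals: list[tuple[int, int]]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds_intervals = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        if self.cds_length % 3 != 0:
            self.warnings.append("cds_length_not_multiple_of_3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def cds_sequence(self, genome: Mapping[str, object]) -> str:
        parts = [ref_slice(genome, self.chrom, s, e) for s, e in self.cds_intervals]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, or None outside CDS."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                plus_coord = offset + (pos - s) + 1
                if self.strand == "+":
                    return plus_coord
                return self.cds_length - plus_coord + 1
            offset += e - s + 1
        return None

    def splice_windows(self) -> list[tuple[int, int]]:
        """2-bp intronic windows flanking internal CDS boundaries."""
        wins: list[tuple[int, int]] = []
        for (s1, e1), (s2, e2) in zip(self.cds_intervals, self.cds_intervals[1:]):
            wins.append((e1 + 1, min(e1 + SPLICE_WINDOW, s2 - 1)))
            wins.append((max(s2 - SPLICE_WINDOW, e1 + 1), s2 - 1))
        return wins


@dataclass(frozen=True)
class EffectRecord:
    """One variant × transcript effect call."""

    variant_key: VariantKey
    gene_id: str
    effect: EffectClass
    ref_residues: str = ""
    alt_residues: str = ""
    protein_position: int | None = None
    residues_removed: int = 0
    residues_added: int = 0


@dataclass
class FilterLedger:
    """Stage-by-stage accounting of a variant filter cascade."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (stage name, input count, removed count, retained count)

    def add(self, name: str, input_count: int, removed: int) -> None:
        retained = input_count - removed
        if self.stages and self.stages[-1][3] != input_count:
            raise ValueError(
                f"stage {name!r}: input {input_count} != previous retained "
                f"{self.stages[-1][3]}"
            )
        self.stages.append((name, input_count, removed, retained))

    @property
    def final_retained(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.stages, columns=["stage", "input", "removed", "retained"]
        )


# ---------------------------------------------------------------------------
# Gene model loading


def load_gene_models(gff_text: str, genome: Mapping[str, object]) -> list[GeneModel]:
    """Parse GFF3 into per-transcript gene models.

    CDS features are grouped by their Parent transcript (mRNA features when
    present, otherwise the raw Parent attribute).  Models whose CDS length is
    not a multiple of 3, or whose extracted CDS lacks a terminal stop, carry
    a warning flag rather than raising.
    """
    db = gffutils.create_db(
        gff_text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    groups: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "unparented"])
        for parent in parents:
            groups.setdefault(parent, []).append(cds)

    models: list[GeneModel] = []
    for tx_id, cds_list in groups.items():
        chroms = {c.seqid for c in cds_list}
        strands = {c.strand for c in cds_list}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{tx_id}: CDS features span chromosomes/strands")
        chrom, strand = chroms.pop(), strands.pop()
        intervals = sorted((c.start, c.end) for c in cds_list)
        for s, e in intervals:
            if e > len(genome[chrom]) or s < 1:
                raise ValueError(f"{tx_id}: CDS interval {s}-{e} outside {chrom}")
        model = GeneModel(tx_id, chrom, strand, intervals)
        cds_seq = model.cds_sequence(genome)
        if len(cds_seq) % 3 == 0 and cds_seq[-3:].upper() not in ("TAA", "TAG", "TGA"):
            model.warnings.append("no_terminal_stop")
        models.append(model)
    models.sort(key=lambda m: (m.chrom, m.span))
    return models


# ---------------------------------------------------------------------------
# Translation and protein statistics


class FrameError(ValueError):
    """CDS length is not a multiple of 3."""


def translate(cds: str) -> str:
    """Translate a CDS with the standard nuclear codon table, returning
    residues up to and excluding the first stop codon.

    A 948-nt single-exon CDS with one terminal stop yields 315 residues.
    An internal stop truncates the product and emits a warning.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} not a multiple of 3")
    full = str(Seq(cds).translate())
    stop_at = full.find("*")
    if stop_at == -1:
        return full
    if stop_at < len(full) - 1:
        warnings.warn(
            f"internal stop codon at codon {stop_at + 1}; product truncated",
            stacklevel=2,
        )
    return full[:stop_at]


def molecular_weight(protein: str) -> float:
    """Average molecular weight of a peptide in daltons (residues + one water)."""
    if not protein:
        return 18.02
    bad = set(protein.upper()) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
    return float(_bio_mw(protein.upper(), seq_type="protein"))


# ---------------------------------------------------------------------------
# Annotation


def _changed_span(v: Variant) -> tuple[int, int] | None:
    """Genomic span of the bases a normalized variant actually changes.

    For anchored indels the anchor base is untouched: a deletion changes
    pos+1..end; an insertion adds bases between pos and pos+1 (span None,
    handled via the insertion point).  SNP/MNP change pos..end.
    """
    lr, la = len(v.ref), len(v.alt)
    if lr == la:
        return (v.pos, v.end)
    if lr > la:  # deletion
        return (v.pos + la, v.end)
    return None  # pure insertion: no reference base changes


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _diff_proteins(ref_prot: str, alt_prot: str) -> tuple[str, str, int]:
    """Minimal residue-level diff: (removed, added, 1-based protein position)."""
    i = 0
    while i < len(ref_prot) and i < len(alt_prot) and ref_prot[i] == alt_prot[i]:
        i += 1
    j = 0
    while (
        j < len(ref_prot) - i
        and j < len(alt_prot) - i
        and ref_prot[len(ref_prot) - 1 - j] == alt_prot[len(alt_prot) - 1 - j]
    ):
        j += 1
    return ref_prot[i : len(ref_prot) - j], alt_prot[i : len(alt_prot) - j], i + 1


def _mutate_cds(
    model: GeneModel, genome: Mapping[str, object], v: Variant
) -> str | None:
    """Apply a variant to the model's CDS, returning the mutated CDS in
    transcript orientation, or None when the edit is not containable within a
    single CDS interval."""
    for idx, (s, e) in enumerate(model.cds_intervals):
        # the REF span (minus the anchor for indels) must sit inside one exon;
        # the anchor base itself may lie one base upstream of the exon.
        span = _changed_span(v)
        if span is None:  # insertion: bases added between pos and pos+1
            if not (s <= v.pos < e):
                continue
        else:
            if not _spans_overlap(span, (s, e)):
                continue
            if not (s <= span[0] and span[1] <= e):
                return None  # changed bases cross the exon edge
        exon = ref_slice(genome, model.chrom, s, e)
        rel = v.pos - s  # may be -1: anchored deletion whose anchor precedes the exon
        if rel < 0:
            if rel != -1 or len(v.alt) != 1:
                return None
            new_exon = exon[v.end - s + 1 :]
        else:
            new_exon = exon[:rel] + v.alt + exon[rel + len(v.ref) :]
        parts = []
        for k, (ps, pe) in enumerate(model.cds_intervals):
            parts.append(new_exon if k == idx else ref_slice(genome, model.chrom, ps, pe))
        seq = "".join(parts)
        return revcomp(seq) if model.strand == "-" else seq
    return None


def annotate(
    variant: Variant,
    models: Sequence[GeneModel],
    genome: Mapping[str, object],
) -> list[EffectRecord]:
    """Classify a normalized variant against every transcript it touches.

    Returns one record per overlapped transcript; variants touching no CDS or
    splice window yield a single ``noncoding`` record.
    """
    observed = ref_slice(genome, variant.chrom, variant.pos, variant.end)
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} REF {variant.ref!r} != genome {observed!r}"
        )
    records: list[EffectRecord] = []
    span = _changed_span(variant)
    touch = span if span is not None else (variant.pos, variant.pos + 1)
    for model in models:
        if model.chrom != variant.chrom:
            continue
        lo, hi = model.span
        if not _spans_overlap(touch, (lo - SPLICE_WINDOW, hi + SPLICE_WINDOW)):
            continue
        rec = _annotate_one(variant, model, genome, span)
        if rec is not None:
            records.append(rec)
    if not records:
        records.append(
            EffectRecord(variant.key, gene_id="", effect=EffectClass.NONCODING)
        )
    return records


def _annotate_one(
    v: Variant,
    model: GeneModel,
    genome: Mapping[str, object],
    span: tuple[int, int] | None,
) -> EffectRecord | None:
    in_cds = False
    if span is not None:
        in_cds = any(_spans_overlap(span, iv) for iv in model.cds_intervals)
    else:
        # insertion is coding when its insertion point lies strictly inside
        # a CDS interval (inserting between two coding bases)
        in_cds = any(s <= v.pos < e for s, e in model.cds_intervals)

    if not in_cds:
        probe = span if span is not None else (v.pos, v.pos + 1)
        for ws, we in model.splice_windows():
            if ws <= we and _spans_overlap(probe, (ws, we)):
                return EffectRecord(v.key, model.gene_id, EffectClass.SPLICE_BOUNDARY)
        return None

    mutated = _mutate_cds(model, genome, v)
    if mutated is None:
        # coding bases are affected but the edit crosses an exon edge
        return EffectRecord(v.key, model.gene_id, EffectClass.SPLICE_BOUNDARY)

    delta = len(v.alt) - len(v.ref)
    if delta != 0 and abs(delta) % 3 != 0:
        return EffectRecord(v.key, model.gene_id, EffectClass.FRAMESHIFT)

    ref_cds = model.cds_sequence(genome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref_full = str(Seq(_pad_frame(ref_cds)).translate())
        alt_full = str(Seq(_pad_frame(mutated)).translate())
    ref_prot = _clip_at_stop(ref_full)
    alt_prot = _clip_at_stop(alt_full)
    removed, added, ppos = _diff_proteins(ref_prot, alt_prot)

    if delta == 0:
        if ref_prot == alt_prot and _stop_intact(ref_full, alt_full):
            return EffectRecord(
                v.key, model.gene_id, EffectClass.SYNONYMOUS,
                ref_residues=removed, alt_residues=added,
            )
        if len(alt_prot) < len(ref_prot) and _gained_stop(ref_full, alt_full):
            return EffectRecord(
                v.key, model.gene_id, EffectClass.NONSENSE,
                ref_residues=removed, alt_residues=added, protein_position=ppos,
            )
        if _lost_terminal_stop(ref_full, alt_full):
            return EffectRecord(
                v.key, model.gene_id, EffectClass.STOP_LOSS,
                ref_residues=removed, alt_residues=added, protein_position=ppos,
            )
        return EffectRecord(
            v.key, model.gene_id, EffectClass.MISSENSE,
            ref_residues=removed, alt_residues=added, protein_position=ppos,
        )

    effect = EffectClass.INFRAME_DELETION if delta < 0 else EffectClass.INFRAME_INSERTION
    return EffectRecord(
        v.key, model.gene_id, effect,
        ref_residues=removed, alt_residues=added, protein_position=ppos,
        residues_removed=len(removed), residues_added=len(added),
    )


def _pad_frame(cds: str) -> str:
    return cds[: len(cds) - len(cds) % 3]


def _clip_at_stop(prot_full: str) -> str:
    i = prot_full.find("*")
    return prot_full if i == -1 else prot_full[:i]


def _stop_intact(ref_full: str, alt_full: str) -> bool:
    return ("*" in ref_full) == ("*" in alt_full)


def _gained_stop(ref_full: str, alt_full: str) -> bool:
    return alt_full.find("*") != -1 and (
        ref_full.find("*") == -1 or alt_full.find("*") < ref_full.find("*")
    )


def _lost_terminal_stop(ref_full: str, alt_full: str) -> bool:
    return ref_full.endswith("*") and "*" not in alt_full


# ---------------------------------------------------------------------------
# Filter cascade


def apply_filters(
    effects: Iterable[EffectRecord],
    keep_classes: frozenset[EffectClass] | None = None,
) -> tuple[list[EffectRecord], FilterLedger]:
    """Drop noncoding records, then synonymous ones, counting distinct
    variants (not records) at each stage.

    ``keep_classes`` overrides the retained set of the second stage; the
    default keeps every coding class except synonymous.
    """
    effects = list(effects)
    if keep_classes is None:
        keep_classes = frozenset(CODING_CLASSES - {EffectClass.SYNONYMOUS})

    def n_variants(recs: Iterable[EffectRecord]) -> int:
        return len({r.variant_key for r in recs})

    ledger = FilterLedger()
    total = n_variants(effects)

    coding = [r for r in effects if r.effect != EffectClass.NONCODING]
    # a variant is coding if ANY of its transcript records is coding
    coding_keys = {r.variant_key for r in coding}
    stage1 = [r for r in effects if r.variant_key in coding_keys]
    ledger.add("coding_or_splice", total, total - n_variants(stage1))

    kept_keys = {r.variant_key for r in stage1 if r.effect in keep_classes}
    stage2 = [r for r in stage1 if r.variant_key in kept_keys]
    ledger.add(
        "non_synonymous", n_variants(stage1), n_variants(stage1) - n_variants(stage2)
    )
    return stage2, ledger
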