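"""Reading, normalizing, keying and writing per-strain variant call sets.

The subtraction contract downstream is that output VCF records are the
*original* record lines minus the shared ones, so every parsed variant keeps
its source line verbatim (``raw_record``) and writing never re-serializes
fields.  Identity for all set operations is the normalized
(chrom, pos, ref, alt) tuple: evidence fields (QUAL, DP, GT) never enter it.

Coordinates are 1-based, fully closed, VCF-style; indels carry a single
anchoring reference base and are left-aligned to the smallest equivalent
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "Variant",
    "VariantKey",
    "StrainCallSet",
    "VcfFormatError",
    "VcfParseError",
    "ReferenceMismatchError",
    "parse_vcf",
    "write_vcf",
    "normalize",
    "variant_key",
    "classify_variant",
]


class VcfFormatError(ValueError):
    """Document-level malformation (e.g. missing #CHROM header line)."""


class VcfParseError(ValueError):
    """Record-level malformation; message names the 1-based line number."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference genome."""


class VariantKey(NamedTuple):
    """Identity of an allelic change, taken from the normalized representation."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class Variant:
    """One normalized-or-raw SNP/indel call.

    ``depth_known`` is False when the source record carried no DP; such calls
    keep depth 0 and are flagged rather than rejected, since historical VCFs
    are heterogeneous about INFO keys.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    zygosity: str = "hom_alt"  # "hom_alt" | "het"
    raw_record: str = ""
    depth_known: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference position covered by REF (1-based closed)."""
        return self.pos + len(self.ref) - 1


@dataclass
class StrainCallSet:
    """Ordered variant calls for one strain plus enough source metadata to
    reconstruct the original file."""

    strain_name: str
    variants: list[Variant] = field(default_factory=list)
    header_lines: list[str] = field(default_factory=list)
    source_path: str | None = None

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}

    def sort(self) -> None:
        self.variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


_ZYG_HOM = "hom_alt"
_ZYG_HET = "het"


def _parse_info_depth(info: str) -> tuple[int, bool]:
    for entry in info.split(";"):
        if entry.startswith("DP="):
            try:
                return int(entry[3:]), True
            except ValueError:
                break
    return 0, False


def _parse_gt(fmt: str, sample: str) -> str:
    keys = fmt.split(":")
    vals = sample.split(":")
    try:
        gt = vals[keys.index("GT")]
    except (ValueError, IndexError):
        return _ZYG_HOM
    alleles = {a for a in gt.replace("|", "/").split("/") if a not in (".", "")}
    return _ZYG_HET if len(alleles) > 1 else _ZYG_HOM


def parse_vcf(
    text: str | Iterable[str],
    strain_name: str = "",
    source_path: str | None = None,
) -> StrainCallSet:
    """Parse a VCF v4.x document into a :class:`StrainCallSet`.

    Multi-allelic records are split into one Variant per ALT allele (each
    retaining the same raw record line).  QUAL '.' maps to 0; depth comes
    from INFO DP (0 and ``depth_known=False`` when absent); zygosity from the
    first sample's GT when FORMAT/sample columns exist, else hom_alt.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    header_lines: list[str] = []
    variants: list[Variant] = []
    seen: set[VariantKey] = set()
    saw_chrom_header = False

    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        if line.startswith("#"):
            header_lines.append(line)
            if line.startswith("#CHROM"):
                saw_chrom_header = True
            continue
        if not saw_chrom_header:
            raise VcfFormatError("missing #CHROM header line before records")
        fields = line.split("\t")
        if len(fields) < 8:
            raise VcfParseError(
                f"line {lineno}: expected >=8 tab-separated columns, got {len(fields)}"
            )
        chrom, pos_s, _id, ref, alt_field, qual_s, _filt, info = fields[:8]
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(f"line {lineno}: non-numeric POS {pos_s!r}") from None
        if pos < 1:
            raise VcfParseError(f"line {lineno}: POS must be >= 1, got {pos}")
        qual = 0.0 if qual_s in (".", "") else _try_float(qual_s, lineno)
        depth, depth_known = _parse_info_depth(info)
        if len(fields) >= 10:
            zyg = _parse_gt(fields[8], fields[9])
        else:
            zyg = _ZYG_HOM
        for alt in alt_field.split(","):
            if alt in (".", "", "<*>") or set(alt) - set("ACGTNacgtn"):
                continue  # symbolic/missing alts are out of scope
            if ref.upper() == alt.upper():
                continue
            v = Variant(
                chrom=chrom,
                pos=pos,
                ref=ref.upper(),
                alt=alt.upper(),
                qual=qual,
                depth=depth,
                zygosity=zyg,
                raw_record=line,
                depth_known=depth_known,
            )
            if v.key in seen:
                continue  # duplicate spelling of the same change
            seen.add(v.key)
            variants.append(v)

    if not saw_chrom_header:
        raise VcfFormatError("missing #CHROM header line")
    cs = StrainCallSet(strain_name, variants, header_lines, source_path)
    cs.sort()
    return cs


def _try_float(s: str, lineno: int) -> float:
    try:
        return float(s)
    except ValueError:
        raise VcfParseError(f"line {lineno}: non-numeric QUAL {s!r}") from None


def write_vcf(callset: StrainCallSet) -> str:
    """Serialize a call set as header lines followed by the original record
    lines, in callset order.  Variants split from one multi-allelic record
    share a raw line, which is emitted once."""
    out: list[str] = list(callset.header_lines)
    last_raw: str | None = None
    for v in callset.variants:
        if v.raw_record and v.raw_record == last_raw:
            continue
        out.append(v.raw_record)
        last_raw = v.raw_record
    return "\n".join(out) + "\n" if out else ""


# ---------------------------------------------------------------------------
# Reference access and normalization


def ref_slice(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Reference bases for [start, end] 1-based closed, upper-cased.

    Accepts plain ``{chrom: str}`` mappings or pyfaidx-style objects whose
    items support slicing and str().
    """
    seq = genome[chrom]
    return str(seq[start - 1 : end]).upper()


def normalize(variant: Variant, genome: Mapping[str, object]) -> Variant:
    """Left-align and trim a variant to its canonical minimal representation.

    Repeatedly drops a shared terminal base (re-extending left from the
    reference when an allele would empty) and then strips shared leading
    bases; guarantees that indels keep exactly one anchoring base and sit at
    the smallest equivalent position.  SNPs pass through unchanged.
    Idempotent; raises :class:`ReferenceMismatchError` when REF disagrees
    with the genome.
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    observed = ref_slice(genome, variant.chrom, pos, pos + len(ref) - 1)
    if observed != ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{pos} REF {ref!r} != reference {observed!r}"
        )
    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            last = ref[-1]
            ref, alt = ref[:-1], alt[:-1]
            changed = True
            if not ref or not alt:
                if pos == 1:  # cannot extend past the chromosome start; undo
                    ref, alt = ref + last, alt + last
                    break
                pos -= 1
                base = ref_slice(genome, variant.chrom, pos, pos)
                ref, alt = base + ref, base + alt
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
    if ref == variant.ref and alt == variant.alt and pos == variant.pos:
        return variant
    return replace(variant, pos=pos, ref=ref, alt=alt)


def variant_key(variant: Variant) -> VariantKey:
    """Identity key of a normalized variant (chrom, pos, ref, alt)."""
    return variant.key


def classify_variant(variant: Variant) -> str:
    """Classify a normalized variant as 'snp', 'insertion', 'deletion' or 'mnp'."""
    lr, la = len(variant.ref), len(variant.alt)
    if lr == 1 and la == 1:
        return "snp"
    if lr > la:
        return "deletion"
    if la > lr:
        return "insertion"
    return "mnp"


def normalize_callset(callset: StrainCallSet, genome: Mapping[str, object]) -> StrainCallSet:
    """Normalize every member, re-deduplicate by key, and re-sort."""
    seen: set[VariantKey] = set()
    out: list[Variant] = []
    for v in callset.variants:
        nv = normalize(v, genome)
        if nv.key in seen:
            continue
        seen.add(nv.key)
        out.append(nv)
    cs = StrainCallSet(callset.strain_name, out, list(callset.header_lines), callset.source_path)
    cs.sort()
    return cs
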