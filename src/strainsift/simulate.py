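"""Synthetic strain-panel worlds for exercising the whole pipeline.

Emulates the structure the analysis assumes: a reference genome with
single- and two-exon genes, a panel of strains sharing a block-structured
ancestral polymorphism pool (polymorphisms concentrated on designated
chromosome regions, so some strains show ~90% of their changes on a few
chromosomes), per-strain private variants, one query strain carrying a
planted causative coding change, and tetrads segregating the mutation 2:2
with a configurable marker–mutation recombination fraction.

The sharing model is an ancestral pool, not a coalescent: a strain carries a
pool variant iff the variant lies in one of its blocks, plus a small global
background rate.  That is sufficient to reproduce the union/subtraction
arithmetic and the concentrated per-chromosome distributions without
population-genetic machinery.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .effects import GeneModel, revcomp
from .mapping import MUTANT, WILD, MarkerDef, Progeny, Tetrad
from .variants import StrainCallSet, Variant, VariantKey, normalize, ref_slice

__all__ = [
    "SimConfig",
    "CausativeSpec",
    "simulate_genome",
    "simulate_panel",
    "plant_causative",
    "simulate_tetrads",
    "genome_to_fasta",
    "models_to_gff3",
]

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class CausativeSpec:
    """What to plant in the query strain.

    kind: 'inframe_del_before_stop' (anchored deletion of the ``length``
    coding bases immediately 5' of the stop codon), 'missense', or
    'frameshift' (1-bp deletion mid-CDS unless ``length`` says otherwise).
    """

    kind: str = "inframe_del_before_stop"
    length: int = 9
    gene_id: str | None = None  # None: pick the first suitable gene
    qual: float = 214.0  # evidence mirrors a well-supported call
    depth: int = 122


@dataclass
class SimConfig:
    """Stated world for the synthetic panel.

    Defaults follow the structure of the real panel at desk scale: 17
    chromosomes, 16 strains, block-concentrated ancestral polymorphism on
    five designated chromosomes for most strains, and a causative in-frame
    deletion of 9 nt immediately before a stop codon in the query strain.
    """

    seed: int = 0
    n_chromosomes: int = 17
    chrom_length: int = 120_000
    n_genes: int = 30
    cds_codons_min: int = 100
    cds_codons_max: int = 320
    two_exon_prob: float = 0.3
    minus_strand_prob: float = 0.5
    n_strains: int = 16
    query_strain: str = "strain_01"
    pool_size: int = 6000
    concentrated_chromosomes: int = 5  # blocks drawn from this many chromosomes
    block_fraction: float = 0.9  # fraction of a block chromosome covered
    # 0.025 makes the expected share of a strain's changes on its five block
    # chromosomes ≈90% at the default pool/private sizes (see docs/methods.md)
    background_rate: float = 0.025
    private_per_strain: int = 120
    # explicit per-strain (chrom, start, end) block lists; None = draw at random
    blocks: dict[str, list[tuple[str, int, int]]] | None = None
    indel_fraction: float = 0.1
    max_indel_len: int = 6
    qual_range: tuple[float, float] = (30.0, 250.0)
    depth_range: tuple[int, int] = (20, 160)
    causative: CausativeSpec = field(default_factory=CausativeSpec)
    n_tetrads: int = 30
    crossover_prob: float = 0.06
    marker_name: str = "marker1"
    marker_offset: int = 5000  # bp between the linked marker and the mutation

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def strain_names(self) -> list[str]:
        return [f"strain_{i + 1:02d}" for i in range(self.n_strains)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


# ---------------------------------------------------------------------------
# Genome and gene models


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons−2) random sense codons + one stop codon."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random uniform-composition chromosomes with non-overlapping genes.

    Every gene has a valid CDS (ATG start, terminal stop, length divisible by
    3, no internal stop); two-exon genes get a canonical GT..AG intron.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chrom_names()
    genome = {
        c: "".join(BASES[i] for i in rng.integers(4, size=config.chrom_length))
        for c in chrom_names
    }
    models: list[GeneModel] = []
    # spread genes round-robin over chromosomes, sequential placement
    cursors = {c: 2000 for c in chrom_names}
    for g in range(config.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        n_codons = int(rng.integers(config.cds_codons_min, config.cds_codons_max + 1))
        cds = _random_cds(rng, n_codons)
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        two_exon = rng.random() < config.two_exon_prob and n_codons > 40
        tx = cds if strand == "+" else revcomp(cds)
        start = cursors[chrom]
        if two_exon:
            # split the spliced CDS (genomic plus-orientation) at a random point
            cut = int(rng.integers(30, len(tx) - 30))
            intron_len = int(rng.integers(60, 200))
            intron = (
                "GT"
                + "".join(BASES[i] for i in rng.integers(4, size=intron_len - 4))
                + "AG"
            )
            embedded = tx[:cut] + intron + tx[cut:]
            iv1 = (start, start + cut - 1)
            iv2 = (start + cut + intron_len, start + len(embedded) - 1)
            intervals = [iv1, iv2]
        else:
            embedded = tx
            intervals = [(start, start + len(tx) - 1)]
        end = start + len(embedded) - 1
        if end + 2000 > config.chrom_length:
            raise ValueError(
                f"cannot place gene {g} on {chrom}: chromosome too short "
                f"for n_genes={config.n_genes}"
            )
        genome[chrom] = genome[chrom][: start - 1] + embedded + genome[chrom][end:]
        models.append(GeneModel(f"g{g + 1:03d}", chrom, strand, intervals))
        cursors[chrom] = end + int(rng.integers(1500, 3000))
    for m in models:
        assert not m.warnings, f"{m.gene_id}: {m.warnings}"
    return genome, models


def genome_to_fasta(genome: Mapping[str, str], width: int = 70) -> str:
    out: list[str] = []
    for name, seq in genome.items():
        out.append(f">{name}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def models_to_gff3(models: Sequence[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.span
        gene_id = f"{m.gene_id}.gene"
        lines.append(
            f"{m.chrom}\tsim\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={gene_id}"
        )
        lines.append(
            f"{m.chrom}\tsim\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id};Parent={gene_id}"
        )
        for s, e in m.cds_intervals:
            lines.append(
                f"{m.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\tParent={m.gene_id}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Strain panel


_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample",
]


def _vcf_line(v: Variant) -> str:
    gt = "1/1" if v.zygosity == "hom_alt" else "0/1"
    qual = f"{v.qual:g}"
    return (
        f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\tPASS\tDP={v.depth}\tGT\t{gt}"
    )


def _make_variant(
    rng: np.random.Generator,
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    config: SimConfig,
) -> Variant | None:
    """One random SNP or anchored indel at (chrom, pos); None if unbuildable."""
    ref_base = genome[chrom][pos - 1]
    if rng.random() >= config.indel_fraction:
        alt = BASES[rng.integers(4)]
        while alt == ref_base:
            alt = BASES[rng.integers(4)]
        ref, alt_allele = ref_base, alt
    else:
        ln = int(rng.integers(1, config.max_indel_len + 1))
        if rng.random() < 0.5 and pos + ln <= len(genome[chrom]):
            ref = genome[chrom][pos - 1 : pos + ln]  # deletion
            alt_allele = ref_base
        else:
            ins = "".join(BASES[i] for i in rng.integers(4, size=ln))
            ref = ref_base
            alt_allele = ref_base + ins
    qual = float(rng.uniform(*config.qual_range))
    depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
    v = Variant(chrom, pos, ref, alt_allele, round(qual, 1), depth)
    v = normalize(v, genome)
    return v


def simulate_panel(
    config: SimConfig,
    genome: Mapping[str, str],
    models: Sequence[GeneModel] | None = None,
) -> list[StrainCallSet]:
    """Ancestral pool + blocks + private variants, one call set per strain.

    A strain carries a pool variant iff it lies in one of the strain's blocks
    or (with probability ``background_rate``) anywhere; private variants are
    unique to their strain.  All calls are hom_alt with QUAL/DP sampled
    uniformly from the configured ranges.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom_names = config.chrom_names()
    strains = config.strain_names()

    # distinct variant positions genome-wide
    used: set[tuple[str, int]] = set()

    def sample_position() -> tuple[str, int]:
        while True:
            chrom = chrom_names[rng.integers(len(chrom_names))]
            pos = int(rng.integers(2, config.chrom_length - config.max_indel_len - 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    # pool variants
    pool: list[Variant] = []
    pool_keys: set[VariantKey] = set()
    while len(pool) < config.pool_size:
        chrom, pos = sample_position()
        v = _make_variant(rng, genome, chrom, pos, config)
        if v is None or v.key in pool_keys:
            continue
        pool_keys.add(v.key)
        pool.append(v)

    # per-strain blocks: each strain concentrates on a subset of chromosomes
    if config.blocks is not None:
        blocks = {s: list(config.blocks.get(s, [])) for s in strains}
    else:
        blocks = {}
        block_span = int(config.block_fraction * config.chrom_length)
        n_conc = min(config.concentrated_chromosomes, len(chrom_names))
        for s in strains:
            chosen = rng.choice(len(chrom_names), size=n_conc, replace=False)
            strain_blocks = []
            for ci in chosen:
                start = int(rng.integers(1, config.chrom_length - block_span + 1))
                strain_blocks.append((chrom_names[ci], start, start + block_span - 1))
            blocks[s] = strain_blocks

    def in_blocks(s: str, v: Variant) -> bool:
        return any(c == v.chrom and a <= v.pos <= b for c, a, b in blocks[s])

    carriers: dict[str, list[Variant]] = {s: [] for s in strains}
    for v in pool:
        for s in strains:
            if in_blocks(s, v) or rng.random() < config.background_rate:
                # evidence is per-strain, identity is shared
                q = round(float(rng.uniform(*config.qual_range)), 1)
                d = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
                carriers[s].append(replace(v, qual=q, depth=d))

    # private variants
    for s in strains:
        n_priv = config.private_per_strain
        added = 0
        while added < n_priv:
            chrom, pos = sample_position()
            v = _make_variant(rng, genome, chrom, pos, config)
            if v is None or v.key in pool_keys:
                continue
            pool_keys.add(v.key)  # reserve so no other strain reuses it
            carriers[s].append(v)
            added += 1

    callsets = []
    for s in strains:
        variants = [replace(v, raw_record=_vcf_line(v)) for v in carriers[s]]
        cs = StrainCallSet(s, variants, list(_VCF_HEADER))
        cs.sort()
        callsets.append(cs)
    return callsets


# ---------------------------------------------------------------------------
# Planted causative mutation


def _del_before_stop(gene: GeneModel, genome: Mapping[str, str], length: int) -> Variant:
    """Anchored deletion of the ``length`` coding bases immediately 5' of the
    stop codon, strand-aware."""
    if gene.strand == "+":
        s, e = gene.cds_intervals[-1]
        # stop codon occupies e-2..e; deleted span e-2-length..e-3
        del_end = e - 3
        del_start = del_end - length + 1
        anchor = del_start - 1
        ref = ref_slice(genome, gene.chrom, anchor, del_end)
        alt = ref[0]
        return Variant(gene.chrom, anchor, ref, alt, 0.0, 0)
    s, e = gene.cds_intervals[0]
    # minus strand: stop codon at genomic s..s+2; bases before stop are s+3..s+2+length
    del_start = s + 3
    del_end = del_start + length - 1
    anchor = del_start - 1
    ref = ref_slice(genome, gene.chrom, anchor, del_end)
    alt = ref[0]
    return Variant(gene.chrom, anchor, ref, alt, 0.0, 0)


def plant_causative(
    query_callset: StrainCallSet,
    gene: GeneModel,
    spec: CausativeSpec,
    genome: Mapping[str, str],
    panel_keys: set[VariantKey] | None = None,
) -> tuple[StrainCallSet, Variant]:
    """Insert the causative variant into the query strain's call set.

    Returns the modified call set and the planted (normalized) variant.  If
    the planted key collides with an existing panel key a ValueError is
    raised — the caller should regenerate with another gene or seed.
    """
    if spec.kind == "inframe_del_before_stop":
        if gene.cds_length < spec.length + 6:
            raise ValueError(f"gene {gene.gene_id} CDS too short to plant deletion")
        last_len = (
            gene.cds_intervals[-1][1] - gene.cds_intervals[-1][0] + 1
            if gene.strand == "+"
            else gene.cds_intervals[0][1] - gene.cds_intervals[0][0] + 1
        )
        if last_len < spec.length + 4:
            raise ValueError(f"gene {gene.gene_id}: terminal exon too short")
        v = _del_before_stop(gene, genome, spec.length)
    elif spec.kind == "frameshift":
        s, e = gene.cds_intervals[0]
        mid = (s + e) // 2
        ln = spec.length if spec.length % 3 != 0 else 1
        ref = ref_slice(genome, gene.chrom, mid, mid + ln)
        v = Variant(gene.chrom, mid, ref, ref[0], 0.0, 0)
    elif spec.kind == "missense":
        # mutate the second base of the second codon: ATG Nxx -> guaranteed
        # residue change is not certain for arbitrary codons, so scan codons
        # for a substitution that changes the residue
        v = _find_missense(gene, genome)
    else:
        raise ValueError(f"unknown causative kind {spec.kind!r}")
    v = normalize(replace(v, qual=spec.qual, depth=spec.depth), genome)
    if panel_keys and v.key in panel_keys:
        raise ValueError("planted variant collides with an existing panel key")
    v = replace(v, raw_record=_vcf_line(v))
    variants = [x for x in query_callset.variants if x.key != v.key] + [v]
    out = StrainCallSet(
        query_callset.strain_name,
        variants,
        list(query_callset.header_lines),
        query_callset.source_path,
    )
    out.sort()
    return out, v


def _find_missense(gene: GeneModel, genome: Mapping[str, str]) -> Variant:
    from .effects import EffectClass, annotate

    cds = gene.cds_sequence(genome)
    for codon_idx in range(1, len(cds) // 3 - 1):
        for offset in range(3):
            cds_pos = codon_idx * 3 + offset + 1  # 1-based CDS coordinate
            gpos = _cds_to_genomic(gene, cds_pos)
            ref_base = ref_slice(genome, gene.chrom, gpos, gpos)
            for alt_base in BASES:
                if alt_base == ref_base:
                    continue
                v = Variant(gene.chrom, gpos, ref_base, alt_base, 0.0, 0)
                recs = annotate(v, [gene], genome)
                if any(r.effect == EffectClass.MISSENSE for r in recs):
                    return v
    raise ValueError(f"no missense substitution found in {gene.gene_id}")


def _cds_to_genomic(gene: GeneModel, cds_pos: int) -> int:
    if gene.strand == "-":
        cds_pos = gene.cds_length - cds_pos + 1
    offset = 0
    for s, e in gene.cds_intervals:
        width = e - s + 1
        if cds_pos <= offset + width:
            return s + (cds_pos - offset - 1)
        offset += width
    raise ValueError(f"CDS position {cds_pos} outside {gene.gene_id}")


# ---------------------------------------------------------------------------
# Whole-world orchestration


@dataclass
class SimWorld:
    """Everything one synthetic run produces."""

    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    callsets: list[StrainCallSet]
    planted: Variant
    causative_gene: GeneModel
    tetrads: list[Tetrad]
    marker: MarkerDef


def _suitable_genes(models: Sequence[GeneModel], spec: CausativeSpec) -> list[GeneModel]:
    out = []
    for g in models:
        if spec.gene_id is not None and g.gene_id != spec.gene_id:
            continue
        term = (
            g.cds_intervals[-1] if g.strand == "+" else g.cds_intervals[0]
        )
        if term[1] - term[0] + 1 >= spec.length + 4 and g.cds_length >= spec.length + 6:
            out.append(g)
    return out


def simulate_world(config: SimConfig) -> SimWorld:
    """Genome + panel + planted causative variant + tetrads, fully seeded.

    The causative gene is the first suitable gene (or the configured one);
    if the planted key collides with an existing panel key the next suitable
    gene is tried, with a warning.
    """
    import warnings as _w

    genome, models = simulate_genome(config)
    callsets = simulate_panel(config, genome, models)
    by_name = {cs.strain_name: cs for cs in callsets}
    query = by_name[config.query_strain]
    panel_keys: set[VariantKey] = set()
    for cs in callsets:
        if cs.strain_name != config.query_strain:
            panel_keys |= cs.keys()
    last_err: Exception | None = None
    for gene in _suitable_genes(models, config.causative):
        try:
            new_query, planted = plant_causative(
                query, gene, config.causative, genome, panel_keys
            )
        except ValueError as err:
            _w.warn(f"replanting in another gene: {err}")
            last_err = err
            continue
        by_name[config.query_strain] = new_query
        ordered = [by_name[cs.strain_name] for cs in callsets]
        tetrads = simulate_tetrads(config)
        marker_pos = min(planted.pos + config.marker_offset, config.chrom_length - 1)
        marker = MarkerDef(config.marker_name, planted.chrom, marker_pos)
        return SimWorld(config, genome, models, ordered, planted, gene, tetrads, marker)
    raise ValueError(f"could not plant causative variant: {last_err}")


# ---------------------------------------------------------------------------
# Tetrads


def simulate_tetrads(
    config: SimConfig,
    mutant_allele: str = "parentA",
    wild_allele: str = "parentB",
) -> list[Tetrad]:
    """Tetrads under the single-crossover tetratype model.

    Every tetrad segregates the mutation 2:2.  With probability c
    (``crossover_prob``) the tetrad is a tetratype — exactly two spores (one
    mutant, one wild) carry the recombinant marker allele — otherwise it is a
    parental ditype.  Spore order within a tetrad is shuffled.  NPDs (double
    crossovers) are not modelled.
    """
    c = config.crossover_prob
    if not (0.0 <= c <= 0.5):
        raise ValueError(f"crossover probability must be in [0, 0.5], got {c}")
    rng = np.random.default_rng(config.seed + 2)
    marker = config.marker_name
    tetrads: list[Tetrad] = []
    for t in range(config.n_tetrads):
        tetratype = rng.random() < c
        if tetratype:
            spores = [
                (MUTANT, mutant_allele),
                (MUTANT, wild_allele),
                (WILD, mutant_allele),
                (WILD, wild_allele),
            ]
        else:
            spores = [
                (MUTANT, mutant_allele),
                (MUTANT, mutant_allele),
                (WILD, wild_allele),
                (WILD, wild_allele),
            ]
        order = rng.permutation(4)
        progeny = [
            Progeny(f"t{t + 1}.{i + 1}", spores[j][0], {marker: spores[j][1]})
            for i, j in enumerate(order)
        ]
        tetrads.append(Tetrad(f"t{t + 1}", progeny))
    return tetrads
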