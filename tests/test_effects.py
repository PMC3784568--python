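"""Gene-model extraction, translation, and coding-effect classification."""

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from strainsift.effects import (
    EffectClass,
    FrameError,
    GeneModel,
    annotate,
    apply_filters,
    load_gene_models,
    molecular_weight,
    revcomp,
    translate,
)
from strainsift.simulate import SimConfig, models_to_gff3, simulate_genome
from strainsift.variants import Variant

rng = np.random.default_rng(2024)


def _random_sense_codons(n):
    codons = [c for c in standard_dna_table.forward_table]
    return "".join(codons[i] for i in rng.integers(len(codons), size=n))


def make_gene(cds, flank=30, strand="+", gene_id="g1", chrom="chrT", rng=rng):
    """Embed a CDS (transcript orientation) in random flanks; returns
    (genome, model)."""
    left = "".join("ACGT"[i] for i in rng.integers(4, size=flank))
    right = "".join("ACGT"[i] for i in rng.integers(4, size=flank))
    embedded = cds if strand == "+" else revcomp(cds)
    genome = {chrom: left + embedded + right}
    model = GeneModel(gene_id, chrom, strand, [(flank + 1, flank + len(cds))])
    return genome, model


# ---------------------------------------------------------------------------
# Gene model loading


def test_plus_strand_single_exon_cds_equals_slice():
    cds = "ATG" + _random_sense_codons(20) + "TAA"
    genome, model = make_gene(cds)
    assert model.cds_sequence(genome) == cds


def test_minus_strand_two_exon_cds_is_revcomp_of_descending_slices():
    # manual construction: genomic plus strand holds revcomp(CDS) split by an
    # intron; extraction must reverse-complement the concatenated slices
    cds = "ATG" + _random_sense_codons(9) + "TGA"
    plus = revcomp(cds)
    exon1, exon2 = plus[:14], plus[14:]
    intron = "GTAAGCATTACAG"
    seq = "CCCCC" + exon1 + intron + exon2 + "GGGGG"
    genome = {"chrT": seq}
    model = GeneModel(
        "g1",
        "chrT",
        "-",
        [(6, 6 + len(exon1) - 1), (6 + len(exon1) + len(intron), 5 + len(plus) + len(intron))],
    )
    assert model.cds_sequence(genome) == cds
    manual = revcomp(
        seq[5 : 5 + len(exon1)] + seq[5 + len(exon1) + len(intron) : 5 + len(plus) + len(intron)]
    )
    assert manual == cds


def test_load_gene_models_round_trips_simulated_gff():
    cfg = SimConfig(seed=9, n_chromosomes=3, chrom_length=40_000, n_genes=6)
    genome, models = simulate_genome(cfg)
    loaded = load_gene_models(models_to_gff3(models), genome)
    assert {m.gene_id for m in loaded} == {m.gene_id for m in models}
    for orig in models:
        twin = next(m for m in loaded if m.gene_id == orig.gene_id)
        assert twin.cds_intervals == orig.cds_intervals
        assert twin.strand == orig.strand
        assert twin.cds_sequence(genome) == orig.cds_sequence(genome)
        assert not twin.warnings


def test_948_nt_cds_gives_316_codons():
    cds = "ATG" + _random_sense_codons(314) + "TGA"
    assert len(cds) == 948
    genome, model = make_gene(cds)
    assert model.cds_length == 948
    assert model.cds_length // 3 == 316


def test_cds_length_not_multiple_of_three_is_warned_not_fatal():
    model = GeneModel("g1", "chrT", "+", [(1, 10)])
    assert "cds_length_not_multiple_of_3" in model.warnings


# ---------------------------------------------------------------------------
# Translation and protein mass


def test_translate_minimal_orf():
    assert translate("ATGTAA") == "M"


def test_948_nt_cds_translates_to_315_residues():
    cds = "ATG" + _random_sense_codons(314) + "TGA"
    assert len(translate(cds)) == 315


def test_translate_matches_codon_lookup_oracle():
    cds = "ATG" + _random_sense_codons(29)
    expected = "".join(
        standard_dna_table.forward_table[cds[i : i + 3]] for i in range(0, len(cds), 3)
    )
    assert translate(cds) == expected


def test_translate_frame_and_internal_stop():
    with pytest.raises(FrameError):
        translate("ATGTA")
    with pytest.warns(UserWarning, match="internal stop"):
        assert translate("ATGTAAATGTAA") == "M"


@pytest.mark.parametrize(
    "protein, expected",
    [("", 18.02), ("G", 75.07), ("GG", 132.12)],
)
def test_molecular_weight_average_masses(protein, expected):
    assert molecular_weight(protein) == pytest.approx(expected, abs=0.01)


def test_molecular_weight_rejects_unknown_residue():
    with pytest.raises(ValueError, match="unknown residue"):
        molecular_weight("GXZ")


# ---------------------------------------------------------------------------
# Effect classification


def _one(records):
    assert len(records) == 1
    return records[0]


def test_missense_cgg_to_cag_is_r_to_q():
    # middle-position G->A in a CGG codon: R (cGg) -> Q (cAg)
    cds = "ATG" + "CGG" + _random_sense_codons(5) + "TAA"
    genome, model = make_gene(cds)
    g_pos = 30 + 5  # codon 2, middle base (flank 30)
    v = Variant("chrT", g_pos, "G", "A", 50, 40)
    rec = _one(annotate(v, [model], genome))
    assert rec.effect == EffectClass.MISSENSE
    assert (rec.ref_residues, rec.alt_residues) == ("R", "Q")
    assert rec.protein_position == 2


def test_synonymous_third_position_cgg_to_cga():
    cds = "ATG" + "CGG" + _random_sense_codons(5) + "TAA"
    genome, model = make_gene(cds)
    v = Variant("chrT", 30 + 6, "G", "A", 50, 40)  # CGG -> CGA, both R
    rec = _one(annotate(v, [model], genome))
    assert rec.effect == EffectClass.SYNONYMOUS


def test_yfl_terminal_deletion_is_inframe_removing_three():
    # CDS ends ...TAC TTC CTG TGA; the 9 bases before the stop encode Y,F,L
    cds = "ATG" + _random_sense_codons(10) + "TACTTCCTGTGA"
    genome, model = make_gene(cds)
    stop_end = model.cds_intervals[0][1]
    del_end = stop_end - 3
    anchor = del_end - 9
    ref = genome["chrT"][anchor - 1 : del_end]
    v = Variant("chrT", anchor, ref, ref[0], 214, 122)
    rec = _one(annotate(v, [model], genome))
    assert rec.effect == EffectClass.INFRAME_DELETION
    assert rec.residues_removed == 3
    assert rec.ref_residues == "YFL"
    assert rec.alt_residues == ""


def test_single_base_deletion_is_frameshift():
    cds = "ATG" + _random_sense_codons(10) + "TAA"
    genome, model = make_gene(cds)
    pos = 30 + 7
    ref = genome["chrT"][pos - 1 : pos + 1]
    v = Variant("chrT", pos, ref, ref[0], 50, 40)
    rec = _one(annotate(v, [model], genome))
    assert rec.effect == EffectClass.FRAMESHIFT


def test_nonsense_and_stop_loss():
    cds = "ATG" + "TAT" + _random_sense_codons(5) + "TGA"
    genome, model = make_gene(cds)
    # TAT -> TAA: premature stop
    v = Variant("chrT", 30 + 6, "T", "A", 50, 40)
    assert _one(annotate(v, [model], genome)).effect == EffectClass.NONSENSE
    # terminal TGA -> CGA: stop lost
    stop_start = model.cds_intervals[0][1] - 2
    v2 = Variant("chrT", stop_start, "T", "C", 50, 40)
    assert _one(annotate(v2, [model], genome)).effect == EffectClass.STOP_LOSS


def test_intron_splice_window_and_noncoding():
    cds = "ATG" + _random_sense_codons(19) + "TAA"
    plus = cds
    exon1, exon2 = plus[:30], plus[30:]
    intron = "GT" + "C" * 40 + "AG"
    seq = "A" * 20 + exon1 + intron + exon2 + "T" * 20
    genome = {"chrT": seq}
    model = GeneModel(
        "g1", "chrT", "+",
        [(21, 50), (51 + len(intron), 50 + len(intron) + len(exon2))],
    )
    donor1 = Variant("chrT", 51, "G", "A", 50, 40)  # first intron base
    rec = _one(annotate(donor1, [model], genome))
    assert rec.effect == EffectClass.SPLICE_BOUNDARY
    deep = Variant("chrT", 70, "C", "T", 50, 40)  # mid-intron
    assert _one(annotate(deep, [model], genome)).effect == EffectClass.NONCODING
    outside = Variant("chrT", 5, "A", "G", 50, 40)
    assert _one(annotate(outside, [model], genome)).effect == EffectClass.NONCODING


def test_minus_strand_annotation_mirrors_plus_strand():
    cds = "ATG" + "CGG" + _random_sense_codons(8) + "TAA"
    genome_p, model_p = make_gene(cds, strand="+")
    genome_m, model_m = make_gene(cds, strand="-")
    # same transcript edit: middle base of codon 2, G->A (R->Q)
    vp = Variant("chrT", 30 + 5, "G", "A", 50, 40)
    # on the minus strand the transcript base G sits at genomic coordinate
    # counted from the CDS end, and carries the complementary allele
    end = model_m.cds_intervals[0][1]
    gpos = end - (5 - 1)
    vm = Variant("chrT", gpos, "C", "T", 50, 40)
    rp = _one(annotate(vp, [model_p], genome_p))
    rm = _one(annotate(vm, [model_m], genome_m))
    assert rp.effect == rm.effect == EffectClass.MISSENSE
    assert (rp.ref_residues, rp.alt_residues) == (rm.ref_residues, rm.alt_residues)
    assert rp.protein_position == rm.protein_position == 2


def test_synonymous_iff_translation_unchanged_random_pairs():
    """Classifier agrees with the translate-and-diff definition on random
    CDS/SNP pairs."""
    local = np.random.default_rng(77)
    n_syn = 0
    for _ in range(100):
        n = int(local.integers(5, 40))
        cds = "ATG" + _random_sense_codons(n) + "TAA"
        genome, model = make_gene(cds)
        cds_pos = int(local.integers(1, len(cds) + 1))
        gpos = 30 + cds_pos
        ref = genome["chrT"][gpos - 1]
        alt = "ACGT"[local.integers(4)]
        if alt == ref:
            continue
        v = Variant("chrT", gpos, ref, alt, 50, 40)
        rec = _one(annotate(v, [model], genome))
        mutated = cds[: cds_pos - 1] + alt + cds[cds_pos:]
        # oracle: full translations (stop included) identical
        same_protein = str(Seq(cds).translate()) == str(Seq(mutated).translate())
        if rec.effect == EffectClass.SYNONYMOUS:
            n_syn += 1
        assert (rec.effect == EffectClass.SYNONYMOUS) == same_protein, (cds, v)
    assert n_syn > 0  # the sample actually exercised both branches


def test_frameshift_iff_length_difference_not_multiple_of_three():
    local = np.random.default_rng(88)
    for _ in range(40):
        cds = "ATG" + _random_sense_codons(int(local.integers(15, 40))) + "TAA"
        genome, model = make_gene(cds)
        ln = int(local.integers(1, 7))
        lo = 30 + 2
        hi = model.cds_intervals[0][1] - ln - 4
        pos = int(local.integers(lo, hi))
        ref = genome["chrT"][pos - 1 : pos + ln]
        v = Variant("chrT", pos, ref, ref[0], 50, 40)
        rec = _one(annotate(v, [model], genome))
        if ln % 3 == 0:
            assert rec.effect == EffectClass.INFRAME_DELETION
            # translate-and-diff oracle: residue counts follow the mutated
            # protein (a junction that creates a new stop removes the tail)
            mutated = genome["chrT"][: pos] + genome["chrT"][pos + ln :]
            mut_model = type(model)(
                "g1", "chrT", "+",
                [(model.cds_intervals[0][0], model.cds_intervals[0][1] - ln)],
            )
            alt_prot = translate(mut_model.cds_sequence({"chrT": mutated}))
            ref_prot = translate(cds)
            assert rec.residues_removed - rec.residues_added == len(ref_prot) - len(alt_prot)
        else:
            assert rec.effect == EffectClass.FRAMESHIFT


# ---------------------------------------------------------------------------
# Filter ledger


def _eff(key_pos, effect):
    from strainsift.effects import EffectRecord
    from strainsift.variants import VariantKey

    return EffectRecord(VariantKey("c1", key_pos, "A", "G"), "g1", effect)


def test_apply_filters_default_cascade():
    records = (
        [_eff(i, EffectClass.NONCODING) for i in range(100, 140)]
        + [_eff(i, EffectClass.MISSENSE) for i in range(10)]
        + [_eff(i, EffectClass.SYNONYMOUS) for i in range(50, 55)]
    )
    kept, ledger = apply_filters(records)
    assert ledger.stages == [
        ("coding_or_splice", 55, 40, 15),
        ("non_synonymous", 15, 5, 10),
    ]
    assert len({r.variant_key for r in kept}) == 10


def test_apply_filters_no_synonymous_keeps_everything():
    records = [_eff(i, EffectClass.MISSENSE) for i in range(7)]
    kept, ledger = apply_filters(records)
    assert len(kept) == 7
    assert ledger.stages[-1][2] == 0  # nothing removed


def test_ledger_counts_match_brute_force_tally(small_world):
    from strainsift.effects import annotate as ann

    world = small_world
    records = []
    for v in world.callsets[0].variants[:300]:
        records.extend(ann(v, world.models, world.genome))
    kept, ledger = apply_filters(records)
    keys = {r.variant_key for r in records}
    coding_keys = {
        r.variant_key for r in records if r.effect != EffectClass.NONCODING
    }
    nonsyn_keys = {
        r.variant_key
        for r in records
        if r.effect not in (EffectClass.NONCODING, EffectClass.SYNONYMOUS)
    }
    assert ledger.stages[0][1] == len(keys)
    assert ledger.stages[0][3] == len(coding_keys)
    assert ledger.stages[1][3] == len(nonsyn_keys & coding_keys)
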