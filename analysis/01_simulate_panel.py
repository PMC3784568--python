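#!/usr/bin/env python
"""Simulate the synthetic strain panel every later step analyses.

Generates a 17-chromosome genome with gene models, a 16-strain panel sharing
block-structured ancestral polymorphism, a query strain carrying a planted
causative in-frame deletion (9 nt immediately before a stop codon), a linked
dCAPS marker, and 30 tetrads.  Raw FASTA/GFF3/VCF/tetrad files go to
scratch/simdata/ (large, regenerable); a small provenance table goes to
results/.
"""

from pathlib import Path

from strainsift.mapping import write_tetrad_table
from strainsift.simulate import SimConfig, genome_to_fasta, models_to_gff3, simulate_world
from strainsift.variants import write_vcf

SEED = 20130905  # fixed for the whole analysis chain

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    world = simulate_world(cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    (SCRATCH / "genome.fasta").write_text(genome_to_fasta(world.genome))
    (SCRATCH / "genes.gff3").write_text(models_to_gff3(world.models))
    for cs in world.callsets:
        (SCRATCH / f"{cs.strain_name}.vcf").write_text(write_vcf(cs))
    (SCRATCH / "tetrads.tsv").write_text(
        write_tetrad_table(world.tetrads, [cfg.marker_name])
    )
    (SCRATCH / "markers.tsv").write_text(
        "name\tchrom\tpos\tsite\tcut_allele\n"
        f"{world.marker.name}\t{world.marker.chrom}\t{world.marker.pos}\t\t\n"
    )

    v = world.planted
    lines = [
        "key\tvalue",
        f"seed\t{SEED}",
        f"strains\t{len(world.callsets)}",
        f"chromosomes\t{cfg.n_chromosomes} x {cfg.chrom_length} bp",
        f"genes\t{len(world.models)}",
        f"query_strain\t{cfg.query_strain}",
        f"planted_variant\t{v.chrom}:{v.pos} {v.ref}>{v.alt}",
        f"planted_gene\t{world.causative_gene.gene_id} ({world.causative_gene.strand})",
        f"marker\t{world.marker.name} at {world.marker.chrom}:{world.marker.pos}",
        f"tetrads\t{cfg.n_tetrads} (crossover probability {cfg.crossover_prob})",
    ]
    (RESULTS / "01_panel_provenance.tsv").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))
    print(f"\nwrote raw panel files to {SCRATCH}")


if __name__ == "__main__":
    main()
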