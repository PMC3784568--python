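#!/usr/bin/env python
"""Chromosome distributions and 100-kb-style window profiles.

For the synthetic query strain: per-chromosome counts/percentages (with the
unplaced-scaffold bucket) and fixed-width window counts along each
chromosome, the desk-scale analogue of the published distribution table and
density figure.  Windows are 10 kb here because synthetic chromosomes are
120 kb; the window operation itself defaults to 100 kb.  Also re-checks the
published concentration: the CC-124 column summed over chromosomes
3/6/12/16/17 rounds to 90%.
"""

from pathlib import Path

from strainsift.library import chromosome_distribution, window_profile
from strainsift.published import CONCENTRATED_CHROMOSOMES
from strainsift.published import chromosome_distribution as published_dist
from strainsift.simulate import SimConfig, simulate_world

SEED = 20130905
WINDOW = 10_000
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    world = simulate_world(cfg)
    query = next(
        cs for cs in world.callsets if cs.strain_name == cfg.query_strain
    )
    RESULTS.mkdir(exist_ok=True)

    dist = chromosome_distribution(query, cfg.chrom_names())
    dist["percent"] = dist["percent"].round(2)
    dist.to_csv(RESULTS / "03_query_chromosome_distribution.tsv", sep="\t", index=False)
    top5 = dist.nlargest(5, "count")
    share = top5["percent"].sum()
    print(dist.to_string(index=False))
    print(
        f"\n{cfg.query_strain}: {share:.1f}% of changes sit on 5 of "
        f"{cfg.n_chromosomes} chromosomes ({', '.join(top5['sequence'])})"
    )

    profiles = window_profile(query, WINDOW, chrom_lengths=cfg.chrom_lengths())
    rows = ["chrom\twindow_start\twindow_end\tcount"]
    for chrom, counts in profiles.items():
        for k, n in enumerate(counts):
            rows.append(f"{chrom}\t{k * WINDOW + 1}\t{(k + 1) * WINDOW}\t{n}")
    (RESULTS / "03_query_window_counts.tsv").write_text("\n".join(rows) + "\n")
    busiest = max(
        ((c, int(p.argmax()), int(p.max())) for c, p in profiles.items()),
        key=lambda t: t[2],
    )
    print(
        f"busiest {WINDOW // 1000}-kb window: {busiest[0]}:"
        f"{busiest[1] * WINDOW + 1}-{(busiest[1] + 1) * WINDOW} with {busiest[2]} changes"
    )

    pub = published_dist().set_index("chromosome")
    pub_share = pub.loc[CONCENTRATED_CHROMOSOMES, "CC-124"].sum()
    print(
        f"published CC-124 column: chromosomes {'+'.join(CONCENTRATED_CHROMOSOMES)} "
        f"carry {pub_share:.2f}% of changes (rounds to {round(pub_share)}%)"
    )


if __name__ == "__main__":
    main()
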