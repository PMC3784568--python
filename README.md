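# strainsift

Forward genetics by whole-genome sequencing produces tens of thousands of
SNPs and small indels per strain, of which exactly one is the mutation you
care about. `strainsift` implements the comparative triage that finds it:
build a multi-strain SNP/indel library, subtract every change shared with
other strains, keep coding changes, intersect with the meiotic mapping
interval, and rank what is left by read support and cross-strain occurrence.
It is written for people mapping chemically or UV-induced mutants in haploid
organisms with tractable tetrad genetics (the motivating organism is
*Chlamydomonas reinhardtii*), and it ships a synthetic strain-panel
generator so the whole pipeline is testable without any sequencing data.

## The method

**Library and subtraction.** Each strain's calls are normalized
(left-aligned, anchor-base indels) and keyed by `(chrom, pos, ref, alt)`;
evidence fields (QUAL, DP, GT) never enter the identity. The library maps
each key to the set of strains carrying it, so the library "Total" is union
semantics — each distinct change counted once. That gives the exclusion
identity the summary tables rely on:

```
union(all strains) − union(all except s) = |changes private to s|
```

Subtraction returns the query's original VCF records minus the shared keys
— output preserves the input records byte-for-byte.

**Effect annotation.** A variant is coding iff its changed bases intersect a
CDS interval or the 2-bp intronic splice window. Substitutions are
classified by translating the reference and mutated CDS and diffing
(synonymous / missense / nonsense / stop-loss); indels are frameshift when
`|len(ref) − len(alt)| mod 3 ≠ 0`, otherwise in-frame with residue changes
taken from the whole-CDS translate-and-diff, which stays correct when the
edit spans codon boundaries. Upstream/downstream/intergenic/deep-intron/UTR
changes are dropped; heterozygous calls are skipped (haploid vegetative
cells) and counted.

**Meiotic mapping.** Tetrads are scored for 2:2 segregation of the
phenotype; pooled progeny are classified parental/recombinant against a
dCAPS marker, and the two-point distance is the recombinant fraction,
`100·R/(P+R)` cM (a Haldane-corrected value is reported alongside). The
closest linked marker defines the genomic interval candidates must fall in.

**Triage.** Candidates outside the interval are excluded; candidates seen in
external strains, or with depth/quality below thresholds (defaults 10 reads,
Phred 30), are demoted — never silently removed — and the ranked ledger
records every stage's input/removed/retained counts.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic panel (17 chromosomes × 120 kb, 16 strains, one planted causative
9-nt in-frame deletion immediately before a stop codon):

```
python analysis/01_simulate_panel.py
python analysis/02_library_summary.py
...
python analysis/06_prioritize.py
```

The final step prints:

```
status: ok
stage   input   removed retained
unique  1892    1762    130
coding_or_splice        130     129     1
non_synonymous  1       0       1
in_interval     1       0       1
after_cross_check       1       0       1
# ranked candidates: 1

rank  chrom  pos   ref         alt  gene  effect            residue_change  depth  qual  flags  cross_check_hits
1     chr1   2002  AATCGGTCGT  A    g001  inframe_deletion  TTD>            122    214   .      .

rank-1 candidate matches the planted mutation at chr1:2002
```

Reading it: of the query strain's 1,892 changes, 130 are private (shared by
no other strain), one of those is coding and non-synonymous, it lies inside
the tetrad-derived mapping interval, no external strain carries it, and its
evidence (122 reads, Phred 214) raises no flag — it is the planted
causative deletion, an in-frame removal of three residues.

The same operations are available as a CLI — `strainsift simulate`,
`subtract`, `summary`, `distribution`, `windows`, `annotate`, `map`,
`prioritize`; run `strainsift --help`. The library is built in memory from
the VCFs each subcommand receives; there is no on-disk library format.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch and fully seeded, the
package's desk-scale reference quantities: the residue count removed by a
9-nt deletion placed immediately before the stop codon of a synthetic CDS
ending Tyr-Phe-Leu-stop; the number of 30 simulated tetrads passing the 2:2
segregation test; and the pooled-progeny map distance from 2,500 simulated
tetrads at crossover probability 0.06. Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/strainsift/` — the library: `variants` (VCF subset I/O,
  normalization, keys), `library` (union/subtraction/summaries/windows),
  `effects` (gene models, translation, effect classes, filter ledger),
  `mapping` (tetrads, dCAPS, map distance, intervals), `prioritize`
  (cross-check, flags, the full cascade), `simulate` (synthetic worlds),
  `published` (shipped summary tables of the original 16-strain panel).
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — unit, property, and acceptance suites.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
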