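# Methods

## Variant identity and normalization

Coordinates are 1-based, fully closed, VCF-style; indels carry one anchoring
reference base. Identity for every set operation is the normalized
`(chrom, pos, ref, alt)` tuple. Normalization repeatedly (i) drops a shared
terminal base, re-extending both alleles leftward from the reference when
one would become empty, and (ii) strips shared leading bases while both
alleles are longer than 1. The result is the minimal-length representation
at the smallest equivalent position (left alignment); the operation is
idempotent and preserves the alternate haplotype. At the chromosome start,
where no left anchor exists, the last trim is undone and the
right-anchored form is kept — the only position where two spellings of one
edit cannot be unified, and one that never arises in practice.

Multi-allelic records are split into one variant per ALT before keying, so
subtraction is well defined per allelic change. QUAL/DP/GT are evidence,
not identity: two strains "share" a change whenever the normalized alleles
match, regardless of call quality. Records missing INFO/DP parse with depth
0 and an `depth_known=False` flag rather than failing, because historical
VCFs are heterogeneous; such calls will be flagged LOW_DEPTH at triage,
which is the conservative direction.

Original record lines are kept verbatim on every parsed variant, and
subtraction output is written as those original lines minus the shared
ones. This is a contract, not an implementation detail: downstream tools
must see the caller's own records.

## Library arithmetic

The library maps keys to strain sets. "Total" is the union of distinct
keys; excluding a strain from the union removes exactly that strain's
private keys, giving `union(∅) − union({s}) = unique(s)`. Unique
percentages are reported both at one decimal and floored to an integer (the
display convention of the source tables). Chromosome distributions place
every sequence not on the supplied roster into a single
"unplaced scaffolds" bucket so percentages always total 100; window
profiles bin positions into `[kW+1, (k+1)W]` windows (default W = 100 kb),
keeping zero-count windows.

## Effect annotation

A variant is coding iff its *changed* bases intersect a CDS interval: for
anchored deletions that span is `pos+1 … pos+len(ref)−1`; for insertions it
is the insertion point strictly inside an exon; the anchor base itself is
inert. Classification:

- substitutions: translate reference and mutated CDS, diff; identical full
  translations ⇒ synonymous; new earlier stop ⇒ nonsense; lost terminal
  stop ⇒ stop-loss; otherwise missense with the residue change and 1-based
  protein position.
- indels: length difference not divisible by 3 ⇒ frameshift; otherwise
  in-frame deletion/insertion with removed/added residues from a whole-CDS
  translate-and-diff. This handles edits spanning codon boundaries (the
  canonical example: a 9-nt deletion immediately before the stop removes
  exactly the last three residues). When the new exon junction happens to
  create a premature stop, the diff reports the full truncated tail — the
  translated consequence, not the nominal `Δ/3`.
- a variant whose changed bases cross a CDS/intron edge, or fall within the
  2-bp intronic window flanking an internal CDS boundary, is
  `splice_boundary`. The 2-bp window is the canonical donor/acceptor choice;
  the source analysis said only "exon/intron boundaries".
- everything else is `noncoding` and is dropped by the first filter stage,
  mirroring an annotator run with upstream/downstream/intergenic/intron/UTR
  calls disabled.

Only homozygous-alt calls enter annotation (vegetative cells are haploid);
het calls are counted and skipped. A variant overlapping several
transcripts yields one record per transcript, but the filter ledger counts
distinct variants, so multi-isoform genes do not inflate stage counts.
Translation uses the standard nuclear codon table (organelle genomes are out
of scope) via Biopython; protein mass is the average-isotope residue sum
plus one water.

## Meiotic mapping

`segregation_test` passes a tetrad iff exactly 2 of 4 progeny are mutant;
tetrads with missing phenotypes are excluded with a warning count, not
failed. dCAPS genotyping calls the cut allele when the recognition site
occurs on either strand of the amplicon. The two-point estimator is the
pooled-progeny recombinant fraction, `100·R/(P+R)` cM, with a Haldane value
(`−50·ln(1−2r)`) reported alongside; at the short distances this package is
used for the two coincide, which is why no mapping function is applied by
default. Missing marker calls are uninformative, never recombinant. The
mapping interval is centred on the closest marker at or below `max_cm`,
with half-width `distance/cm_per_mb` and a 0.1 Mb floor so a 0-cM marker
still yields a usable region. `cm_per_mb` is a required user choice
(default 1 cM/Mb, prominently not a species constant); on desk-scale
synthetic chromosomes the 0.1 Mb floor spans the whole chromosome, i.e. the
interval stage acts as chromosome-level localization there.

## Triage

Stage order follows the narrative the package reproduces: total → unique →
coding/splice → non-synonymous → in-interval → cross-check. A config switch
applies the interval before annotation instead; the surviving set is
identical (tested), only intermediate counts differ. Cross-check hits
(external strains carrying the same key) and evidence flags
(depth < 10 reads, Phred < 30 by default, strict inequality) demote
candidates instead of deleting them, because a weakly supported candidate
is still a candidate until contradicted; hard filtering is available behind
an explicit option. Ranking: unflagged first, then no cross-check hits,
then higher depth, higher quality, and (chrom, pos) as the final
deterministic tie-break. Identical inputs and seeds give byte-identical
ledgers.

## The synthetic world

The generator emulates the structure the analysis assumes, not sequencing
physics:

- **Genome/genes**: uniform-composition chromosomes (default 17 × 120 kb);
  single- or two-exon genes with valid CDSs (ATG, terminal stop, no
  internal stop), two-exon genes getting a GT…AG intron. Defaults: 30
  genes, 100–320 codons, strands equiprobable.
- **Panel**: an ancestral pool of 6,000 variants (90% SNP, 10% indels ≤6
  bp) placed uniformly; each of 16 strains carries a pool variant iff it
  falls in one of the strain's blocks (five chromosomes, 90% span each) or
  with a 2.5% background probability, plus 120 private variants. The block
  model concentrates ≈90% of each strain's changes on five chromosomes —
  the empirically observed structure of the real panel — with the 2.5%
  background chosen analytically (before any test was run) to put the
  expected concentration at 90%. This is deliberately an assignment model,
  not a coalescent: it reproduces the union/subtraction arithmetic and the
  concentrated distributions, and nothing downstream depends on genealogy.
- **Evidence**: QUAL ~ U(30, 250), DP ~ U(20, 160), independent, all calls
  homozygous — the source analysis provides no error model, and coverage
  in the real panel spans 26–162×. The planted causative variant carries
  the reference evidence pair (122 reads, Phred 214).
- **Causative mutation**: by default an anchored 9-nt deletion of the
  coding bases immediately 5′ of the stop codon (strand-aware), planted
  into the query strain's call set in the first gene whose terminal exon
  can hold it; missense and frameshift variants are available. A planted
  key colliding with a panel key triggers replanting in the next gene with
  a warning.
- **Tetrads**: per meiosis the tetrad is a tetratype with probability c
  (exactly two recombinant spores, one per phenotype) else a parental
  ditype; no chromatid interference, no NPDs, no gene conversion — the
  simplest model consistent with the reported counts, so every simulated
  tetrad segregates 2:2 by construction and `E[R/N] = c/2`. A linked
  marker is placed 5 kb from the planted mutation.

What a green synthetic test does **not** establish: robustness to
alignment/caller artifacts, non-uniform coverage, repeat-induced false
calls, assembly misjoins (the real analysis had to reconcile two assembly
versions by hand), or gene-model error. The generator's worlds are clean by
design; the tests establish the *logic* of the pipeline, not the quality of
any upstream caller.

## Numerical and degenerate-input choices

- Phred/QUAL `.` parses as 0 (maximally distrusted, flag-demoted later).
- `map_distance` with no informative progeny raises rather than returning
  NaN; `mapping_interval` with no linked marker raises.
- CDS lengths not divisible by 3, or missing terminal stops, set warning
  flags on the gene model instead of failing, and translation pads to the
  frame boundary; internal stops truncate with a warning.
- Percentages are exact fractions internally; 2-decimal rounding happens
  only at table-writing time.
- All simulation randomness flows from one integer seed through
  `numpy.random.default_rng`; sub-generators use fixed offsets (seed,
  seed+1, seed+2) so genome, panel, and tetrads can be regenerated
  independently.

## Known limitations

- No liftover between assembly versions; subtraction only compares calls
  against the same reference (the chromosome-2/9 discordance in the
  motivating study is left to the user's interval choice).
- BCF, genotype likelihoods (PL/GL), structural and symbolic alleles are
  out of scope; `<*>`-style ALTs are ignored at parse time.
- Effect annotation assumes gene models are correct and does not score
  conservation or codon usage.
- The dCAPS caller models digestion as exact recognition-site matching;
  partial digestion and star activity are wet-lab concerns outside this
  package.
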