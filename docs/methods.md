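# Methods

`egt` implements the computational workflow used to characterize plant
organellar genomes and the traffic of DNA among the three genome-bearing
compartments of the plant cell: assembly of a circular mitogenome from
short paired-end reads by iterative baiting, quantification of exact
duplicated regions, structural comparison of mitogenomes through syntenic
blocks, and detection of endosymbiotic transfers — mitochondrial plastid
DNA (MTPT), and nuclear copies of mitochondrial and plastid DNA (NUMT,
NUPT). A synthetic-data generator emulates the statistical structure of a
tomato-like genome trio and logs ground truth, so every stage can be
scored against known events.

## The synthetic genome trio

The generator draws i.i.d. background sequence at a configurable GC
(default 45%, the GC content typical of solanaceous mitogenomes) and
implants structure into it:

* **Plastome** — a circular quadripartite molecule LSC–IRa–SSC–IRb with
  IRb the exact reverse complement of IRa. Defaults: 155 kb total, 25 kb
  IRs, 18 kb SSC, matching published tomato plastomes.
* **Mitogenome** — a circular molecule (default 430 kb) carrying (a) exact
  repeat families, direct and inverted, 0.1–20 kb (the published tomato
  mitogenomes carry 42–76 kb of duplication), and (b) MTPT implants copied
  verbatim from stated plastome compartments. The default MTPT footprint is
  the published one: 2,558 bp of LSC, 32 bp of SSC and 7,008 bp of IR,
  9,598 bp in all.
* **Nuclear chromosomes** — linear molecules carrying organellar implants
  in two regimes: scattered small fragments (0.1–0.4 kb) and tightly
  clustered multi-kb fragments, the spectrum seen in real tomato
  chromosomes. Implants are *inserted* (not overwritten), so total
  chromosome growth equals total implanted bp. Each implant is degraded by
  its "age": substitutions at the stated divergence (uniform over the three
  alternative bases) and indels at divergence/10 per base with
  Geometric(0.5) lengths capped at 10 bp. Default chromosomes are a few
  hundred kb — three orders smaller than real chromosomes, but carrying the
  implant spectrum the callers must resolve; background that carries no
  homology only adds runtime, not difficulty, for a seed-and-extend caller
  whose null hit rate is controlled by the E-value (verified by the null
  specificity tests).
* **Reads** — paired-end, uniform starts honoring circularity, insert
  sizes Normal(400, 60), 100 bp reads at 200× default depth, constant Q40
  qualities, configurable per-base substitution error (default 0,
  representing a post-trimming idealization). Per-genome mixture weights
  let plastome reads over-represent plastome-identical mitogenome regions,
  reproducing the high-depth peaks over MTPTs seen in real organelle read
  pools.

Two generator details matter for exactness. First, every implant receives
two **guard bases** on each flank, forced to differ from the
source-adjacent bases; implant boundaries are therefore sharp, and an
aligner's X-drop extension recovers divergence-0 implants at exact base
resolution instead of chance-extending a few bp into the flank. Second,
clustered implants are separated by 150–500 bp background spacers and
scattered implants by at least 1 kb, so one implanted event maps to exactly
one call. Both choices define what "exact recovery" means for the tests:
real NUMT boundaries are not sharp, and the package's boundary accuracy on
real data is bounded by alignment extension behavior, not by these tests.

All stochastic stages derive their streams from a single seed
(per-stage offsets), and identical configurations produce byte-identical
FASTA/FASTQ outputs.

## Bait-and-iterate assembly

"Mapping" is operationalized throughout as exact k-mer anchoring plus
ungapped exact comparison — the reproducible reading of a zero-mismatch,
zero-gap assembler.

1. **Baiting** (k = 31): a read pair is kept iff either mate shares one
   exact 31-mer (either strand) with any bait sequence.
2. **Contigs** (k = 63): maximal unbranched paths of the de Bruijn graph
   over both strands of the baited reads; per-base support is the count of
   the covering k-mer.
3. **Iterative extension**: each contig end recruits reads whose prefix
   exactly matches the contig suffix by ≥ 50 bp and extends by per-column
   consensus of the overhangs. Extension **halts** at any column where a
   second allele has real support (≥ 2 reads and ≥ 25% of the column, or a
   tie) — repeat-boundary and plastome-boundary ambiguity is surfaced, not
   guessed. This branch-aware halt is deliberately stricter than a bare
   majority vote: at a genuine fork both alleles carry many reads, and a
   majority rule would follow stochastic coverage noise into a chimera.
   After extension, contained contigs are removed and the contig pair with
   the longest exact end overlap (≥ 50 bp, any orientation) is merged;
   iteration stops when nothing grows, when a lone contig closes on
   itself, or at the iteration cap. The longest contig length never
   decreases across iterations.
4. **Circularization**: if the contig's two ends share an exact overlap
   ≥ 50 bp, one copy is trimmed and the genome is emitted circular at its
   canonical rotation (lexicographically minimal rotation of the smaller of
   sequence and reverse complement). Multiple closure overlaps not
   explained by the periodicity of the longest one raise an ambiguity
   error. Over-extension past the origin is harmless: the terminal overlap
   absorbs it.
5. **Coverage QC**: reads are placed wherever they match exactly (a read
   matching n loci contributes 1/n depth to each, so exact repeats keep
   true copy depth). Intervals below 200× are flagged `low`; intervals at
   ≥ 5× the median are flagged `plastome_like_high_depth` — the MTPT
   signature. Flags narrower than 25 bp are suppressed as threshold-crossing
   noise (depth at 250× is Poisson with σ ≈ 16, so isolated single-base
   dips below 200 are expected on any genome).

A two-copy direct repeat longer than the insert size is resolvable on a
circle: extension walks each unique segment through both repeat copies and
halts at the exits, producing contigs R·A·R and R·B·R whose merge and
closure yield the unique Eulerian circuit A·R·B·R. An equal-depth mixture
of plastome reads, by contrast, makes long-MTPT boundaries genuinely
ambiguous (the two genomes are locally identical over the implant and a
400 bp insert cannot span 7 kb), so the pipeline assembles from the
organelle-enriched read set and uses the mixed pool only for coverage QC.

## Local alignment and E-values

All comparisons run on a blastn-style engine: exact word seeds (word size
11 for transfer calling), ungapped X-drop extension (X = 20) along seed
diagonals, greedy collinear chaining of nearby segments (gap ≤ 100 bp,
diagonal shift ≤ 50), and gapped refinement of multi-segment chains by an
affine local alignment over the chain's bounding box. Scores are +1/−2
with gap open −5 and extend −2 (a gap of length L costs open + L·extend);
identity counts matches over alignment columns, gaps included. E-values
use E = K·m·n·e^(−λS) with the standard ungapped constants for this
scheme, K = 0.46 and λ = 1.28; at an organelle-versus-nuclear-genome
search space these put the shortest significant exact hit near 36 bp,
which is exactly the minimum NUMT length reported for real tomato
chromosomes at E ≤ 10⁻⁵. Hits are filtered to E ≤ 10⁻⁵ (10⁻¹⁰ for
structural mitogenome comparison), truncated to 50,000 by descending
score, and ordered deterministically. The engine is validated against a
full quadratic Smith–Waterman oracle: the best HSP reaches ≥ 95% of the
global local optimum whenever that optimum is ≥ 50.

## Repeats

Duplicated regions are maximal exactly-repeated pairs ≥ 100 bp with zero
mismatches, both orientations. Detection anchors on shared 100-mers (any
qualifying repeat contains one at its left edge) and extends each anchored
pair to maximality; a per-diagonal coverage marker makes the cost linear
in total repeat length, and circular genomes are searched on the doubled
sequence with pairs deduplicated modulo the length and split at the
origin. N matches nothing, itself included. The "length of duplicated
regions" is the **union** of all repeat-member intervals — each genomic
position counted once — because any per-pair sum double-counts overlapping
repeat families; the per-pair lengths are also reported so the alternative
convention can be read off. An all-diagonals numpy scan serves as the
independent test oracle.

## Transfers

Transfer classes follow from the role pair: plastome→mitogenome hits are
MTPTs, mitogenome→nucleus NUMTs, plastome→nucleus NUPTs. No direction is
inferred for mitochondrial/nuclear sharing — noncoding mitochondrial
sequence gives no directional signal, so every shared segment is counted
as a NUMT. Post-processing:

* **Repeat dedup** — calls whose targets overlap reciprocally ≥ 50% and
  whose sources lie (≥ 80% contained) in different members of the same
  organellar repeat family collapse to the single best-scoring call,
  marked `deduped`. Idempotent. The 50%/80% thresholds are configuration;
  the containment rule links a call to a family only when the repeat
  actually explains the duplicate hit.
* **Compartment attribution** — plastome-side coverage is intersected with
  LSC/SSC/IR; IRb hits are reflected onto IRa before the per-compartment
  union is taken, so the same segment hitting both IR copies counts once.
* **Summaries** — per chromosome: count, mean/median/max/min call length,
  the same restricted to calls ≥ 250 bp, cumulative union bp and percent
  of the chromosome, plus a genome rollup. One retained HSP counts as one
  transfer.
* **Clusters** — single-linkage chaining of calls ≥ 1 kb along each
  chromosome with inter-call gaps ≤ 100 kb; clusters of ≥ 2 members are
  reported by total bp.
* **Dot-matrix reports** — per nuclear region, every fragment ≥ 1 kb with
  organelle interval, orientation and identity, plus a mosaic flag (true
  iff fragments derive from organellar loci > 10 kb apart or mixed
  orientations), the signature of a cluster stitched from independent
  events.

## Synteny and annotation utilities

Syntenic blocks chain same-orientation HSPs (E ≤ 10⁻¹⁰) collinearly with
inter-hit gaps ≤ 500 bp, then keep blocks > 1 kb containing at least one
annotated gene. Blocks are made non-overlapping on the first genome:
higher-scoring blocks win, lower ones are trimmed at the edges (alignment
ends chance-extend a few bp across a rearrangement breakpoint) and dropped
only if a kept block sits strictly inside them. Conserved fractions
decompose each genome of a trio, on its own coordinates, into the four
homology classes (shared with both, with each alone, unique), which tile
the genome exactly. Ribbon bins assign each HSP its score / max-score
ratio in the four conventional color bins (≤ 0.25, ≤ 0.50, ≤ 0.75,
> 0.75); raw alignment score is used, which for a fixed scoring scheme is
equivalent to using bit scores. The ORF finder reports ATG-initiated,
stop-terminated frames ≥ 303 bp (stop included) on both strands, crossing
the origin on circular genomes, longest-per-stop by default; ORFs that
span the origin are clipped there so all reported coordinates satisfy
start < end. The gene matrix classes each gene per genome as
absent/single/duplicated and tallies duplicated genes excluding ORFs and
tRNAs.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive, BED stays half-open. Features crossing a circular origin are
  represented as split interval pairs.
* Word size, E-value cutoffs, the 100 bp repeat floor, the 303 bp ORF
  floor, the 250 bp summary threshold, the 1 kb cluster floor and the
  50,000-hit cap are the field-standard values for this analysis and are
  echoed in every run report header.
* Seeding k-mer sizes (31 bait / 63 assembly), the 50 bp minimum overlap,
  X-drop 20, band 50 and chain gap 100 are engineering defaults recorded
  in configuration; none is pinned by the underlying analysis design.
* Desk-scale problem sizes (30–45 kb organelles, 50–300 kb chromosomes,
  10–20 recovery seeds) are used by the test suite and the acceptance
  script; they exercise every code path of the full-scale analysis while
  keeping a complete run in minutes on one core. The acceptance script
  states the size used (`n`) next to every reported value.

## Known limitations

* The read simulator has uniform substitution errors only — no
  quality-dependent error profiles, indel errors, or coverage bias — so
  assembler robustness to realistic Illumina noise is untested.
* The zero-mismatch assembler is designed for organelle-sized genomes at
  high depth; it makes no attempt at heterozygosity, heteroplasmy, or
  nuclear-scale assembly.
* Repeat detection is exact-only by design (mismatch-tolerant repeats are
  a different statistic); diverged duplications appear through the
  alignment engine instead.
* The aligner's seed table is a plain dictionary: appropriate for
  organelle-vs-chromosome searches at desk scale, not for genome-scale
  all-vs-all work.
* NUMT/NUPT cross-talk is inherent: nuclear copies of plastome DNA also
  align to the mitogenome's plastome-derived regions and are counted as
  NUMTs, exactly as the no-direction-inference rule dictates. Recovery
  statistics against ground truth are therefore computed per class on
  configurations without the competing class.
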