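# Methods

`pfinish` implements the computational half of a grass plastome
finishing-and-verification workflow, plus the rare-genomic-change
statistics used downstream of it. This note documents the models,
their assumptions, the tunable parameters, and the design choices made
where the procedure was genuinely open.

## The synthetic study system

Grass plastomes are ~130–160 kb circles with a quadripartite layout:
a Large Single Copy region (LSC), a Small Single Copy region (SSC),
and two Inverted Repeats (IRa/IRb) whose sequences are exact reverse
complements. The generator (`pfinish.synthetic`) emulates this system
at a reduced scale so that whole-pipeline tests run in seconds:

* **Genome**: LSC + IRa + SSC + revcomp(IRa), i.i.d. base composition
  at a configurable GC fraction (default 0.38, typical of grass
  plastomes). Default region lengths 8 000 / 3 000 / 2 000 bp (16 kb
  total) scale the real ~80/22.5/12.5 kb layout down ~8-fold while
  keeping every structural property (two-copy IR much longer than any
  chance repeat, IR longer than a read, LSC > SSC).
* **Boundary sharpness**: candidate genomes are screened so that no
  *spurious* inverted pair ≥ 100 bp exists and the true IR is not
  extensible by a chance complementary base at either boundary; a
  colliding candidate is regenerated from the same seeded stream.
  Without this screen, "0 bp boundary error" would be unattainable
  for ~1/2 of random genomes for reasons unrelated to the caller.
* **Spacer locus**: two 24 bp tRNA-like marker features flank a point
  locus inside IRa (default: the IR midpoint). `inject_foreign_segment`
  inserts a donor there in *both* IR copies (reverse-complemented in
  IRb), as required to preserve the mirror invariant — mirroring how a
  real mtDNA insert in the trnI–trnL spacer appears in both repeats.
* **Reads**: single-end, fixed length (default 100 bp), uniform starts
  on each circle, read count Poisson with mean
  `mean_depth × copy_number × G / L`. Copy number models organelle
  stoichiometry (tens of plastids vs hundreds-to-thousands of
  mitochondria per cell). Errors are i.i.d. substitutions only; no
  indels, chimeras, paired ends or library bias — sufficient for every
  downstream operation tested here, and a stated limitation for
  transfer to real data. Qualities are constant Phred 40 placeholders
  (read QC is out of scope).
* **Fragmentation**: the circle is cut into `n_contigs` contigs
  separated by gaps of length uniform in [min_gap, 2·min_gap]
  (default min_gap 150), each contig randomly strand-flipped —
  emulating de novo assembler output, which for these genomes averaged
  about five contigs per sample.

What passing tests on this generator do **not** show: robustness to
indel errors, heterogeneous coverage (GC bias), nuclear paralogs
(NUPTs), or repeats beyond the IR. The generator deliberately omits
these so that each operation's tests isolate one mechanism.

## Genome walking (`pfinish.finishing`)

Gap closing follows the read-overlap walking recipe: reads overlapping
a contig end by at least `min_overlap` (default 30 bp, either strand)
with at most `max_mismatch` mismatches (default 0) are collected, and
extension proceeds column by column, appending the majority base,
"minus the overlap". Design decisions where the recipe is ambiguous:

* **Per-column majority with conservative halting.** Extension stops
  at a tie, when top support falls below `min_support` (default 2
  reads, avoiding single-read chimeras), or on a *supported conflict*:
  a runner-up base carried by ≥ `min_support` reads and ≥ 30 % of the
  column (`conflict_frac`). The conflict rule is what makes walking
  stall cleanly at the IR exits, where the read pile genuinely forks
  between the two single-copy continuations, instead of committing to
  an arbitrary branch.
* **Capped rounds.** One round appends at most
  `(read_len − min_overlap) / 2` columns, so every appended column is
  voted on by a thick pile; the thin far tail of a pile (1–3 reads)
  could otherwise cross a fork silently before the conflict becomes
  visible. Thin ambiguous columns (≤ 3 voters with any dissent) defer
  to the next, re-anchored round. At very low coverage (≲ 10×) forks
  can still in principle be crossed; organelle data is far above this.
* **Merging** uses exact suffix–prefix overlap ≥ `merge_overlap`
  (default 100 bp), in any orientation combination; the longest
  overlap wins, and one end matching two *distinct* partners at equal
  best overlap raises an ambiguity error naming the contigs. Contigs
  wholly contained in another (either strand) are dropped — after
  walking, the two IR-internal copies of a contig converge to
  identical sequences and must be deduplicated.
* **Circularization**: a single remaining contig is closed when its
  ends share an exact overlap ≥ `merge_overlap`, or — because walking
  stalls *exactly at* IR exit junctions, leaving abutting ends with no
  overlap — when ≥ `min_support` reads span the end-to-start butt
  junction with `min_overlap` anchor on each side.

**Flip-flop isomers.** A quadripartite circle exists as two inversion
isomers (the SSC flips orientation by recombination between the IR
copies); no read shorter than the IR can distinguish them, and the
walker deterministically reconstructs one. `ir.canonical_form`
therefore defines assembly identity: linearize as LSC+IRa+SSC+IRb and
take the lexicographic minimum over both strands and both SSC
orientations. Recovery tests compare canonical forms; this is the
strongest identity claim the data supports.

## Read mapping and depth (`compute_depth`)

Reads are placed by exact k-mer seeding (15-mers at 15 bp stride,
both strands, circular) and verified by Hamming distance at
`min_identity` (default 0.95) — adequate because the simulator's error
model is substitution-only. A read matching m locations (e.g. both IR
copies) contributes 1/m of a read at each, so total coverage is
conserved (Σ per-base counts = total aligned bases) and the IR's mean
depth matches the genome-wide mean, as observed when a plastid read
pool is mapped to a complete quadripartite assembly. The alternative
(counting multi-mappers fully at every location) would double the IR's
apparent depth and break both the tiling-arithmetic identity
(mean = nL/G) and the ~1.0 insert/IR ratios seen for genuine inserts.

## Insert provenance (`pfinish.inserts`)

* **Segmentation** tiles a region greedily by the best local-alignment
  hit against labeled FASTA panels (both strands), recursing into the
  flanks; unclaimed positions become "unassigned" segments, and the
  segments always partition the region exactly. Alignment uses
  `Bio.Align.PairwiseAligner` with blastn-like scoring (match +2,
  mismatch −3, gap open −5, extend −2). A hit qualifies with
  alignment length ≥ `min_hit_len` (30 bp), percent identity ≥
  `min_identity` (65 %, just below the weakest informative hit class
  worth reporting), **and** raw score ≥ `min_score` (40 ≈ 20 net
  matches). The score floor is the standard guard against chance local
  alignments between a ~kb random region and a multi-kb panel, which
  can reach 30+ columns at ~65 % identity; a genuine short hit such as
  a 176 bp rRNA fragment at 67 % identity scores ≈ 60 and passes.
* **Depth-ratio verdict**: ratio = mean(insert) / mean(IR) on one
  depth profile. Under fractional multi-mapping a genuine plastid
  insert rides at the IR's own depth (ratio ≈ 1), while sequence
  present only in the mitochondria at copy ratio R shows ratio ≈ R.
  The verdict threshold `suspect_ratio` = 3.0 sits between the ≈ 1.0
  ratios of verified inserts and the ≥ 5 of the order-of-magnitude
  organelle copy-number argument; coverage at the first/last insert
  base is reported alongside as a continuity check.
* **In-silico PCR**: a primer binds where it matches the template with
  ≤ `max_mismatch` mismatches *and* its 3′-terminal 5-mer matches
  exactly (polymerase extension chemistry). Product length is the
  distance between the two primers' 5′ positions, inclusive; all
  products ≤ `max_product` (10 kb) are reported, sorted by length,
  mirroring a gel check of product number and size.
* **Percent identity** is matches / alignment columns × 100, from a
  global alignment for `pairwise_identity` and per-hit local
  alignments for segments. Identities from BLASTn-style tools may
  differ slightly on gapped hits; tests assert tolerance bands, not
  equality.

## Hotspot signatures (`pfinish.hotspots`)

A maximal perfect tandem repeat with unit p is a maximal run
[i, j) with seq[x] = seq[x+p] throughout and j−i ≥ 2p; it is reported
once per unit length with `copies = span // p` full copies (the span
may include a partial copy). The same definition is enforced in tests
by an exhaustive O(n³) oracle. `detect_repeat_creation` combines the
SNP list of two pre-aligned sequences with the repeats present in the
derived but not the ancestral sequence — the signature of
substitutions converting a degenerate duplication into a perfect
repeat, which then becomes a slipped-strand deletion substrate (the
textbook case here: two SNPs creating a perfect 18 bp repeat in the
infA region). Deletion catalogues treat per-taxon maximal gap runs in
an alignment interval as events; events are merged as "shared" only at
*identical* alignment endpoints — overlapping but unequal gaps stay
separate, a deliberate convention since reported approximate deletion
sizes are alignment-dependent.

## Parsimony statistics (`pfinish.parsimony`)

Step counts use the Hartigan generalization of the Fitch pass, exact
on multifurcations (including the basal trifurcation of an unrooted
binary tree). Gap and ambiguity characters are missing data: a missing
leaf carries the full state set and never forces a step on its pendant
edge. Per site with n_eff non-missing leaves:
min = #states − 1; max = n_eff − largest state class (the star-tree
score). Ensemble CI = Σmin/Σobs and RI = (Σmax−Σobs)/(Σmax−Σmin);
following the PAUP* convention the CI sums exclude
parsimony-uninformative sites by default (such sites always have
min = obs = max, so the RI is unaffected either way). CI is undefined
(None) when no included site varies, RI when Σmax = Σmin.
`brute_force_best_tree` enumerates all unrooted topologies for 4–7
taxa (3, 15, 105, 945) by stepwise edge insertion and returns every
optimal tree — a small-instance stand-in for heuristic MP search,
which is out of scope, as is recomputing statistics of any large
real multi-genome matrix (those require the original accessions).

## Problem sizes and numerical notes

Test and acceptance runs use 5–16 kb genomes at 12–50× depth, 50–100
random genome replicates for boundary recovery, 200 random ≤ 6-taxon
matrices against exhaustive ancestral-labeling enumeration, and 100
random ≤ 200 b sequences against the cubic repeat oracle — sizes
chosen so the full suite completes in well under a minute of CPU per
module while every statistical assertion retains a derived 3σ
tolerance (never a fitted one). Coordinates are 0-based half-open
internally; BED output keeps BED conventions, GFF3 and human-readable
TSV/CLI output are 1-based inclusive.
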