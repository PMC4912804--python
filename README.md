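# pfinish

Finishing and verification toolkit for organelle (plastid) genome
assemblies, with the rare-genomic-change statistics that typically
follow: in-silico genome walking to close assembly gaps, inverted-repeat
boundary calling and quadripartite annotation, detection and
verification of foreign (mitochondrial) inserts, mutational-hotspot
signatures, and Fitch parsimony matrix statistics.

## Who this is for

Anyone assembling chloroplast genomes from shotgun reads: de novo
assemblers leave a grass plastome in a handful of contigs, and the
finishing steps — closing gaps with the reads themselves, locating the
inverted repeat (IR), and deciding whether an unexpected sequence in
the trnI–trnL spacer is a genuine mitochondrial-to-plastid transfer or
an assembly artifact — are exactly the steps this package makes
scriptable and testable.

## The methods in brief

* **Genome walking.** Reads overlapping a contig end by ≥ 30 bp are
  collected (either strand) and the per-column majority base is
  appended, minus the overlap; extension halts conservatively at ties,
  low support, or a supported conflict (which is how walking stalls at
  IR exits instead of guessing). Contigs merge on exact end overlaps
  ≥ 100 bp; a lone contig circularizes by end overlap or a
  read-supported end-to-start junction.
* **IR structure.** The IR pair is found by seeded self-comparison of
  the sequence against its reverse complement; the boundaries are the
  outermost positions where inverted-orientation identity ends
  (the plus/plus → plus/minus transition). Regions are labeled
  LSC/IRa/SSC/IRb with |LSC| ≥ |SSC|, and one IR copy can be excised
  for matrix building.
* **Insert provenance.** A spacer region is tiled by best local hits
  against labeled reference panels (mito / contaminant / …), and the
  insert's mean read depth is compared with the IR's: organelle copy
  numbers (tens of plastids vs hundreds–thousands of mitochondria per
  cell) make a genuine plastid insert ride at ratio ≈ 1 while
  mitochondrial carry-over shows the copy ratio. Primer pairs are
  checked by in-silico PCR (exact product lengths, 3′-anchored
  binding).
* **Hotspots.** Maximal perfect tandem repeats (slipped-strand
  mispairing substrate), SNPs that convert a degenerate duplication
  into a perfect repeat, and per-taxon deletion catalogues from an
  alignment.
* **Parsimony statistics.** Parsimony-informative site counts, Fitch
  (Hartigan) tree length, and ensemble CI/RI with the PAUP*-style
  exclusion of uninformative sites, plus exhaustive best-tree search
  for ≤ 7 taxa as a small-instance oracle.

A synthetic-data module generates quadripartite plastomes, injected
inserts, shotgun reads at organelle-specific copy numbers, and
assembler-like contig fragmentation — all with serializable ground
truth, so every pipeline stage is tested by parameter recovery.

## Worked example

Simulate a 5.2 kb plastome (LSC 3000, IR 800, SSC 600), shear it into
4 contigs, and finish it from the reads alone:

```
$ pfinish simulate --lsc 3000 --ir 800 --ssc 600 --depth 40 \
      --n-contigs 4 --seed 5 --out-dir demo
wrote genome (5200 bp), 2085 reads, 4 contigs to demo

$ pfinish finish --contigs demo/contigs.fasta --reads demo/reads.fastq \
      --out-dir demo/out
1 sequence(s); circular=True; mean depth 40.1
```

All four gaps closed, the assembly circularized, and the mean mapped
depth (40.1×) matches the simulated 40×. Annotate the quadripartite
structure (coordinates 1-based inclusive):

```
$ pfinish ir --genome demo/genome.fasta --min-ir-len 500 --out-dir demo/ir
LSC     1       3000
IRa     3001    3800
SSC     3801    4400
IRb     4401    5200
```

The boundaries equal the generator's ground truth exactly. The repeat
scanner on the 36-base derived infA-region haplotype reports the
perfect duplication created by its two SNPs — start 1, unit 18 bp,
2 copies:

```
$ pfinish repeat --seq TATGACAGAAAAAAAAAATATGACAGAAAAAAAAAA --min-unit 10
1       18      2       TATGACAGAAAAAAAAAA
```

The library surface mirrors the CLI (`pfinish.generate_plastome`,
`walk_close_gaps`, `find_inverted_repeats`, `classify_segments`,
`depth_ratio_test`, `predict_amplicon`, `find_tandem_repeats`,
`compute_ci_ri`, …); see `docs/methods.md` for the models, parameter
defaults and design decisions.

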