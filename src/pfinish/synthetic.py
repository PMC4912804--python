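"""Synthetic quadripartite plastomes, foreign-insert injection, shotgun
reads and assembler-like fragmentation, with full ground truth.

The generator emulates the statistical structure a grass plastome
analysis assumes: a circular genome partitioned into LSC, IRa, SSC and
IRb (IRb the reverse complement of IRa), an intergenic spacer locus
inside the IR flanked by two tRNA-like marker features, single-end
shotgun reads with Poisson coverage scaled by per-genome copy number,
i.i.d. substitution errors, and fragmentation into a handful of contigs
separated by gaps.

Real plastomes are 130-160 kb; defaults here are scaled to the tens of
kilobases so that whole-pipeline tests run in seconds while preserving
every structural property the downstream operations depend on.

Coordinates are 0-based half-open on the circle throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import LocusNotFoundError, ParameterError
from .sequtils import circular_slice, mutate, random_seq, revcomp

#: smallest inverted repeat the structure caller is expected to detect;
#: generated genomes are screened so no *spurious* pair this long exists.
MIN_DETECTABLE_IR = 100

#: length of the tRNA-like marker features flanking the spacer locus.
MARKER_LEN = 24

LEFT_MARKER = "trnI_like"
RIGHT_MARKER = "trnL_like"


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic quadripartite plastome.

    lsc_len / ir_len / ssc_len are the region lengths in bases,
    gc_frac the i.i.d. GC fraction (grass plastomes sit near 0.38),
    spacer_offset the position of the insert locus within the IR.
    """

    lsc_len: int = 8000
    ir_len: int = 3000
    ssc_len: int = 2000
    gc_frac: float = 0.38
    spacer_offset: int | None = None  # default: IR midpoint
    seed: int = 0

    @property
    def spacer(self) -> int:
        return self.ir_len // 2 if self.spacer_offset is None else self.spacer_offset

    def validate(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise ParameterError("all region lengths must be > 0")
        if self.ir_len < 2 * MIN_DETECTABLE_IR:
            raise ParameterError(
                f"ir_len must be >= {2 * MIN_DETECTABLE_IR} "
                "(twice the minimum detectable IR length)"
            )
        if not 0.0 <= self.gc_frac <= 1.0:
            raise ParameterError("gc_frac must lie in [0, 1]")
        if not 0 <= self.spacer < self.ir_len:
            raise ParameterError("spacer_offset must lie in [0, ir_len)")

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class Plastome:
    """A circular genome with optional quadripartite annotation.

    regions maps LSC/IRa/SSC/IRb to (start, end) half-open intervals
    (end may wrap past len(sequence) only conceptually; canonical
    genomes are linearized at the LSC start so intervals never wrap).
    features holds additional labeled intervals (marker stand-ins).
    """

    sequence: str
    regions: dict[str, tuple[int, int]] | None = None
    features: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def region_seq(self, name: str) -> str:
        if self.regions is None or name not in self.regions:
            raise LocusNotFoundError(name)
        s, e = self.regions[name]
        return circular_slice(self.sequence, s, e) if s >= e else self.sequence[s:e]


Read = tuple[str, str, str]  # (id, sequence, quality)


@dataclass
class ReadSet:
    """Single-end reads plus per-read ground truth.

    truth holds one (genome_index, start, strand) triple per read,
    where strand 0 is forward and 1 reverse, and start is the forward-
    strand origin on the source circle.
    """

    reads: list[Read]
    read_len: int
    truth: list[tuple[int, int, int]] = field(default_factory=list)
    _kmer_index: dict | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.reads)

    def subset(self, keep) -> "ReadSet":
        """New ReadSet with reads at the given indices."""
        keep = list(keep)
        return ReadSet(
            reads=[self.reads[i] for i in keep],
            read_len=self.read_len,
            truth=[self.truth[i] for i in keep] if self.truth else [],
        )


@dataclass
class TruthRecord:
    """Serializable ground truth sufficient to recompute every expected
    recovery value in parameter-recovery tests."""

    kind: str
    regions: dict[str, tuple[int, int]] | None = None
    insert: dict | None = None
    copy_numbers: dict[str, float] | None = None
    seeds: dict[str, int] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["regions"] = (
            {k: tuple(v) for k, v in d["regions"].items()} if d.get("regions") else None
        )
        return cls(**d)


def _fix_boundaries(genome: list[str], spec: GenomeSpec, rng: np.random.Generator) -> None:
    """Resample bases adjacent to the IR boundaries so the true IR is
    not extensible by chance (which would blur exact boundary calls)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L, I, S = spec.lsc_len, spec.ir_len, spec.ssc_len
    n = L + 2 * I + S
    # outward extension: base before IRa vs base after IRb (wraps to 0)
    while genome[L - 1] == comp[genome[0]]:
        genome[L - 1] = "ACGT"[rng.integers(4)]
    # inward extension: first SSC base vs last SSC base
    a1, b0 = L + I, L + I + S
    if S == 1:
        # single-base SSC cannot pair with itself unless self-complementary
        while genome[a1] == comp[genome[a1]]:  # pragma: no cover - impossible for DNA
            genome[a1] = "ACGT"[rng.integers(4)]
    else:
        while genome[a1] == comp[genome[b0 - 1]]:
            genome[a1] = "ACGT"[rng.integers(4)]
    assert n == len(genome)


def generate_plastome(
    spec: GenomeSpec, max_tries: int = 25
) -> tuple[Plastome, TruthRecord]:
    """Generate a circular quadripartite plastome with ground truth.

    The genome is LSC + IRa + SSC + revcomp(IRa), linearized at the LSC
    start. Candidate genomes containing any *other* inverted repeat of
    at least MIN_DETECTABLE_IR bases, or whose IR boundaries happen to
    be extensible, are rejected and regenerated (deterministically,
    from the same seeded stream).
    """
    spec.validate()
    from .ir import find_inverted_repeats  # local import: no cycle

    rng = np.random.default_rng(spec.seed)
    L, I, S = spec.lsc_len, spec.ir_len, spec.ssc_len
    n = spec.total_len
    true_regions = {
        "LSC": (0, L),
        "IRa": (L, L + I),
        "SSC": (L + I, L + I + S),
        "IRb": (L + I + S, n),
    }
    for _ in range(max_tries):
        lsc = random_seq(L, spec.gc_frac, rng)
        ira = random_seq(I, spec.gc_frac, rng)
        ssc = random_seq(S, spec.gc_frac, rng)
        genome = list(lsc + ira + ssc)
        genome[L + I + S :] = revcomp("".join(genome[L : L + I]))
        _fix_boundaries(genome, spec, rng)
        seq = "".join(genome)
        pairs = find_inverted_repeats(seq, min_len=MIN_DETECTABLE_IR)
        if len(pairs) == 1 and (pairs[0].ira, pairs[0].irb) == (
            true_regions["IRa"],
            true_regions["IRb"],
        ):
            break
    else:  # pragma: no cover - vanishingly unlikely for sane specs
        raise ParameterError(
            "could not generate a collision-free plastome; spec too small?"
        )

    off = min(max(spec.spacer, MARKER_LEN), I - MARKER_LEN)
    locus = L + off
    features = {
        LEFT_MARKER: (locus - MARKER_LEN, locus),
        RIGHT_MARKER: (locus, locus + MARKER_LEN),
    }
    plastome = Plastome(sequence=seq, regions=dict(true_regions), features=features)
    truth = TruthRecord(
        kind="plastome",
        regions=dict(true_regions),
        seeds={"genome": spec.seed},
        extra={"spec": dataclasses.asdict(spec), "spacer_locus": locus},
    )
    return plastome, truth


def inject_foreign_segment(
    p: Plastome, donor_seq: str, locus: str = LEFT_MARKER
) -> tuple[Plastome, TruthRecord]:
    """Insert ``donor_seq`` immediately 3' of the named feature, in BOTH
    IR copies (reverse-complemented in IRb), preserving IR mirror
    identity. Returns a new Plastome; the input is not modified.
    """
    if not donor_seq:
        raise ParameterError("donor sequence must be non-empty")
    if locus not in p.features:
        raise LocusNotFoundError(locus)
    if p.regions is None:
        raise LocusNotFoundError("plastome has no quadripartite annotation")
    a0, a1 = p.regions["IRa"]
    b0, b1 = p.regions["IRb"]
    ir_len = a1 - a0
    pos_a = p.features[locus][1]
    if not a0 < pos_a < a1:
        raise ParameterError("insert locus must lie strictly inside IRa")
    d = pos_a - a0
    pos_b = b0 + (ir_len - d)  # mirror point inside IRb (original coords)
    ld = len(donor_seq)

    seq = (
        p.sequence[:pos_a]
        + donor_seq
        + p.sequence[pos_a:pos_b]
        + revcomp(donor_seq)
        + p.sequence[pos_b:]
    )

    # intervals starting at pos_a are pushed right of the donor; intervals
    # ending at pos_b grow to absorb the mirrored donor (half-open logic)
    def shift_start(s: int) -> int:
        return s + ld * (s >= pos_a) + ld * (s > pos_b)

    def shift_end(e: int) -> int:
        return e + ld * (e > pos_a) + ld * (e >= pos_b)

    regions = {
        k: (shift_start(s), shift_end(e)) for k, (s, e) in p.regions.items()
    }
    features = {
        k: (shift_start(s), shift_end(e)) for k, (s, e) in p.features.items()
    }
    new = Plastome(sequence=seq, regions=regions, features=features)
    truth = TruthRecord(
        kind="insert",
        regions=regions,
        insert={
            "ira_copy": (pos_a, pos_a + ld),
            "irb_copy": (pos_b + ld, pos_b + 2 * ld),
            "donor_len": ld,
            "locus": locus,
        },
    )
    return new, truth


def simulate_reads(
    genomes: list[tuple[str, float]],
    read_len: int = 100,
    mean_depth: float = 50.0,
    err_rate: float = 0.0,
    seed: int = 0,
    min_overlap: int = 30,
) -> ReadSet:
    """Simulate single-end shotgun reads from one or more circles.

    Each genome carries a copy number; the expected per-base depth of
    genome g is mean_depth * copy_number(g), emulating organelle
    stoichiometry (tens of plastids vs hundreds-to-thousands of
    mitochondria per cell). Read starts are uniform on each circle,
    substitution errors i.i.d. at ``err_rate``; qualities are constant
    Phred 40 placeholders.
    """
    if read_len < 2 * min_overlap:
        raise ParameterError(f"read_len must be >= {2 * min_overlap}")
    if not 0.0 <= err_rate < 0.25:
        raise ParameterError("err_rate must lie in [0, 0.25)")
    if not genomes:
        raise ParameterError("need at least one genome")
    for gseq, copy in genomes:
        if read_len > len(gseq):
            raise ParameterError("read_len exceeds the shortest genome")
        if copy <= 0:
            raise ParameterError("copy numbers must be positive")

    rng = np.random.default_rng(seed)
    qual = "I" * read_len  # Phred 40
    reads: list[Read] = []
    truth: list[tuple[int, int, int]] = []
    for gi, (gseq, copy) in enumerate(genomes):
        n = len(gseq)
        doubled = gseq + gseq
        lam = mean_depth * copy * n / read_len
        n_reads = int(rng.poisson(lam))
        starts = rng.integers(0, n, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for ri, (s, st) in enumerate(zip(starts, strands)):
            frag = doubled[s : s + read_len]
            if st:
                frag = revcomp(frag)
            if err_rate > 0:
                frag = mutate(frag, err_rate, rng)
            reads.append((f"g{gi}_r{ri}", frag, qual))
            truth.append((gi, int(s), int(st)))
    return ReadSet(reads=reads, read_len=read_len, truth=truth)


def fragment_into_contigs(
    p: Plastome, n_contigs: int, min_gap: int = 150, seed: int = 0
) -> tuple[list, TruthRecord]:
    """Break a circular genome into disjoint contigs separated by
    ``n_contigs`` gaps of at least ``min_gap`` bases, emulating de novo
    assembler output (grass plastomes typically assemble into about
    five contigs).

    Gap lengths are drawn uniformly from [min_gap, 2*min_gap]; each
    contig keeps at least one base. Contigs are reverse-complemented
    with probability 1/2 (recorded in the truth).
    """
    from .finishing import Contig

    if n_contigs < 1:
        raise ParameterError("n_contigs must be >= 1")
    n = len(p.sequence)
    if min_gap < 0:
        raise ParameterError("min_gap must be >= 0")
    if n_contigs * (min_gap + 1) > n:
        raise ParameterError("gaps do not fit in the genome")

    rng = np.random.default_rng(seed)
    if n_contigs == 1 and min_gap == 0:
        contig = Contig(id="contig_1", sequence=p.sequence)
        truth = TruthRecord(
            kind="fragmentation",
            seeds={"fragment": seed},
            extra={"contigs": [{"id": "contig_1", "start": 0, "end": n, "rc": False}],
                   "gaps": [[0, 0]]},
        )
        return [contig], truth

    gap_lens = (min_gap + rng.integers(0, min_gap + 1, size=n_contigs)).tolist()
    if sum(gap_lens) + n_contigs > n:
        gap_lens = [min_gap] * n_contigs
        if sum(gap_lens) + n_contigs > n:  # pragma: no cover - guarded above
            raise ParameterError("gaps do not fit in the genome")
    slack = n - sum(gap_lens) - n_contigs
    extra = rng.multinomial(slack, [1.0 / n_contigs] * n_contigs).tolist()
    contig_lens = [1 + e for e in extra]
    origin = int(rng.integers(0, n))

    contigs, contig_truth, gap_truth = [], [], []
    pos = origin
    for i in range(n_contigs):
        gs, ge = pos, pos + gap_lens[i]
        cs, ce = ge, ge + contig_lens[i]
        seq = circular_slice(p.sequence, cs, ce) or p.sequence[cs % n :]
        rc = bool(rng.integers(0, 2))
        if rc:
            seq = revcomp(seq)
        contigs.append(Contig(id=f"contig_{i + 1}", sequence=seq))
        contig_truth.append(
            {"id": f"contig_{i + 1}", "start": cs % n, "end": ce % n, "rc": rc}
        )
        gap_truth.append([gs % n, ge % n])
        pos = ce
    truth = TruthRecord(
        kind="fragmentation",
        seeds={"fragment": seed},
        extra={"contigs": contig_truth, "gaps": gap_truth},
    )
    return contigs, truth
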