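"""Mutational hotspot signatures.

Covers three rare-genomic-change analyses: perfect tandem repeats
(substrate for slipped-strand mispairing), SNPs that *create* such a
repeat (e.g. two substitutions converting a degenerate duplication
into a perfect 18 bp repeat, which is subsequently lost in several
lineages), and alignment-based deletion catalogues for a region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError, ParameterError


@dataclass(frozen=True)
class RepeatFinding:
    """A maximal perfect tandem repeat: ``copies`` full copies of a
    ``unit_len``-base unit starting at ``start``; ``span`` is the
    maximal periodic stretch (may include a partial extra copy)."""

    start: int
    unit_len: int
    copies: int
    span: int
    perfect: bool = True

    @property
    def unit_end(self) -> int:
        return self.start + self.unit_len * self.copies


@dataclass(frozen=True)
class SNPRecord:
    position: int
    state_a: str
    state_b: str


@dataclass(frozen=True)
class DeletionEvent:
    taxa: tuple[str, ...]
    start: int
    end: int
    shared: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatCreationReport:
    snps: list[SNPRecord]
    created: list[RepeatFinding]
    snps_in_repeat: dict[int, list[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def find_tandem_repeats(
    seq: str, min_unit: int = 2, min_copies: int = 2
) -> list[RepeatFinding]:
    """All maximal perfect tandem repeats in ``seq``.

    A repeat with unit length p is a maximal run [i, j) with
    seq[x] == seq[x+p] for every x in [i, j-p) and j-i >= 2p; it is
    reported once per unit length with copies = (j-i) // p. Results
    are sorted by (start, unit_len).
    """
    n = len(seq)
    if min_unit < 1 or min_copies < 2:
        raise ParameterError("min_unit must be >= 1 and min_copies >= 2")
    if n < min_unit * min_copies:
        raise ParameterError("sequence shorter than min_unit * min_copies")
    out: list[RepeatFinding] = []
    for p in range(min_unit, n // min_copies + 1):
        i = 0
        limit = n - p  # positions x with a partner x+p
        while i < limit:
            if seq[i] != seq[i + p]:
                i += 1
                continue
            j = i
            while j < limit and seq[j] == seq[j + p]:
                j += 1
            span = (j - i) + p  # periodic stretch [i, j+p)
            copies = span // p
            if copies >= min_copies:
                out.append(
                    RepeatFinding(start=i, unit_len=p, copies=copies, span=span)
                )
            i = j + 1
    out.sort(key=lambda r: (r.start, r.unit_len))
    return out


def spanning_repeat(seq: str, min_unit: int = 2) -> RepeatFinding | None:
    """The perfect repeat whose full copies tile the entire input, if
    one exists (largest unit preferred)."""
    hits = [
        r
        for r in find_tandem_repeats(seq, min_unit=min_unit)
        if r.start == 0 and r.unit_len * r.copies == len(seq)
    ]
    return max(hits, key=lambda r: r.unit_len) if hits else None


def snp_compare(a: str, b: str) -> list[SNPRecord]:
    """One record per mismatching column of two pre-aligned,
    equal-length sequences, positions ascending."""
    if len(a) != len(b):
        raise FormatError("inputs must be pre-aligned to equal length")
    return [
        SNPRecord(position=i, state_a=x, state_b=y)
        for i, (x, y) in enumerate(zip(a, b))
        if x != y
    ]


def detect_repeat_creation(
    ancestral: str, derived: str, min_unit: int = 2
) -> RepeatCreationReport:
    """SNPs between two equal-length sequences plus any maximal perfect
    repeat present in the derived sequence but absent from the
    ancestral one, with the SNP positions each new repeat contains."""
    snps = snp_compare(ancestral, derived)
    anc = {
        (r.start, r.unit_len, r.copies)
        for r in find_tandem_repeats(ancestral, min_unit=min_unit)
    } if len(ancestral) >= min_unit * 2 else set()
    created = [
        r
        for r in find_tandem_repeats(derived, min_unit=min_unit)
        if (r.start, r.unit_len, r.copies) not in anc
    ] if len(derived) >= min_unit * 2 else []
    report = RepeatCreationReport(snps=snps, created=created)
    for idx, r in enumerate(created):
        inside = [s.position for s in snps if r.start <= s.position < r.start + r.span]
        report.snps_in_repeat[idx] = inside
    return report


def catalog_deletions(
    alignment: list[tuple[str, str]],
    interval: tuple[int, int] | None = None,
) -> list[DeletionEvent]:
    """Deletion events within an alignment interval.

    ``alignment`` is a list of (taxon, aligned sequence) pairs of equal
    length. Maximal runs of gap characters ('-') per taxon inside the
    interval become events; events with *identical* alignment intervals
    across taxa are merged and marked shared. Near-identical gaps stay
    separate events (coordinate-identity convention).
    """
    if not alignment:
        return []
    lengths = {len(s) for _t, s in alignment}
    if len(lengths) != 1:
        raise FormatError("ragged alignment: sequences have unequal lengths")
    aln_len = lengths.pop()
    lo, hi = interval if interval is not None else (0, aln_len)
    if not 0 <= lo <= hi <= aln_len:
        raise ParameterError("interval outside the alignment")

    by_interval: dict[tuple[int, int], list[str]] = {}
    for taxon, seq in alignment:
        i = lo
        while i < hi:
            if seq[i] != "-":
                i += 1
                continue
            j = i
            while j < hi and seq[j] == "-":
                j += 1
            by_interval.setdefault((i, j), []).append(taxon)
            i = j
    events = [
        DeletionEvent(
            taxa=tuple(sorted(taxa)), start=s, end=e, shared=len(taxa) >= 2
        )
        for (s, e), taxa in by_interval.items()
    ]
    events.sort(key=lambda ev: (ev.start, ev.end, ev.taxa))
    return events
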