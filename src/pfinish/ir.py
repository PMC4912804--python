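"""Inverted-repeat location, boundary calling and quadripartite
annotation.

The IR pair is found by seeded self-comparison of the sequence against
its own reverse complement (exact k-mer seeds, extended to maximality),
which reproduces the plus/plus -> plus/minus orientation-transition
semantics of a self-BLAST without an external binary. Boundaries are
the outermost positions at which inverted-orientation identity ends;
the two single-copy regions are then labeled LSC (the longer) and SSC
(the shorter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import AnnotationStateError, ParameterError
from .sequtils import revcomp

DEFAULT_SEED_LEN = 20


@dataclass(frozen=True)
class IRPair:
    """One inverted-repeat pair: two disjoint intervals of equal length
    whose sequences are reverse complements up to `mismatches`."""

    ira: tuple[int, int]
    irb: tuple[int, int]
    length: int
    mismatches: int = 0


@dataclass(frozen=True)
class QuadripartiteAnnotation:
    """LSC/IRa/SSC/IRb intervals partitioning the circle. By convention
    |LSC| >= |SSC| and IRa is the IR copy that follows the LSC."""

    LSC: tuple[int, int]
    IRa: tuple[int, int]
    SSC: tuple[int, int]
    IRb: tuple[int, int]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.LSC, "IRa": self.IRa, "SSC": self.SSC, "IRb": self.IRb}


def _extend_exact(seq: str, rc: str, x: int, y: int) -> tuple[int, int, int]:
    """Maximally extend an exact match seq[x]==rc[y] along its diagonal.
    Returns (x0, y0, length) of the maximal run."""
    n = len(seq)
    x0, y0 = x, y
    while x0 > 0 and y0 > 0 and seq[x0 - 1] == rc[y0 - 1]:
        x0 -= 1
        y0 -= 1
    x1, y1 = x, y
    while x1 + 1 < n and y1 + 1 < n and seq[x1 + 1] == rc[y1 + 1]:
        x1 += 1
        y1 += 1
    return x0, y0, x1 - x0 + 1


def _extend_mismatch(
    seq: str, rc: str, x0: int, y0: int, length: int, max_frac: float
) -> tuple[int, int, int, int]:
    """Greedily extend past single mismatches while the running mismatch
    fraction stays within max_frac; trailing mismatches are trimmed so
    both ends land on matching positions."""
    n = len(seq)
    mism = 0
    # extend right
    x1, y1 = x0 + length - 1, y0 + length - 1
    while True:
        nx, ny = x1 + 1, y1 + 1
        if nx >= n or ny >= n:
            break
        add_mism = 0 if seq[nx] == rc[ny] else 1
        if add_mism and (mism + 1) > max_frac * (x1 - x0 + 2):
            break
        # a mismatch is only kept if a match follows within budget
        if add_mism:
            if nx + 1 >= n or ny + 1 >= n or seq[nx + 1] != rc[ny + 1]:
                break
        mism += add_mism
        x1, y1 = nx, ny
    # extend left
    while True:
        px, py = x0 - 1, y0 - 1
        if px < 0 or py < 0:
            break
        add_mism = 0 if seq[px] == rc[py] else 1
        if add_mism and (mism + 1) > max_frac * (x1 - px + 1):
            break
        if add_mism:
            if px - 1 < 0 or py - 1 < 0 or seq[px - 1] != rc[py - 1]:
                break
        mism += add_mism
        x0, y0 = px, py
    return x0, y0, x1 - x0 + 1, mism


def find_inverted_repeats(
    seq: str,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.0,
    seed_len: int = DEFAULT_SEED_LEN,
) -> list[IRPair]:
    """Locate maximal inverted-repeat pairs of at least ``min_len``
    bases by exact-seed self-comparison against the reverse complement.

    Returns pairs sorted by length descending (empty list possible).
    Self-overlapping (palindromic) matches are split into their two
    disjoint halves.
    """
    n = len(seq)
    if n <= 2 * min_len:
        raise ParameterError("sequence must be longer than 2 * min_len")
    if seed_len > min_len:
        seed_len = max(4, min_len // 2)
    rc = revcomp(seq)

    index: dict[str, list[int]] = {}
    for j in range(n - seed_len + 1):
        index.setdefault(rc[j : j + seed_len], []).append(j)

    covered: dict[int, list[tuple[int, int]]] = {}
    raw: list[tuple[int, int, int, int]] = []  # (x0, y0, length, mismatches)
    for i in range(n - seed_len + 1):
        hits = index.get(seq[i : i + seed_len])
        if not hits:
            continue
        for j in hits:
            diag = i - j
            skip = False
            for a, b in covered.get(diag, ()):  # seed inside a known run
                if a <= i and i + seed_len <= b:
                    skip = True
                    break
            if skip:
                continue
            x0, y0, length = _extend_exact(seq, rc, i, j)
            if max_mismatch_frac > 0:
                x0, y0, length, mism = _extend_mismatch(
                    seq, rc, x0, y0, length, max_mismatch_frac
                )
            else:
                mism = 0
            covered.setdefault(diag, []).append((x0, x0 + length))
            if length >= min_len:
                raw.append((x0, y0, length, mism))

    pairs: dict[tuple[int, int, int], int] = {}
    for x0, y0, length, mism in raw:
        a = (x0, x0 + length)  # interval on seq
        b = (n - y0 - length, n - y0)  # partner interval on seq
        if a[0] > b[0]:
            a, b = b, a
        if a[1] > b[0]:  # palindromic self-overlap: split into halves
            span = b[1] - a[0]
            half = span // 2
            if half < min_len:
                continue
            a, b = (a[0], a[0] + half), (b[1] - half, b[1])
        key = (a[0], b[0], a[1] - a[0])
        if key not in pairs or pairs[key] > mism:
            pairs[key] = mism

    out = [
        IRPair(ira=(s1, s1 + ln), irb=(s2, s2 + ln), length=ln, mismatches=m)
        for (s1, s2, ln), m in pairs.items()
    ]
    out.sort(key=lambda p: (-p.length, p.ira))
    return out


def call_ir_boundaries(seq: str, pair: IRPair) -> QuadripartiteAnnotation:
    """Annotate the quadripartite structure from one IR pair.

    The two intervals between the IR copies on the circle become the
    single-copy regions; the longer is labeled LSC. IRa is defined as
    the IR copy immediately clockwise of the LSC.
    """
    n = len(seq)
    (a0, a1), (b0, b1) = pair.ira, pair.irb
    sc1 = (a1, b0)  # between copy 1 and copy 2
    sc2 = (b1 % n, a0)  # wraps through the origin
    len1 = (sc1[1] - sc1[0]) % n
    len2 = (sc2[1] - sc2[0]) % n
    if len1 == 0 or len2 == 0:
        warnings.warn(
            "degenerate quadripartite geometry: a single-copy region has length 0",
            stacklevel=2,
        )
    if len2 >= len1:
        lsc, ssc = sc2, sc1
        ir_a, ir_b = pair.ira, pair.irb  # LSC wraps, then copy1 follows it
    else:
        lsc, ssc = sc1, sc2
        ir_a, ir_b = pair.irb, pair.ira
    return QuadripartiteAnnotation(LSC=lsc, IRa=ir_a, SSC=ssc, IRb=ir_b)


def annotate(plastome, min_len: int = 1000, max_mismatch_frac: float = 0.0):
    """Find the IR, call boundaries and store them on the plastome.

    The largest pair of at least ``min_len`` is taken as THE inverted
    repeat; any further pairs trigger a warning. Returns the plastome
    (annotated in place) for chaining.
    """
    pairs = find_inverted_repeats(
        plastome.sequence, min_len=min_len, max_mismatch_frac=max_mismatch_frac
    )
    if not pairs:
        raise AnnotationStateError("no inverted repeat found at the given min_len")
    if len(pairs) > 1:
        warnings.warn(
            f"{len(pairs) - 1} additional inverted-repeat pair(s) ignored",
            stacklevel=2,
        )
    ann = call_ir_boundaries(plastome.sequence, pairs[0])
    plastome.regions = ann.as_dict()
    return plastome


def _linearized_regions(seq: str, min_len: int) -> dict[str, str]:
    """Region sequences of a circle, via fresh annotation."""
    from .sequtils import circular_slice

    pairs = find_inverted_repeats(seq, min_len=min_len)
    if not pairs:
        raise AnnotationStateError("no inverted repeat found")
    ann = call_ir_boundaries(seq, pairs[0])
    return {
        name: circular_slice(seq, *getattr(ann, name))
        for name in ("LSC", "IRa", "SSC", "IRb")
    }


def canonical_form(seq: str, min_len: int = 1000) -> str:
    """Canonical string for a quadripartite circle.

    A plastome population carries two inversion isomers (the single-copy
    regions flip orientation by recombination between the IR copies),
    and a circle has no intrinsic origin or strand; short-read data
    cannot distinguish any of these. The canonical form linearizes as
    LSC+IRa+SSC+IRb and takes the lexicographic minimum over both
    strands and both SSC orientations, so two assemblies of the same
    molecule always compare equal.
    """
    candidates = []
    for strand_seq in (seq, revcomp(seq)):
        parts = _linearized_regions(strand_seq, min_len)
        base = parts["LSC"] + parts["IRa"]
        tail = parts["IRb"]
        for ssc in (parts["SSC"], revcomp(parts["SSC"])):
            candidates.append(base + ssc + tail)
    return min(candidates)


def excise_one_ir(p) -> str:
    """Linearize the plastome with one IR copy removed: LSC + IRa + SSC.

    Reinserting revcomp(IRa) after the SSC reproduces the original
    circle exactly.
    """
    if p.regions is None:
        raise AnnotationStateError("plastome is not annotated")
    from .sequtils import circular_slice

    out = []
    for name in ("LSC", "IRa", "SSC"):
        s, e = p.regions[name]
        out.append(circular_slice(p.sequence, s, e))
    return "".join(out)
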