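"""Low-level nucleotide string helpers shared across the package.

All coordinates are 0-based, half-open. Circular sequences are plain
strings; wrap-around access goes through :func:`circular_slice`.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice ``seq`` as a circle: ``end`` may exceed ``len(seq)`` or
    ``start`` may exceed ``end`` (wrap through the origin)."""
    n = len(seq)
    if n == 0:
        return ""
    start %= n
    end %= n
    if start < end:
        return seq[start:end]
    if start == end:
        return ""
    return seq[start:] + seq[:end]


def interval_len(start: int, end: int, n: int) -> int:
    """Length of the circular half-open interval [start, end) on a circle
    of size ``n``; [x, x) has length 0."""
    return (end - start) % n


def random_seq(length: int, gc_frac: float, rng: np.random.Generator) -> str:
    """i.i.d. nucleotide string with the given GC fraction."""
    p = np.array(
        [(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2]
    )
    idx = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``
    (always to a different base)."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in ALPHABET if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def circular_equal(a: str, b: str) -> bool:
    """True when two sequences represent the same circle, up to rotation
    and strand."""
    if len(a) != len(b):
        return False
    if not a:
        return True
    doubled = b + b
    return a in doubled or revcomp(a) in doubled
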