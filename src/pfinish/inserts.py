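"""Foreign-insert detection and characterization.

A putative insert (e.g. mitochondrial DNA transferred into the
trnI-trnL spacer of the plastid IR) is characterized three ways:

* similarity segmentation -- the region is tiled greedily by best
  local-alignment hits against labeled reference panels (mito-like,
  contaminant-like, plastid, ...); uncovered stretches are reported as
  unassigned;
* read-depth verification -- organelle copy number makes true plastid
  sequence match the IR's mean depth (ratio ~ 1), while an assembly
  artifact drawn from the far more numerous mitochondria shows a much
  greater depth over the insert;
* in-silico PCR -- primer pairs spanning the insert boundaries are
  bound to the template and exact product lengths predicted, mirroring
  the gel check of product number and length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import (
    LocusNotFoundError,
    ParameterError,
    UndefinedRatioError,
)
from .sequtils import circular_slice, revcomp

DEFAULT_MIN_HIT_LEN = 30
DEFAULT_MIN_IDENTITY = 65.0  # weakest informative hit class worth reporting
DEFAULT_MIN_SCORE = 40.0  # raw-score floor against chance local hits
DEFAULT_SUSPECT_RATIO = 3.0
PRIMER_3P_EXACT = 5  # 3'-terminal bases that must match exactly


@dataclass(frozen=True)
class SegmentCall:
    """One similarity segment of a region: [start, end) on the region,
    the panel it matched, the best hit and its percent identity."""

    start: int
    end: int
    label: str
    hit_id: str | None = None
    identity: float | None = None
    hit_len: int = 0


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str


@dataclass(frozen=True)
class AmpliconPrediction:
    """Product interval on the forward strand of the template,
    inclusive of both primer 5' positions; length = end - start."""

    start: int
    end: int  # half-open; end-1 is the reverse primer's 5' base
    length: int
    forward_mismatches: int
    reverse_mismatches: int


@dataclass
class InsertReport:
    region: tuple[int, int]
    segments: list[SegmentCall]
    insert_mean: float
    ir_mean: float
    ratio: float
    verdict: str
    flank_depths: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------


def extract_region(p, left_marker: str, right_marker: str) -> tuple[str, tuple[int, int]]:
    """Intergenic sequence strictly between two marker features
    (circular-safe). Returns (sequence, (start, end))."""
    for m in (left_marker, right_marker):
        if m not in p.features:
            raise LocusNotFoundError(m)
    start = p.features[left_marker][1]
    end = p.features[right_marker][0]
    return circular_slice(p.sequence, start, end), (start, end)


# ---------------------------------------------------------------------------
# similarity segmentation


def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _best_panel_hit(aligner, region: str, panels: dict[str, dict[str, str]]):
    """Highest-scoring local hit of the region against all panel
    sequences, both strands. Ties break toward the lower region start
    coordinate, then panel/sequence name. Returns None or a dict."""
    best = None
    for label in sorted(panels):
        for sid in sorted(panels[label]):
            pseq = panels[label][sid]
            for strand, target in (("+", pseq), ("-", revcomp(pseq))):
                alns = aligner.align(region, target)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                q_blocks, t_blocks = aln.aligned
                if len(q_blocks) == 0:
                    continue
                ident = sum(
                    sum(a == b for a, b in zip(region[qs:qe], target[ts:te]))
                    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks)
                )
                aln_len = sum(qe - qs for qs, qe in q_blocks)
                for bi in range(1, len(q_blocks)):
                    aln_len += (q_blocks[bi][0] - q_blocks[bi - 1][1]) + (
                        t_blocks[bi][0] - t_blocks[bi - 1][1]
                    )
                q_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
                cand = {
                    "score": float(aln.score),
                    "label": label,
                    "hit_id": sid,
                    "strand": strand,
                    "q_start": q_iv[0],
                    "q_end": q_iv[1],
                    "identity": 100.0 * ident / aln_len if aln_len else 0.0,
                    "aln_len": aln_len,
                }
                key = (-cand["score"], cand["q_start"], label, sid)
                if best is None or key < best[0]:
                    best = (key, cand)
    return best[1] if best else None


def classify_segments(
    region: str,
    panels: dict[str, dict[str, str]],
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[SegmentCall]:
    """Greedy best-hit tiling of a region by panel similarity.

    The single best qualifying local hit claims its interval; the
    process recurses into the flanks. Positions claimed by no
    qualifying hit become 'unassigned' segments. Segments partition
    the region exactly (no overlaps, no gaps).
    """
    if not panels:
        raise ParameterError("need at least one panel")
    if not region:
        return []
    aligner = _aligner()
    calls: list[SegmentCall] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < min_hit_len:
            if hi > lo:
                calls.append(SegmentCall(lo, hi, "unassigned"))
            return
        sub = region[lo:hi]
        hit = _best_panel_hit(aligner, sub, panels)
        if (
            hit is None
            or hit["aln_len"] < min_hit_len
            or hit["identity"] < min_identity
            or hit["score"] < min_score
        ):
            calls.append(SegmentCall(lo, hi, "unassigned"))
            return
        s, e = lo + hit["q_start"], lo + hit["q_end"]
        calls.append(
            SegmentCall(
                s, e, hit["label"],
                hit_id=hit["hit_id"],
                identity=hit["identity"],
                hit_len=hit["aln_len"],
            )
        )
        recurse(lo, s)
        recurse(e, hi)

    recurse(0, len(region))
    calls.sort(key=lambda c: c.start)
    # coalesce adjacent unassigned stretches
    merged: list[SegmentCall] = []
    for c in calls:
        if merged and c.label == "unassigned" and merged[-1].label == "unassigned":
            merged[-1] = SegmentCall(merged[-1].start, c.end, "unassigned")
        else:
            merged.append(c)
    return merged


# ---------------------------------------------------------------------------
# depth-ratio verification


def depth_ratio_test(
    profile,
    insert: tuple[int, int],
    ir: tuple[int, int],
    suspect_ratio: float = DEFAULT_SUSPECT_RATIO,
) -> tuple[float, str, tuple[float, float]]:
    """Mean insert depth over mean IR depth, with a verdict.

    ratio < suspect_ratio -> 'plastid-supported' (depth consistent with
    the plastid's own copy number); otherwise 'suspect-artifact'
    (coverage looks like it came from the higher-copy mitochondria).
    Also returns coverage at the first and last insert base (flank
    continuity).
    """
    ir_mean = profile.interval_mean(*ir)
    if ir_mean == 0:
        raise UndefinedRatioError("IR interval has zero coverage")
    insert_mean = profile.interval_mean(*insert)
    ratio = insert_mean / ir_mean
    verdict = "plastid-supported" if ratio < suspect_ratio else "suspect-artifact"
    n = len(profile.counts)
    first = float(profile.counts[insert[0] % n])
    last = float(profile.counts[(insert[1] - 1) % n])
    return ratio, verdict, (first, last)


# ---------------------------------------------------------------------------
# in-silico PCR


def _binding_sites(template: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Positions where the primer anneals to the forward strand of
    ``template`` (primer 3' end pointing right). Returns
    (start, mismatches); the 3'-terminal PRIMER_3P_EXACT bases must
    match exactly even when mismatches are allowed elsewhere."""
    L = len(primer)
    sites = []
    tail = primer[-PRIMER_3P_EXACT:]
    for s in range(len(template) - L + 1):
        if template[s + L - PRIMER_3P_EXACT : s + L] != tail:
            continue
        mm = sum(a != b for a, b in zip(primer, template[s : s + L]))
        if mm <= max_mismatch:
            sites.append((s, mm))
    return sites


def predict_amplicon(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    max_product: int = 10000,
) -> list[AmpliconPrediction]:
    """Predict PCR products on a linear template.

    The forward primer binds the forward strand; the reverse primer
    binds the reverse strand (its 5' end maps to the rightmost product
    base). Product length is the distance between the two 5' ends,
    inclusive. All products up to ``max_product`` are returned, sorted
    by length.
    """
    if min(len(pair.forward), len(pair.reverse)) < 15:
        raise ParameterError("primers must be >= 15 bases")
    fwd_sites = _binding_sites(template, pair.forward, max_mismatch)
    # reverse primer: binds where its revcomp matches the forward strand
    rc = revcomp(pair.reverse)
    rev_sites = [
        (s + len(rc) - 1, mm)  # 5' end of the reverse primer on fwd coords
        for s, mm in _binding_sites(template, rc, max_mismatch)
    ]
    out = []
    for fs, fmm in fwd_sites:
        for r5, rmm in rev_sites:
            length = r5 - fs + 1
            if 0 < length <= max_product:
                out.append(
                    AmpliconPrediction(
                        start=fs, end=r5 + 1, length=length,
                        forward_mismatches=fmm, reverse_mismatches=rmm,
                    )
                )
    out.sort(key=lambda a: (a.length, a.start))
    return out


# ---------------------------------------------------------------------------
# pairwise identity


def pairwise_identity(a: str, b: str) -> float:
    """Global alignment identity: matches / alignment columns * 100."""
    if not a or not b:
        raise ParameterError("both sequences must be non-empty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    ident = sum(
        sum(x == y for x, y in zip(a[s1:e1], b[s2:e2]))
        for (s1, e1), (s2, e2) in zip(a_blocks, b_blocks)
    )
    # alignment columns: matched blocks + gapped stretches at ends/middle
    cols = 0
    prev_a = prev_b = 0
    for (s1, e1), (s2, e2) in zip(a_blocks, b_blocks):
        cols += (s1 - prev_a) + (s2 - prev_b)  # gap columns
        cols += e1 - s1
        prev_a, prev_b = e1, e2
    cols += (len(a) - prev_a) + (len(b) - prev_b)
    return 100.0 * ident / cols if cols else 0.0


def build_insert_report(
    profile,
    region: tuple[int, int],
    segments: list[SegmentCall],
    ir: tuple[int, int],
    suspect_ratio: float = DEFAULT_SUSPECT_RATIO,
) -> InsertReport:
    """Bundle segmentation and the depth-ratio verdict for one region."""
    ratio, verdict, flanks = depth_ratio_test(profile, region, ir, suspect_ratio)
    return InsertReport(
        region=region,
        segments=segments,
        insert_mean=profile.interval_mean(*region),
        ir_mean=profile.interval_mean(*ir),
        ratio=ratio,
        verdict=verdict,
        flank_depths=flanks,
    )
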