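"""De novo detection of LTR retrotransposon candidates.

The detector looks for paired direct repeats satisfying the classical
LTRharvest-style parameter window: LTR length 100-1000 bp, start-to-start
distance between the two LTRs 3000-11000 bp, and LTR-pair identity above
80%.  Strategy: exact k-mer seeds shared by two genome positions at an
admissible distance are chained along the same diagonal, extended by an
X-drop walk, and the resulting repeat pair is verified with a global
alignment identity.  Direct repeats are strand-symmetric, so only the
forward strand is scanned; element strand is assigned later from ORF
orientation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .align import ltr_identity

_XDROP = 12
_MATCH, _MISMATCH = 1, -2


@dataclass
class DetectorParams:
    """Detection window; defaults follow the standard fungal Copia screen."""

    ltr_min: int = 100
    ltr_max: int = 1000
    dist_min: int = 3000
    dist_max: int = 11000
    min_identity: float = 80.0
    seed_kmer: int = 12
    #: "start" (adopted) or "end": what "distance between LTRs" measures
    distance_anchor: str = "start"
    boundary_motif: tuple[str, str] = ("TG", "CA")
    max_seed_occurrences: int = 60
    chain_gap: int = 150

    def validate(self) -> None:
        if not (0 < self.ltr_min <= self.ltr_max):
            raise ValueError("need 0 < ltr_min <= ltr_max")
        if not (0 < self.dist_min <= self.dist_max):
            raise ValueError("need 0 < dist_min <= dist_max")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must lie in (0, 100]")


@dataclass
class LTRCandidate:
    """A detected element: two LTR spans plus the enclosed internal region.

    All coordinates are 0-based half-open on the forward strand.
    """

    contig: str
    element_start: int
    element_end: int
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    ltr_identity: float
    tsd: str | None = None
    strand: str = "."
    flags: set = field(default_factory=set)

    @property
    def ltr_len(self) -> int:
        return self.ltr5_span[1] - self.ltr5_span[0]

    @property
    def ltr_distance(self) -> int:
        return self.ltr3_span[0] - self.ltr5_span[0]


def _xdrop_extend(seq: str, a: int, b: int, d: int, left: bool) -> int:
    """Extend the repeat [a,b) vs [a+d,b+d) outwards; returns new boundary."""
    score, best, pos = 0, 0, 0
    n = len(seq)
    i = 1
    while True:
        if left:
            p1, p2 = a - i, a + d - i
            if p1 < 0:
                break
        else:
            p1, p2 = b + i - 1, b + d + i - 1
            if p2 >= n:
                break
        score += _MATCH if seq[p1] == seq[p2] else _MISMATCH
        if score > best:
            best, pos = score, i
        if score < best - _XDROP:
            break
        i += 1
    return (a - pos) if left else (b + pos)


def _seed_runs(seq: str, params: DetectorParams):
    """Yield (diagonal d, run_start, run_end) of chained same-distance seeds."""
    k = params.seed_kmer
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    pairs: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2 or len(positions) > params.max_seed_occurrences:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                d = positions[y] - positions[x]
                if params.dist_min <= d <= params.dist_max:
                    pairs[d].append(positions[x])
    for d, starts in pairs.items():
        starts.sort()
        run_start = prev = starts[0]
        for s in starts[1:] + [None]:
            if s is not None and s - prev <= params.chain_gap:
                prev = s
                continue
            yield d, run_start, prev + k
            if s is not None:
                run_start = prev = s

def find_ltr_pairs(genome: dict[str, str],
                   params: DetectorParams | None = None) -> list[LTRCandidate]:
    """Scan contigs for qualifying LTR pairs.

    Every reported candidate satisfies the full parameter window; among
    overlapping candidates the one with the highest LTR identity is kept
    (ties: longer element, then leftmost).  Output is sorted by
    (contig, element_start).
    """
    params = params or DetectorParams()
    params.validate()
    if not genome:
        raise ValueError("empty genome")
    out: list[LTRCandidate] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        raw: list[LTRCandidate] = []
        seen: set[tuple[int, int, int]] = set()
        for d, r0, r1 in _seed_runs(seq, params):
            a = _xdrop_extend(seq, r0, r1, d, left=True)
            b = _xdrop_extend(seq, r0, r1, d, left=False)
            if b - a > params.ltr_max:
                continue
            if b - a < params.ltr_min:
                continue
            if b + d > len(seq):
                continue
            key = (a, b, d)
            if key in seen:
                continue
            seen.add(key)
            ident = ltr_identity(seq[a:b], seq[a + d:b + d])
            if ident <= params.min_identity:
                continue
            raw.append(LTRCandidate(contig, a, b + d, (a, b), (a + d, b + d),
                                    round(ident, 2)))
        out.extend(_resolve_overlaps(raw))
    out.sort(key=lambda c: (c.contig, c.element_start))
    return out


def _resolve_overlaps(cands: list[LTRCandidate]) -> list[LTRCandidate]:
    # highest identity wins; ties prefer the *compact* candidate, then the
    # leftmost.  Preferring long candidates lets a spurious join between the
    # 3' LTR of one copy and the 5' LTR of a neighbouring identical copy
    # displace both genuine elements.
    ranked = sorted(cands, key=lambda c: (-c.ltr_identity,
                                          c.element_end - c.element_start,
                                          c.element_start))
    kept: list[LTRCandidate] = []
    for c in ranked:
        if all(c.element_end <= k.element_start or c.element_start >= k.element_end
               for k in kept):
            kept.append(c)
    return kept


def refine_boundaries(candidate: LTRCandidate, genome: dict[str, str],
                      window: int = 15, tsd_len: int = 5) -> LTRCandidate:
    """Shift LTR boundaries (<= ``window`` bp) onto the nearest position where
    both LTR copies start with TG(T) and end with CA; unchanged with a flag
    when no such position exists.

    Identical LTR copies plus chance flank matches can make several shifts
    motif-consistent; among them, a shift pair whose flanks form an exact
    target-site duplication is preferred (the hallmark of the true
    insertion boundary), then the smallest total shift.
    """
    seq = genome[candidate.contig].upper()
    (s5, e5), (s3, e3) = candidate.ltr5_span, candidate.ltr3_span

    def shifts(motifs: list[str], p1: int, p2: int, at_end: bool) -> list[int]:
        for motif in motifs:
            ln = len(motif)
            found = []
            for delta in sorted(range(-window, window + 1), key=abs):
                if at_end:
                    q1, q2 = p1 + delta - ln, p2 + delta - ln
                else:
                    q1, q2 = p1 + delta, p2 + delta
                if q1 < 0 or q2 + ln > len(seq):
                    continue
                if seq[q1:q1 + ln] == motif and seq[q2:q2 + ln] == motif:
                    found.append(delta)
            if found:
                return found
        return []

    starts = shifts(["TGT", "TG"], s5, s3, at_end=False)
    ends = shifts(["CA"], e5, e3, at_end=True)
    if not starts or not ends:
        c = _copy(candidate)
        c.flags.add("boundary_motif_missing")
        return c
    best = None
    for dstart in starts:
        for dend in ends:
            s, e = s5 + dstart, e3 + dend
            tsd_match = (s - tsd_len >= 0 and e + tsd_len <= len(seq)
                         and seq[s - tsd_len:s] == seq[e:e + tsd_len])
            key = (not tsd_match, abs(dstart) + abs(dend), abs(dstart))
            if best is None or key < best[0]:
                best = (key, dstart, dend)
    _, ds, de = best
    c = _copy(candidate)
    c.ltr5_span = (s5 + ds, e5 + de)
    c.ltr3_span = (s3 + ds, e3 + de)
    c.element_start = s5 + ds
    c.element_end = e3 + de
    c.ltr_identity = round(ltr_identity(seq[c.ltr5_span[0]:c.ltr5_span[1]],
                                        seq[c.ltr3_span[0]:c.ltr3_span[1]]), 2)
    if ds or de:
        c.flags.add("boundary_refined")
    return c


def detect_tsd(candidate: LTRCandidate, genome: dict[str, str],
               tsd_len: int = 5) -> str | None:
    """Exact-match target-site duplication: the ``tsd_len`` flanks left and
    right of the element, when identical.  None at contig edges (edge flag
    set on the candidate)."""
    seq = genome[candidate.contig]
    s, e = candidate.element_start, candidate.element_end
    if s - tsd_len < 0 or e + tsd_len > len(seq):
        candidate.flags.add("contig_edge")
        return None
    left = seq[s - tsd_len:s].upper()
    right = seq[e:e + tsd_len].upper()
    if left == right:
        candidate.tsd = left
        return left
    return None


def _copy(c: LTRCandidate) -> LTRCandidate:
    return LTRCandidate(c.contig, c.element_start, c.element_end, c.ltr5_span,
                        c.ltr3_span, c.ltr_identity, c.tsd, c.strand,
                        set(c.flags))
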