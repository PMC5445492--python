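"""Pairwise alignment helpers.

DNA identities are computed with edlib (banded Myers bit-vector alignment);
protein local alignments use Biopython's PairwiseAligner with BLOSUM62 and
BLASTx default gap costs (open 11, extend 1).  Identity is always defined as
matches over alignment columns, gap columns included — the stricter of the
common conventions.
"""

from __future__ import annotations

import math
import re
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# Karlin-Altschul style parameters used for the bit-score / significance
# surrogate (gapped BLOSUM62, open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended cigar."""
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def ltr_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two DNA sequences.

    100 x matches / alignment-columns, counting gap columns.  Symmetric.
    """
    if not a or not b:
        raise ValueError("ltr_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    if (len(b), b) < (len(a), a):   # canonical order: exact symmetry even
        a, b = b, a                 # when co-optimal paths differ
    res = edlib.align(a, b, mode="NW", task="path")
    matches, columns = _cigar_stats(res["cigar"])
    return 100.0 * matches / columns


def glocal_identity(query: str, target: str) -> float:
    """Percent identity of the best semi-global alignment of the full
    ``query`` inside ``target`` (edlib HW mode)."""
    if not query or not target:
        raise ValueError("empty sequence")
    res = edlib.align(query.upper(), target.upper(), mode="HW", task="path")
    matches, columns = _cigar_stats(res["cigar"])
    return 100.0 * matches / columns


def dna_identity_coverage(a: str, b: str,
                          coverage_of: str = "query") -> tuple[float, float]:
    """BLAST-like (identity%, coverage) for two DNA sequences.

    The shorter sequence is treated as the query and aligned semi-globally
    inside the longer one; identity is matches/columns over the trimmed
    alignment.  ``coverage_of="query"`` reports the aligned fraction of the
    query (rescue semantics: how much of the fragment matches);
    ``coverage_of="both"`` reports the aligned fraction of the *longer*
    sequence as well, returning the smaller of the two (cluster semantics:
    a 30% fragment does not cover a full-length copy).
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    query, target = query.upper(), target.upper()
    # cheap k-mer prefilter: pairs sharing essentially no 12-mers cannot
    # reach any of the clustering thresholds, so skip the alignment
    if len(query) >= 400:
        kmers = {target[i:i + 12] for i in range(len(target) - 11)}
        probes = range(0, len(query) - 11, 7)
        shared = sum(query[i:i + 12] in kmers for i in probes)
        if shared / max(len(probes), 1) < 1e-3:
            return 50.0, 0.0
    band = max(100, len(query) // 2)
    res = edlib.align(query, target, mode="HW", task="path", k=band)
    if res["editDistance"] == -1:  # beyond the band: identity is far below
        return 50.0, 1.0           # any threshold of interest
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    # trim leading/trailing non-match blocks (soft local semantics)
    qlen_aligned = sum(n for n, op in ops if op in "=XI")
    while ops and ops[0][1] != "=":
        n, op = ops.pop(0)
        if op in "=XI":
            qlen_aligned -= n
    while ops and ops[-1][1] != "=":
        n, op = ops.pop()
        if op in "=XI":
            qlen_aligned -= n
    if not ops:
        return 0.0, 0.0
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, _ in ops)
    cov = qlen_aligned / len(query)
    if coverage_of == "both":
        tstart, tend = res["locations"][0]
        cov = min(cov, (tend - tstart + 1) / len(target))
    return 100.0 * matches / columns, cov


@lru_cache(maxsize=1)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_protein_score(query: str, ref: str) -> float:
    """Smith-Waterman score (BLOSUM62, 11/1) of two protein sequences.
    Characters outside the 20-letter alphabet are replaced by X."""
    q = _sanitize(query)
    r = _sanitize(ref)
    if not q or not r:
        return 0.0
    return float(protein_aligner().score(q, r))


def local_protein_alignment(query: str, ref: str):
    """Best local alignment; returns (score, qstart, qend, rstart, rend,
    aligned_length) or None if no positive-scoring alignment exists."""
    q = _sanitize(query)
    r = _sanitize(ref)
    if not q or not r:
        return None
    alns = protein_aligner().align(q, r)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    qspan = aln.aligned[0]
    rspan = aln.aligned[1]
    if len(qspan) == 0:
        return None
    qstart, qend = int(qspan[0][0]), int(qspan[-1][1])
    rstart, rend = int(rspan[0][0]), int(rspan[-1][1])
    ncols = sum(int(e - s) for s, e in qspan)
    ncols += sum(max(0, int(qspan[i + 1][0] - qspan[i][1])) for i in range(len(qspan) - 1))
    ncols += sum(max(0, int(rspan[i + 1][0] - rspan[i][1])) for i in range(len(rspan) - 1))
    return float(alns.score), qstart, qend, rstart, rend, ncols


_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _sanitize(protein: str) -> str:
    return "".join(c if c in _VALID_AA else "X" for c in protein.upper())


def bit_score(raw_score: float) -> float:
    """Karlin-Altschul style bit score of a raw local alignment score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def neg_log10_evalue(raw_score: float, m: int, n: int) -> float:
    """-log10 of the significance surrogate K*m*n*exp(-lambda*S).

    Larger means more significant; differences are directly comparable to
    the "orders of magnitude" of a BLAST E-value gap.
    """
    ln_e = math.log(KA_K) + math.log(max(m, 1)) + math.log(max(n, 1)) - KA_LAMBDA * raw_score
    return -ln_e / math.log(10.0)
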