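"""Structural annotation of elements: PBS, CHS, PPT, ORFs, protein motifs.

The centrepiece is the Conserved Hairpin Site (CHS) detector.  Fungal GalEa
elements lack a primer binding site; instead, right after the 5' LTR they
carry a 9 bp CHSeq1 that is a perfect reverse-complement palindrome once the
LTR's terminal A is included, followed 12-41 bp downstream by a 9 bp CHSeq2
that is the reverse complement of CHSeq1 at 8 of 9 positions — the
outstanding pair being a strictly conserved A/A mismatch between CHSeq1
position 7 and CHSeq2 position 3 (1-based).  The two sequences can fold
into a stem-loop immediately downstream of the LTR, the presumed functional
analogue of the PBS.  The hairpin model here is pure Watson-Crick
complementarity; no thermodynamic folding is attempted, because the defining
evidence for the CHS is the sequence complementarity itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .motifs import (CHS_INTERVAL_MAX, CHS_INTERVAL_MIN, CHS_LEN,
                     DEFAULT_PRIMER_DB, FUNGAL_MOTIFS, METAZOAN_MOTIFS,
                     revcomp)

_COMPLEMENT_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

CHS_SEARCH_WINDOW = 60          # bp after the 5' LTR scanned for CHSeq1
CHS_MAX_PALINDROME_SUBS = 1     # derivative CHSeq1 acceptance
PBS_WINDOW = 30
PBS_MAX_MISMATCH = 1
PPT_MIN_RUN = 8
PPT_WINDOW = 50
ORF_MIN_AA = 300
EXTENDED_CHS_MIN, EXTENDED_CHS_MAX = 33, 62
EXTENDED_CHS_IDENTITY = 90.0
RIP_AT_THRESHOLD = 0.70


# ---------------------------------------------------------------------------
# priming region: PBS / CHS
# ---------------------------------------------------------------------------

@dataclass
class PBSAnnotation:
    sequence: str
    offset: int                  # bp after the 5' LTR
    primer_id: str
    match_length: int
    mismatches: int = 0


@dataclass
class CHSAnnotation:
    chseq1: str
    chseq2: str
    interval: int                # bp between CHSeq1 end and CHSeq2 start
    mismatch_pos_1: int | None   # 1-based within CHSeq1
    mismatch_pos_2: int | None   # 1-based within CHSeq2
    palindrome_ok: bool
    hairpin_pairing: list = field(default_factory=list)
    offset: int = 0              # CHSeq1 start, bp after the 5' LTR


def find_pbs(element: str, ltr5_end: int,
             primer_db=DEFAULT_PRIMER_DB, window: int = PBS_WINDOW,
             max_mismatch: int = PBS_MAX_MISMATCH) -> PBSAnnotation | None:
    """Best exact-or-near match of a primer motif within ``window`` bp after
    the 5' LTR (mismatch tolerance 1 by default, for assembly error)."""
    if ltr5_end is None or ltr5_end <= 0:
        raise RuntimeError("element needs an annotated 5' LTR")
    region = element[ltr5_end:ltr5_end + window + 20].upper()
    best = None  # (mismatches, offset, annotation)
    for primer_id, motif in primer_db:
        for off in range(0, min(window, len(region) - len(motif)) + 1):
            seg = region[off:off + len(motif)]
            mm = sum(a != b for a, b in zip(seg, motif))
            if mm <= max_mismatch:
                key = (mm, off)
                if best is None or key < best[0]:
                    best = (key, PBSAnnotation(seg, off, primer_id,
                                               len(motif), mm))
    return best[1] if best else None


def _palindrome_subs(ten_mer: str) -> int:
    """Substitutions needed to make a 10-mer a reverse-complement palindrome
    (number of non-complementary position pairs)."""
    bad = 0
    for i in range(len(ten_mer) // 2):
        if (ten_mer[i], ten_mer[-1 - i]) not in _COMPLEMENT_PAIRS:
            bad += 1
    return bad


def find_chs(element: str, ltr5_end: int,
             window: int = CHS_SEARCH_WINDOW,
             max_palindrome_subs: int = CHS_MAX_PALINDROME_SUBS
             ) -> CHSAnnotation | None:
    """Scan for a Conserved Hairpin Site downstream of the 5' LTR.

    CHSeq1 candidates: 9-mers starting within ``window`` bp of the LTR end
    whose preceding base + 9-mer form a reverse-complement palindrome (or a
    derivative within ``max_palindrome_subs`` substitutions — observed
    derivatives mostly vary at the third and/or sixth nucleotide).  CHSeq2:
    a 9-mer 12-41 bp downstream matching the reverse complement of CHSeq1 at
    >= 8 of 9 positions.  The best-scoring pair is reported with its stem
    pairing map; position i of CHSeq1 pairs position 10-i of CHSeq2.
    """
    seq = element.upper()
    best = None  # (rank key, annotation)
    for p in range(ltr5_end, min(ltr5_end + window, len(seq) - CHS_LEN)):
        if p < 1:
            continue
        s1 = seq[p:p + CHS_LEN]
        ten = seq[p - 1] + s1
        subs = _palindrome_subs(ten)
        if subs > max_palindrome_subs:
            continue
        rc1 = revcomp(s1)
        s1_end = p + CHS_LEN
        for interval in range(CHS_INTERVAL_MIN, CHS_INTERVAL_MAX + 1):
            q = s1_end + interval
            if q + CHS_LEN > len(seq):
                break
            s2 = seq[q:q + CHS_LEN]
            mism = [i for i in range(CHS_LEN) if s2[i] != rc1[i]]
            if len(mism) > 1:
                continue
            if mism:
                m2 = mism[0] + 1           # 1-based position in CHSeq2
                m1 = CHS_LEN + 1 - m2      # paired position in CHSeq1
                aa = s1[m1 - 1] == "A" and s2[m2 - 1] == "A"
                if not aa:                 # the single stem mismatch must be
                    continue               # the conserved A/A pair
            else:
                m1 = m2 = None
                aa = False
            pairing = [(i, CHS_LEN + 1 - i) for i in range(1, CHS_LEN + 1)
                       if m1 is None or i != m1]
            ann = CHSAnnotation(s1, s2, interval, m1, m2,
                                palindrome_ok=(subs == 0),
                                hairpin_pairing=pairing,
                                offset=p - ltr5_end)
            # prefer: intact palindrome, canonical A/A mismatch, fewer stem
            # mismatches, closest to the LTR
            key = (subs, not aa, len(mism), p - ltr5_end, interval)
            if best is None or key < best[0]:
                best = (key, ann)
    return best[1] if best else None


def detect_extended_chs(post_ltr_blocks: dict[str, str],
                        chs_annotations: dict[str, CHSAnnotation],
                        min_identity: float = EXTENDED_CHS_IDENTITY
                        ) -> int | None:
    """Length of the 'extended CHS' shared by the families of one species.

    ``post_ltr_blocks``: family id -> sequence starting right after the
    5' LTR.  The extended CHS is the longest block starting at the LTR end,
    containing both CHSeq1 and CHSeq2, conserved at >= ``min_identity``
    percent between every pair of families, with length within 33-62 bp.
    """
    if len(post_ltr_blocks) < 2:
        raise ValueError("extended CHS needs at least two families")
    ids = sorted(post_ltr_blocks)
    need = 0
    for fid in ids:
        ann = chs_annotations.get(fid)
        if ann is None:
            return None
        need = max(need, ann.offset + CHS_LEN + ann.interval + CHS_LEN)
    for length in range(EXTENDED_CHS_MAX, EXTENDED_CHS_MIN - 1, -1):
        if length < need:
            break
        if any(len(post_ltr_blocks[f]) < length for f in ids):
            continue
        # the block must end on a conserved position, otherwise the 90%
        # allowance pads it with unconserved tail
        last = {post_ltr_blocks[f][length - 1] for f in ids}
        if len(last) != 1:
            continue
        ok = True
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                x, y = post_ltr_blocks[a][:length], post_ltr_blocks[b][:length]
                ident = 100.0 * sum(u == v for u, v in zip(x, y)) / length
                if ident < min_identity:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return length
    return None


# ---------------------------------------------------------------------------
# PPT / ORFs / protein motifs
# ---------------------------------------------------------------------------

def find_ppt(element: str, ltr3_start: int, min_purine_run: int = PPT_MIN_RUN,
             window: int = PPT_WINDOW) -> tuple[int, int] | None:
    """Longest A/G run of >= ``min_purine_run`` bp within ``window`` bp
    upstream of the 3' LTR; span in element coordinates."""
    lo = max(0, ltr3_start - window)
    region = element[lo:ltr3_start].upper()
    best = None
    for m in re.finditer(r"[AG]+", region):
        if m.end() - m.start() >= min_purine_run:
            if best is None or (m.end() - m.start()) > (best[1] - best[0]):
                best = (lo + m.start(), lo + m.end())
    return best


@dataclass
class ORF:
    start: int        # element coordinates, 0-based half-open, forward strand
    end: int
    strand: str
    length_aa: int
    protein: str


def find_orfs(element: str, min_len_aa: int = ORF_MIN_AA) -> list[ORF]:
    """Maximal stop-to-stop open stretches of >= ``min_len_aa`` codons on
    both strands; sorted by descending length."""
    from Bio.Seq import Seq
    out = []
    n = len(element)
    for strand in "+-":
        seq = element.upper() if strand == "+" else revcomp(element.upper())
        for frame in range(3):
            sub = seq[frame:]
            prot = str(Seq(sub[:len(sub) - len(sub) % 3]).translate())
            for m in re.finditer(r"[^*]+", prot):
                if m.end() - m.start() < min_len_aa:
                    continue
                s = frame + 3 * m.start()
                e = frame + 3 * m.end()
                if strand == "-":
                    s, e = n - e, n - s
                out.append(ORF(s, e, strand, m.end() - m.start(),
                               prot[m.start():m.end()]))
    out.sort(key=lambda o: (-o.length_aa, o.start))
    return out


def element_strand(element: str, min_len_aa: int = ORF_MIN_AA) -> str:
    """Strand of the longest ORF ('.' if none qualifies)."""
    orfs = find_orfs(element, min_len_aa)
    return orfs[0].strand if orfs else "."


@dataclass
class MotifHit:
    name: str
    position: int      # 0-based aa position
    matched: str


def scan_protein_motifs(protein: str,
                        include_metazoan: bool = True) -> list[MotifHit]:
    """Regular-pattern scan for the conserved gag/PR/INT/RT/RNaseH motifs.

    Scans the fungal signature set and (optionally) the metazoan variants;
    all matches are reported, sorted by position.
    """
    if len(protein) < 100:
        raise ValueError("protein too short to scan (need >= 100 aa)")
    sets = FUNGAL_MOTIFS + (METAZOAN_MOTIFS if include_metazoan else [])
    hits = []
    for name, rx, _ in sets:
        for m in re.finditer(rx, protein):
            hits.append(MotifHit(name, m.start(), m.group()))
    hits.sort(key=lambda h: (h.position, h.name))
    return hits


def at_content_rip_flag(dna: str) -> tuple[float, bool]:
    """(AT fraction over unambiguous bases, ripped flag at > 70% AT)."""
    if not dna:
        raise ValueError("empty sequence")
    seq = dna.upper()
    at = sum(seq.count(b) for b in "AT")
    acgt = at + sum(seq.count(b) for b in "CG")
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    frac = at / acgt
    return frac, frac > RIP_AT_THRESHOLD


# ---------------------------------------------------------------------------
# per-element annotation summary
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["element_id", "ltr_len", "tsd", "priming_type",
                      "pbs_seq", "chseq1", "chseq2", "interval",
                      "mismatch_pos1", "mismatch_pos2", "ppt_len",
                      "orf_count", "motifs_found", "at_fraction", "ripped"]


def annotate_element(element_id: str, element: str, ltr_len: int,
                     tsd: str | None = None) -> dict:
    """One summary row per element (layout mirrors a per-family annotation
    table: priming type, CHS geometry, PPT, ORF and motif content, RIP flag)."""
    ltr5_end = ltr_len
    ltr3_start = len(element) - ltr_len
    pbs = find_pbs(element, ltr5_end)
    chs = find_chs(element, ltr5_end)
    if chs is not None:
        priming = "CHS"
        pbs = None  # CHS and PBS are mutually exclusive by construction
    elif pbs is not None:
        priming = "PBS"
    else:
        priming = "none"
    ppt = find_ppt(element, ltr3_start)
    orfs = find_orfs(element)
    motifs = []
    if orfs:
        motifs = [h.name for h in scan_protein_motifs(orfs[0].protein)]
    at_frac, ripped = at_content_rip_flag(element)
    return {
        "element_id": element_id,
        "ltr_len": ltr_len,
        "tsd": tsd or "none",
        "priming_type": priming,
        "pbs_seq": pbs.sequence if pbs else "",
        "chseq1": chs.chseq1 if chs else "",
        "chseq2": chs.chseq2 if chs else "",
        "interval": chs.interval if chs else "",
        "mismatch_pos1": chs.mismatch_pos_1 if chs else "",
        "mismatch_pos2": chs.mismatch_pos_2 if chs else "",
        "ppt_len": (ppt[1] - ppt[0]) if ppt else 0,
        "orf_count": len(orfs),
        "motifs_found": ",".join(dict.fromkeys(motifs)),
        "at_fraction": round(at_frac, 3),
        "ripped": ripped,
    }
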