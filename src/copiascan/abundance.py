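"""Masking-based copy recovery and per-clade abundance estimation.

The detector only reports elements whose two LTRs survived; masking the
genome with the family consensus library additionally recovers solo LTRs,
truncated copies and other degenerate derivatives.  Copy numbers are then
estimated two ways — detector candidates, and merged mask hits longer than
3 kb (the smallest size a two-LTR candidate can have) — and genomic
proportions are computed from all mask hits without a size floor.  The
GalEa/Copia ratio, GalEa / (GalEa + FunCo1 + other Copia), is the
predominance estimator compared across the three measurements.

The masking engine is an in-repo k-mer-seeded aligner honouring the
RepeatMasker-style contract of classic genome screens: divergence cap
20%, hits >= 50 bp, same-family hits merged across gaps <= 100 bp.
Divergence is edit operations over alignment columns (no CpG correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import edlib
import numpy as np
import pandas as pd

from .align import _cigar_stats
from .motifs import revcomp

MAX_DIVERGENCE = 0.20
MIN_HIT_LEN = 50
MERGE_GAP = 100
SIZE_FILTER = 3000
SEED_K = 12


@dataclass
class MaskHit:
    contig: str
    start: int                 # 0-based half-open
    end: int
    family_id: str
    clade: str
    divergence: float
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# masking engine
# ---------------------------------------------------------------------------

def _seed_clusters(consensus: str, contig: str, k: int = SEED_K,
                   max_gap: int = 400, diag_tol: int = 400):
    """Chain shared k-mer positions into putative hit regions.

    Matches are grouped along approximate alignment diagonals, so a genome
    locus matching two distant parts of the consensus (e.g. a solo LTR
    hitting both LTR copies) produces separate fragments.  Yields
    (genome_start, genome_end, cons_start, cons_end) per region.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(consensus) - k + 1):
        index.setdefault(consensus[i:i + k], []).append(i)
    matches = []  # (genome_pos, cons_pos)
    for g in range(len(contig) - k + 1):
        for c in index.get(contig[g:g + k], ()):
            matches.append((g, c))
    matches.sort()
    open_groups: list[list[tuple[int, int]]] = []
    for g, c in matches:
        placed = False
        for grp in open_groups:
            lg, lc = grp[-1]
            if g - lg <= max_gap and abs((g - c) - (lg - lc)) <= diag_tol:
                grp.append((g, c))
                placed = True
                break
        if not placed:
            open_groups.append([(g, c)])
        still_open = []
        for grp in open_groups:
            if g - grp[-1][0] > max_gap:
                yield _group_span(grp, k)
            else:
                still_open.append(grp)
        open_groups = still_open
    for grp in open_groups:
        yield _group_span(grp, k)


def _group_span(group, k):
    gs, ge = group[0][0], group[-1][0] + k
    cs, ce = min(x[1] for x in group), max(x[1] for x in group) + k
    return gs, ge, cs, ce


def mask_genome(genome: dict[str, str], library: list[tuple[str, str, str]],
                max_divergence: float = MAX_DIVERGENCE,
                min_len: int = MIN_HIT_LEN,
                merge_gap: int = MERGE_GAP) -> list[MaskHit]:
    """Screen contigs with a consensus library.

    ``library``: (family_id, clade, consensus DNA).  Both strands of each
    consensus are scanned.  Hits of the same family closer than
    ``merge_gap`` are merged; regions claimed by several families keep the
    best-scoring family label only.
    """
    if not library:
        raise ValueError("empty consensus library")
    raw: list[MaskHit] = []
    for contig_name, contig in genome.items():
        contig = contig.upper()
        for family_id, clade, consensus in library:
            for strand in "+-":
                cons = consensus.upper() if strand == "+" else revcomp(consensus.upper())
                for gs, ge, cs, ce in _seed_clusters(cons, contig):
                    frag = cons[cs:ce]
                    pad = 50 + int(0.25 * len(frag))
                    lo, hi = max(0, gs - pad), min(len(contig), ge + pad)
                    res = edlib.align(frag, contig[lo:hi], mode="HW",
                                      task="path",
                                      k=int(0.5 * len(frag)) + 50)
                    if res["editDistance"] < 0:
                        continue
                    matches, columns = _cigar_stats(res["cigar"])
                    div = 1.0 - matches / columns
                    span = res["locations"][0]
                    start, end = lo + span[0], lo + span[1] + 1
                    if div <= max_divergence and end - start >= min_len:
                        raw.append(MaskHit(contig_name, start, end, family_id,
                                           clade, round(div, 4), strand))
    merged = _merge_family_hits(raw, merge_gap)
    return _resolve_family_overlaps(merged)


def _merge_family_hits(hits: list[MaskHit], merge_gap: int) -> list[MaskHit]:
    out = []
    keyfn = lambda h: (h.contig, h.family_id, h.strand, h.start, h.end)
    by_group: dict[tuple, list[MaskHit]] = {}
    for h in sorted(hits, key=keyfn):
        by_group.setdefault((h.contig, h.family_id, h.strand), []).append(h)
    for (_, _, _), group in sorted(by_group.items()):
        cur = group[0]
        for h in group[1:]:
            if h.start - cur.end <= merge_gap:
                w1, w2 = cur.length, h.length
                div = (cur.divergence * w1 + h.divergence * w2) / (w1 + w2)
                cur = MaskHit(cur.contig, cur.start, max(cur.end, h.end),
                              cur.family_id, cur.clade, round(div, 4),
                              cur.strand)
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return out


def _resolve_family_overlaps(hits: list[MaskHit]) -> list[MaskHit]:
    """Keep the best-labeled hit where families compete for the same locus
    (score: aligned length times identity)."""
    ranked = sorted(hits, key=lambda h: (-(h.length * (1 - h.divergence)),
                                         h.contig, h.start, h.family_id))
    kept: list[MaskHit] = []
    for h in ranked:
        clash = False
        for k in kept:
            if k.contig != h.contig or k.family_id == h.family_id:
                continue
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0.5 * h.length:
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start, h.end, h.family_id))
    return kept


# ---------------------------------------------------------------------------
# abundance estimators
# ---------------------------------------------------------------------------

def copy_counts(hits: list[MaskHit], min_len: int = SIZE_FILTER
                ) -> dict[str, int]:
    """Merged hits of length >= ``min_len``, counted per clade."""
    counts: dict[str, int] = {}
    for h in hits:
        if h.length >= min_len:
            counts[h.clade] = counts.get(h.clade, 0) + 1
    return counts


def _union_length(spans: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(spans):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def genomic_proportion(hits: list[MaskHit], genome_len: int
                       ) -> dict[str, float]:
    """Percent of the genome covered per clade (span union, no size floor)."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    spans: dict[str, dict[str, list]] = {}
    for h in hits:
        spans.setdefault(h.clade, {}).setdefault(h.contig, []).append(
            (h.start, h.end))
    return {clade: 100.0 * sum(_union_length(v) for v in per_contig.values())
            / genome_len
            for clade, per_contig in spans.items()}


def galea_ratio(galea: float, funco1: float, other: float):
    """GalEa / (GalEa + FunCo1 + other Copia), rounded half-up to 2 decimals;
    the sentinel "ne" (not estimated) when the denominator is zero."""
    total = galea + funco1 + other
    if total <= 0:
        return "ne"
    return float(Decimal(galea / total).quantize(Decimal("0.01"),
                                                 rounding=ROUND_HALF_UP))


@dataclass
class AbundanceTable:
    genome: str
    genome_len: int
    detector_copies: dict
    mask_copies_ge3kb: dict
    mask_bp: dict
    proportions: dict
    ratios: dict  # estimator -> ratio or "ne"

    def to_frame(self) -> pd.DataFrame:
        clades = ["GalEa", "FunCo1", "OtherCopia"]
        rows = []
        for c in clades:
            rows.append({
                "genome": self.genome, "clade": c,
                "detector_copies": self.detector_copies.get(c, 0),
                "mask_copies_ge3kb": self.mask_copies_ge3kb.get(c, 0),
                "mask_bp": self.mask_bp.get(c, 0),
                "genomic_proportion_pct": round(self.proportions.get(c, 0.0), 2),
            })
        return pd.DataFrame(rows)


def abundance_table(genome_name: str, genome_len: int,
                    detector_clades: list[str],
                    hits: list[MaskHit],
                    size_filter: int = SIZE_FILTER) -> AbundanceTable:
    """All three estimators for one genome.

    ``detector_clades``: clade label of each detector-reported element.
    """
    det: dict[str, int] = {}
    for c in detector_clades:
        det[c] = det.get(c, 0) + 1
    mask_counts = copy_counts(hits, size_filter)
    props = genomic_proportion(hits, genome_len)
    bp = {clade: int(genome_len * pct / 100.0) for clade, pct in props.items()}

    def _ratio(d: dict) -> object:
        return galea_ratio(d.get("GalEa", 0), d.get("FunCo1", 0),
                           d.get("OtherCopia", 0))

    ratios = {"detector": _ratio(det), "mask_ge3kb": _ratio(mask_counts),
              "mask_proportion": _ratio(props)}
    return AbundanceTable(genome_name, genome_len, det, mask_counts, bp,
                          props, ratios)


def compare_estimators(tables: list[AbundanceTable],
                       flag_threshold: float = 0.15) -> dict:
    """Pairwise Pearson correlations and per-genome deviations between the
    three GalEa/Copia ratio estimators; genomes whose ratios disagree by
    more than ``flag_threshold`` are flagged (the pattern produced by a
    large load of 1-3 kb deleted derivatives invisible to the detector)."""
    if len(tables) < 3:
        raise ValueError("need at least three genomes to compare estimators")
    names = ["detector", "mask_ge3kb", "mask_proportion"]
    ok = [t for t in tables if all(t.ratios[n] != "ne" for n in names)]
    series = {n: np.array([t.ratios[n] for t in ok], dtype=float) for n in names}
    corr = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = series[a], series[b]
            if len(ok) >= 2 and np.std(x) > 0 and np.std(y) > 0:
                r = float(np.corrcoef(x, y)[0, 1])
            else:
                r = 1.0 if np.allclose(x, y) else float("nan")
            corr[(a, b)] = round(r, 4)
    flagged = []
    deviations = {}
    for t in ok:
        devs = [abs(t.ratios[a] - t.ratios[b])
                for i, a in enumerate(names) for b in names[i + 1:]]
        deviations[t.genome] = round(max(devs), 4)
        if max(devs) > flag_threshold:
            flagged.append(t.genome)
    return {"correlations": corr, "deviations": deviations, "flagged": flagged}
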