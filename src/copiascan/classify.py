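"""Superfamily discrimination and clade assignment of detected elements.

Elements are compared, through their translated RT/RNaseH domain, against a
bundled labeled reference panel (Copia / Gypsy / BEL-Pao superfamilies;
Copia entries additionally carry a clade label).  The panel bundled here is
synthetic: it is derived from the simulator's clade consensus proteins plus
decoys, so the package ships no third-party database extracts.

Clade calls follow a two-condition rule: (i) the five best panel hits all
belong to the candidate clade, and (ii) the significance gap between the
best in-clade and the best out-of-clade hit exceeds 10 orders of magnitude
of the E-value-like surrogate.  Both conditions must pass, otherwise the
element stays "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .align import (bit_score, local_protein_alignment, local_protein_score,
                    neg_log10_evalue)
from .motifs import revcomp
from .synth import _seed_from, clade_domain_protein, mutate_protein

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

DEFAULT_MIN_BITS = 50.0
DEFAULT_CLADE_GAP = 10.0


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

@dataclass
class PanelEntry:
    id: str
    superfamily: str  # Copia | Gypsy | BELPao
    clade: str | None
    sequence: str


@dataclass
class ReferencePanel:
    entries: list[PanelEntry]

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("panel ids must be unique")

    def callable_clades(self) -> set[str]:
        """Clades with >= 5 entries (required by the five-best-hits rule)."""
        counts: dict[str, int] = {}
        for e in self.entries:
            if e.clade:
                counts[e.clade] = counts.get(e.clade, 0) + 1
        return {c for c, n in counts.items() if n >= 5}

    def representatives(self) -> list[PanelEntry]:
        """One entry per (superfamily, clade) group, by id order."""
        seen, reps = set(), []
        for e in sorted(self.entries, key=lambda x: x.id):
            key = (e.superfamily, e.clade)
            if key not in seen:
                seen.add(key)
                reps.append(e)
        return reps


def default_panel(n_per_clade: int = 6, divergence: float = 0.08) -> ReferencePanel:
    """Synthetic reference panel: per Copia clade, ``n_per_clade`` diverged
    copies of the clade consensus RT/RNaseH protein; plus Gypsy and BEL-Pao
    decoy groups."""
    entries = []
    groups = [("Copia", "GalEa"), ("Copia", "FunCo1"), ("Copia", "OtherCopia"),
              ("Gypsy", None), ("BELPao", None)]
    for superfamily, clade in groups:
        source = clade or superfamily
        base, protected = clade_domain_protein(source)
        for i in range(n_per_clade):
            seq = mutate_protein(base, divergence,
                                 _seed_from("panel", source, i), protected)
            entries.append(PanelEntry(f"{source}_{i + 1}", superfamily, clade, seq))
    return ReferencePanel(entries)


def write_panel_fasta(panel: ReferencePanel, path) -> None:
    with open(path, "w") as fh:
        for e in panel.entries:
            clade = e.clade or "none"
            fh.write(f">{e.id} superfamily={e.superfamily} clade={clade}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i:i + 60] + "\n")


def read_panel_fasta(path) -> ReferencePanel:
    entries = []
    with open(path) as fh:
        header, chunks = None, []
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header:
                    entries.append(_entry_from(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
        if header:
            entries.append(_entry_from(header, "".join(chunks)))
    return ReferencePanel(entries)


def _entry_from(header: str, seq: str) -> PanelEntry:
    fields = header.split()
    tags = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
    clade = tags.get("clade")
    return PanelEntry(fields[0], tags.get("superfamily", "Copia"),
                      None if clade in (None, "none") else clade, seq)


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate_six_frames(dna: str) -> dict[str, str]:
    """All six frame translations (standard code, stops as ``*``)."""
    if len(dna) < 3:
        raise ValueError("need at least one codon")
    dna = dna.upper()
    rc = revcomp(dna)
    out = {}
    for i, frame in enumerate(("+1", "+2", "+3")):
        sub = dna[i:]
        out[frame] = str(Seq(sub[:len(sub) - len(sub) % 3]).translate())
    for i, frame in enumerate(("-1", "-2", "-3")):
        sub = rc[i:]
        out[frame] = str(Seq(sub[:len(sub) - len(sub) % 3]).translate())
    return out


def rip_aware_translate(dna: str, panel: ReferencePanel,
                        window_codons: int = 60,
                        min_signal: float = 35.0,
                        switch_margin: float = 8.0) -> str:
    """Frameshift-tolerant translation.

    The sequence is cut into ``window_codons``-codon windows.  Within each
    window the forward frame maximizing the best local-alignment score
    against the panel representatives wins; to keep the reading frame
    continuous through regions the panel cannot score (e.g. gag), a window
    only switches away from the previous frame when another frame beats it
    by ``switch_margin``, and windows with no signal at all inherit the
    previous frame.  Inherited-frame windows that are riddled with stops
    (RIP-decayed beyond reading) are emitted as X-runs so downstream
    alignment ignores them.
    """
    reps = panel.representatives()
    win = window_codons * 3
    pieces = []
    frame = 0
    for start in range(0, max(len(dna) - 30, 1), win):
        chunk = dna[start:start + win + 2]
        prots, scores = [], []
        for f in range(3):
            sub = chunk[f:]
            prot = str(Seq(sub[:len(sub) - len(sub) % 3]).translate())
            prots.append(prot)
            scores.append(max((local_protein_score(prot, r.sequence)
                               for r in reps), default=0.0))
        best_f = int(np.argmax(scores))
        if scores[best_f] >= min_signal and \
                scores[best_f] > scores[frame] + switch_margin:
            frame = best_f
        prot = prots[frame]
        if scores[frame] < min_signal and prot.count("*") > 0.1 * max(len(prot), 1):
            pieces.append("X" * len(prot))
        else:
            pieces.append(prot)
    return "".join(pieces)


# ---------------------------------------------------------------------------
# domain extraction and calls
# ---------------------------------------------------------------------------

@dataclass
class DomainHit:
    query_id: str
    ref_id: str
    score: float          # bit-score-like
    evalue_like: float    # -log10 of the significance surrogate
    frame: str
    query_span: tuple[int, int]


@dataclass
class DomainExtract:
    protein: str
    frame: str
    query_span: tuple[int, int]  # aa coordinates in the winning translation
    bits: float


@dataclass
class CladeCall:
    query_id: str
    superfamily: str
    clade: str
    top5_refs: list[str] = field(default_factory=list)
    score_gap: float = 0.0


def extract_rt_rnaseh(element_dna: str, panel: ReferencePanel,
                      min_bits: float = DEFAULT_MIN_BITS) -> DomainExtract | None:
    """Locate and cut out the RT/RNaseH domain of an element.

    The best-scoring local alignment of any frame translation (plus the
    frameshift-tolerant translation for decayed input) against the panel
    fixes the 5' boundary; the 3' boundary is extended to the last ADxxTK
    match within 150 aa downstream, the canonical end of the RNaseH.
    Returns None (element "no-domain") below ``min_bits``.
    """
    if len(element_dna) < 1000:
        raise ValueError("element must be at least 1 kb")
    candidates = dict(translate_six_frames(element_dna))

    def _search(cands):
        found = None
        for frame, prot in cands.items():
            for ref in panel.representatives():
                aln = local_protein_alignment(prot, ref.sequence)
                if aln is None:
                    continue
                score, qstart, qend = aln[0], aln[1], aln[2]
                if found is None or score > found[0]:
                    found = (score, frame, qstart, qend, prot)
        return found

    best = _search(candidates)
    # frameshifted or RIP-decayed input: fall back to the window-stitched
    # translation only when no clean frame carries a strong domain
    if best is None or bit_score(best[0]) < 3.0 * min_bits:
        stitched = _search({"rip-aware":
                            rip_aware_translate(element_dna, panel)})
        if stitched is not None and (best is None or stitched[0] > best[0]):
            best = stitched
    if best is None or bit_score(best[0]) < min_bits:
        return None
    score, frame, qstart, qend, prot = best
    tail = prot[qend:qend + 150]
    import re
    last = None
    for m in re.finditer(r"AD..TK", tail):
        last = m
    if last is not None:
        qend += last.end()
    return DomainExtract(prot[qstart:qend], frame, (qstart, qend),
                         round(bit_score(score), 2))


def score_panel(domain: str, panel: ReferencePanel,
                query_id: str = "query") -> list[DomainHit]:
    """Score a domain protein against every panel entry; hits sorted by
    descending score, ties broken by reference id."""
    hits = []
    for e in panel.entries:
        s = local_protein_score(domain, e.sequence)
        hits.append(DomainHit(query_id, e.id, round(bit_score(s), 2),
                              round(neg_log10_evalue(s, len(domain),
                                                     len(e.sequence)), 2),
                              "", (0, len(domain))))
    hits.sort(key=lambda h: (-h.score, h.ref_id))
    return hits


def assign_superfamily(domain: str, panel: ReferencePanel,
                       min_bits: float = DEFAULT_MIN_BITS) -> str:
    """Superfamily of the best-scoring panel hit ("unknown" below threshold)."""
    if not domain:
        raise ValueError("empty domain")
    if not panel.entries:
        raise RuntimeError("empty reference panel")
    hits = score_panel(domain, panel)
    best = hits[0]
    if best.score < min_bits:
        return "unknown"
    return next(e.superfamily for e in panel.entries if e.id == best.ref_id)


def assign_clade(domain: str, panel: ReferencePanel, query_id: str = "query",
                 gap: float = DEFAULT_CLADE_GAP) -> CladeCall:
    """Two-condition clade call (five best hits + significance gap).

    Only clades with >= 5 panel entries are callable; the gap is measured in
    log10 units of the significance surrogate, mirroring an E-value
    difference of 10 orders of magnitude.
    """
    callable_clades = panel.callable_clades()
    hits = score_panel(domain, panel, query_id)
    by_id = {e.id: e for e in panel.entries}
    top5 = hits[:5]
    call = CladeCall(query_id, "Copia", "unassigned",
                     [h.ref_id for h in top5])
    if not callable_clades or len(hits) < 5:
        return call
    clades5 = {by_id[h.ref_id].clade for h in top5}
    if len(clades5) != 1:
        return call
    clade = clades5.pop()
    if clade is None or clade not in callable_clades:
        return call
    best_in = max(h.evalue_like for h in hits if by_id[h.ref_id].clade == clade)
    out = [h.evalue_like for h in hits if by_id[h.ref_id].clade != clade]
    best_out = max(out) if out else float("-inf")
    call.score_gap = round(best_in - best_out, 2)
    if call.score_gap > gap:
        call.clade = clade
    return call
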