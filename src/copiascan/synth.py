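"""Synthetic Pezizomycotina-like genomes with implanted Copia LTR
retrotransposons and full structural ground truth.

The generator emulates every feature the downstream stages must detect:

* paired LTRs of 100-1000 bp starting ``TGT`` and ending ``CA``;
* a 5 bp target-site duplication (TSD) around intact insertions;
* a priming region right after the 5' LTR — either a classical PBS or, for
  fungal GalEa elements, the Conserved Hairpin Site (CHSeq1 + 12-41 bp
  spacer + CHSeq2 with the conserved A/A stem mismatch);
* a single long ORF whose polyprotein carries the gag/protease/integrase/
  RT/RNaseH motifs in canonical order;
* a polypurine tract (PPT) just upstream of the 3' LTR;
* degraded derivatives: point-mutated copies, 5'/3' truncations, solo LTRs,
  nested insertions, and RIP-like C->T hypermutated copies driven to an
  AT-content target.

Every implanted copy is described by a :class:`TruthRecord`; a fixed
:class:`SimConfig` seed reproduces the genome and truth table bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ltr_identity
from .motifs import (CHS_INTERVAL_MAX, CHS_INTERVAL_MIN, FUNGAL_MOTIFS,
                     PBS_FUNCO1, PBS_GALEA_METAZOAN, chseq2_from_chseq1,
                     revcomp)

BASES = np.array(list("ACGT"))

# filler amino-acid alphabet: excludes C, D, E and H so that random spacers
# cannot spell any of the scanned motif signatures by accident
_FILLER_AA = np.array(list("AFGIKLMNPQRSTVWY"))

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

TOTAL_MIN = 3000
TOTAL_MAX = 11000

DEGRADATIONS = ("intact", "mutated", "truncated", "solo_ltr", "nested", "ripped")


class CapacityError(RuntimeError):
    """Raised when non-overlapping implant sites cannot be placed."""


def _seed_from(*parts) -> int:
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# background and protein scaffolds
# ---------------------------------------------------------------------------

def make_background(length: int, gc: float, seed: int) -> str:
    """I.i.d. random DNA of the requested length and GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _random_protein(length: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(_FILLER_AA, size=length))


def _implant(seq: list[str], motif: str, pos: int) -> None:
    seq[pos:pos + len(motif)] = list(motif)


def clade_domain_protein(clade: str, length: int = 340) -> tuple[str, set[int]]:
    """Deterministic RT/RNaseH domain protein for a clade.

    Copia clades (GalEa, FunCo1, OtherCopia, ...) receive the fungal RT and
    RNaseH signatures (KSRLVI, QTDD, CQPEA, terminal ADxxTK); Gypsy- and
    BEL/Pao-like proteins only carry a YVDD-style RT box.  Returns the
    protein and the set of motif-protected positions.
    """
    low = clade.lower()
    if low.startswith("gypsy"):
        clade = "Gypsy"
    elif low.startswith(("belpao", "bel")):
        clade = "BELPao"
    rng = np.random.default_rng(_seed_from("domain", clade))
    prot = _random_protein(length, rng)
    protected: set[int] = set()
    if clade in ("Gypsy", "BELPao"):
        layout = [("YVDD", 90)]
    else:
        layout = [("KSRLVI", 30), ("QTDD", 90), ("CQPEA", 200),
                  ("ADGMTK", length - 12)]
    for motif, pos in layout:
        _implant(prot, motif, pos)
        protected.update(range(pos, pos + len(motif)))
    return "".join(prot), protected


def mutate_protein(protein: str, rate: float, seed: int,
                   protected: set[int] = frozenset()) -> str:
    rng = np.random.default_rng(seed)
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        choices = [a for a in _FILLER_AA if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _gagpol_protein(spec: "ElementSpec", target_len: int,
                    rng: np.random.Generator) -> str:
    """gag-PR-INT scaffold followed by the clade RT/RNaseH domain, padded
    with filler to ``target_len`` amino acids."""
    motifs = spec.orf_motifs
    if motifs is None:
        motifs = [inst for _, _, inst in FUNGAL_MOTIFS[:4]]
    domain, protected = clade_domain_protein(spec.clade)
    fam_rate = 0.05 if spec.family_id else 0.0
    domain = mutate_protein(domain, fam_rate,
                            _seed_from("famdomain", spec.family_id), protected)
    scaffold: list[str] = []
    scaffold += _random_protein(25, rng)
    for inst in motifs:
        scaffold += list(inst)
        scaffold += _random_protein(30, rng)
    pad = target_len - len(scaffold) - len(domain) - 15
    if pad < 0:
        raise ValueError(
            f"motif list cannot fit: needs >= {len(scaffold) + len(domain) + 15}"
            f" aa, only {target_len} available")
    scaffold += _random_protein(pad, rng)
    return "".join(scaffold) + domain + "".join(_random_protein(15, rng))


def _encode(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[a][int(rng.integers(len(_CODONS[a])))] for a in protein)


def _has_antisense_orf(dna: str, min_codons: int) -> bool:
    from Bio.Seq import Seq
    rc = revcomp(dna)
    for f in range(3):
        sub = rc[f:]
        prot = str(Seq(sub[:len(sub) - len(sub) % 3]).translate())
        run = 0
        for a in prot:
            run = 0 if a == "*" else run + 1
            if run >= min_codons:
                return True
    return False


# ---------------------------------------------------------------------------
# element construction
# ---------------------------------------------------------------------------

@dataclass
class ElementSpec:
    """Blueprint of one retrotransposon family."""

    family_id: str
    clade: str
    ltr_len: int = 250
    internal_len: int = 5600
    #: ("PBS", sequence) or ("CHS", chseq1, interval_bp)
    priming: tuple = ("CHS", "CTGATCAGT", 20)
    ppt: int = 12
    orf_motifs: list[str] | None = None
    gc_background: float = 0.5

    def validate(self) -> None:
        total = 2 * self.ltr_len + self.internal_len
        if not 100 <= self.ltr_len <= 1000:
            raise ValueError("ltr_len must lie in [100, 1000]")
        if not TOTAL_MIN <= total <= TOTAL_MAX:
            raise ValueError("total element length must lie in [3000, 11000]")
        kind = self.priming[0]
        if kind == "CHS":
            chseq1, interval = self.priming[1], self.priming[2]
            if len(chseq1) != 9:
                raise ValueError("CHSeq1 must be 9 bp")
            pal = "A" + chseq1
            if pal != revcomp(pal):
                raise ValueError("A + CHSeq1 must be a reverse-complement palindrome")
            if not CHS_INTERVAL_MIN <= interval <= CHS_INTERVAL_MAX:
                raise ValueError("CHS interval must lie in [12, 41]")
        elif kind != "PBS":
            raise ValueError(f"unknown priming kind {kind!r}")

    @property
    def total_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len


def galea_spec(family_id: str = "GalEa1", chseq1: str = "CTGATCAGT",
               interval: int = 20, **kw) -> ElementSpec:
    return ElementSpec(family_id, "GalEa", priming=("CHS", chseq1, interval), **kw)


def funco1_spec(family_id: str = "FunCo1a", **kw) -> ElementSpec:
    return ElementSpec(family_id, "FunCo1", priming=("PBS", PBS_FUNCO1), **kw)


def copia_spec(family_id: str = "Cop1", **kw) -> ElementSpec:
    return ElementSpec(family_id, "OtherCopia",
                       priming=("PBS", PBS_GALEA_METAZOAN), **kw)


def gypsy_decoy_spec(family_id: str = "Gyp1", **kw) -> ElementSpec:
    return ElementSpec(family_id, "GypsyDecoy",
                       priming=("PBS", PBS_GALEA_METAZOAN), **kw)


def make_ltr(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    core = "".join(rng.choice(BASES, size=length - 5, p=p))
    return "TGT" + core + "CA"


def make_element(spec: ElementSpec, seed: int) -> str:
    """Build the full element sequence: LTR + priming region + ORF + PPT + LTR.

    Deterministic in (spec, seed); two calls with the same arguments return
    the identical sequence, so family copies start out 100% identical.
    """
    spec.validate()
    rng = np.random.default_rng(_seed_from("element", spec.family_id, seed))
    gc = spec.gc_background
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def filler(n: int) -> str:
        return "".join(rng.choice(BASES, size=n, p=p)) if n > 0 else ""

    ltr = make_ltr(spec.ltr_len, gc, rng)
    if spec.priming[0] == "PBS":
        priming = spec.priming[1]
    else:
        chseq1, interval = spec.priming[1], spec.priming[2]
        priming = chseq1 + filler(interval) + chseq2_from_chseq1(chseq1)
    gap1, gap2, tail_min = 10, 5, 20
    ppt = "".join(rng.choice(np.array(list("AG")), size=spec.ppt))
    budget = spec.internal_len - len(priming) - gap1 - tail_min - len(ppt) - gap2
    prot_len = budget // 3 - 2
    protein = _gagpol_protein(spec, prot_len, rng)
    # re-draw synonymous codons until no antisense stop-free stretch reaches
    # ORF length, so intact elements carry exactly one large ORF
    for _ in range(30):
        orf = "ATG" + _encode(protein, rng) + "TAA"
        if not _has_antisense_orf(orf, 300):
            break
    tail = spec.internal_len - len(priming) - gap1 - len(orf) - len(ppt) - gap2
    internal = priming + filler(gap1) + orf + filler(tail) + ppt + filler(gap2)
    assert len(internal) == spec.internal_len
    return ltr + internal + ltr


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def mutation_rate_for_ltr_identity(target_percent: float) -> float:
    """Per-site substitution rate that leaves two independently mutated LTR
    copies at approximately the requested pairwise identity.

    Each site stays identical if neither copy mutated or both mutated to the
    same base: (1-p)^2 + p^2/3 + 2*p*(1-p)*0 ... two independent draws over
    3 alternatives give match probability (1-p)^2 + p^2/3.
    """
    t = target_percent / 100.0
    # solve (1-p)^2 + p^2/3 = t on [0, 0.75]
    lo, hi = 0.0, 0.75
    for _ in range(60):
        mid = (lo + hi) / 2
        if (1 - mid) ** 2 + mid ** 2 / 3 >= t:
            lo = mid
        else:
            hi = mid
    return lo


def degrade(element: str, mode: str, params: dict | None, seed: int) -> str:
    """Apply one degradation mode to an element sequence.

    mode: mutate(p_sub) | truncate(fraction, end) | solo_ltr(ltr_len) |
    nest(inner, site) | rip(target_at, p_ctot)
    """
    params = dict(params or {})
    rng = np.random.default_rng(_seed_from("degrade", mode, seed))
    seq = np.array(list(element))
    if mode == "mutate":
        p_sub = float(params.get("p_sub", 0.03))
        hits = np.nonzero(rng.random(len(seq)) < p_sub)[0]
        for i in hits:
            alt = [b for b in "ACGT" if b != seq[i]]
            seq[i] = alt[int(rng.integers(3))]
        return "".join(seq)
    if mode == "truncate":
        frac = float(params.get("fraction", 0.4))
        end = params.get("end") or ("5p" if rng.random() < 0.5 else "3p")
        cut = int(round(frac * len(element)))
        return element[cut:] if end == "5p" else element[:len(element) - cut]
    if mode == "solo_ltr":
        ltr_len = int(params["ltr_len"])
        return element[:ltr_len]
    if mode == "nest":
        inner = params["inner"]
        site = params.get("site")
        if site is None:
            lo, hi = int(0.3 * len(element)), int(0.7 * len(element))
            site = int(rng.integers(lo, hi))
        return element[:site] + inner + element[site:]
    if mode == "rip":
        target_at = float(params.get("target_at", 0.75))
        p = float(params.get("p_ctot", 0.3))
        for _ in range(100):
            at = np.isin(seq, list("AT")).mean()
            if at >= target_at:
                break
            cg = np.nonzero(np.isin(seq, list("CG")))[0]
            if len(cg) == 0:
                break
            hit = cg[rng.random(len(cg)) < p]
            for i in hit:
                seq[i] = "T" if seq[i] == "C" else "A"
        return "".join(seq)
    raise ValueError(f"unknown degradation mode {mode!r}")


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class CopyPlan:
    """How many copies of one family to implant, per degradation class."""

    spec: ElementSpec
    counts: dict = field(default_factory=lambda: {"intact": 3})
    p_sub: float = 0.03
    truncate_fraction: float = 0.4
    rip_target_at: float = 0.75


@dataclass
class SimConfig:
    seed: int
    plans: list[CopyPlan]
    n_contigs: int = 2
    contig_len: int = 300_000
    gc: float = 0.5
    max_retries: int = 500


TRUTH_COLUMNS = ["element_id", "contig", "start", "end", "strand", "family_id",
                 "clade", "degradation", "tsd", "ltr_identity_truth"]


def _pair_identity(seq: str, ltr_len: int) -> float:
    return ltr_identity(seq[:ltr_len], seq[-ltr_len:])


def simulate_dataset(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate contigs with implanted elements and the matching truth table.

    Returns (contig name -> sequence, truth DataFrame).  Fully deterministic
    under ``config.seed``: re-running yields byte-identical FASTA/TSV output.
    """
    rng = np.random.default_rng(config.seed)
    contigs = {f"contig_{i + 1}": make_background(
        config.contig_len, config.gc, _seed_from("bg", config.seed, i))
        for i in range(config.n_contigs)}

    # build insert jobs -----------------------------------------------------
    jobs = []  # (element_id, family, clade, degradation, seq, tsd?, ltr_id, inner)
    counter = 0
    for pi, plan in enumerate(config.plans):
        spec = plan.spec
        base = make_element(spec, config.seed)
        for mode in DEGRADATIONS:
            for c in range(int(plan.counts.get(mode, 0))):
                counter += 1
                eid = f"E{counter:04d}"
                inner_info = None
                if mode == "intact":
                    seq, tsd, ident = base, True, 100.0
                elif mode == "mutated":
                    seq = degrade(base, "mutate", {"p_sub": plan.p_sub},
                                  _seed_from(config.seed, eid))
                    tsd, ident = False, _pair_identity(seq, spec.ltr_len)
                elif mode == "truncated":
                    seq = degrade(base, "truncate",
                                  {"fraction": plan.truncate_fraction},
                                  _seed_from(config.seed, eid))
                    tsd, ident = False, float("nan")
                elif mode == "solo_ltr":
                    seq = degrade(base, "solo_ltr", {"ltr_len": spec.ltr_len},
                                  _seed_from(config.seed, eid))
                    tsd, ident = False, float("nan")
                elif mode == "ripped":
                    seq = degrade(base, "rip", {"target_at": plan.rip_target_at},
                                  _seed_from(config.seed, eid))
                    tsd, ident = False, _pair_identity(seq, spec.ltr_len)
                else:  # nested: host carries a copy of the next plan's family
                    donor_plan = config.plans[(pi + 1) % len(config.plans)]
                    inner_seq = make_element(donor_plan.spec, config.seed)
                    lo, hi = int(0.3 * len(base)), int(0.7 * len(base))
                    site = int(rng.integers(lo, hi))
                    seq = base[:site] + inner_seq + base[site:]
                    counter += 1
                    inner_info = (f"E{counter:04d}", donor_plan.spec, site,
                                  len(inner_seq))
                    tsd, ident = False, _pair_identity(seq, spec.ltr_len)
                jobs.append([eid, spec, mode, seq, tsd, ident, inner_info])

    # place jobs on contigs -------------------------------------------------
    names = list(contigs)
    placements = {n: [] for n in names}  # (bg_pos, job)
    margin = 50
    for job in jobs:
        placed = False
        for _ in range(config.max_retries):
            cname = names[int(rng.integers(len(names)))]
            pos = int(rng.integers(margin, config.contig_len - margin))
            if all(abs(pos - p) > 10 for p, _ in placements[cname]):
                placements[cname].append((pos, job))
                placed = True
                break
        if not placed:
            raise CapacityError("could not place implant after max_retries")

    records = []
    for cname in names:
        seq = contigs[cname]
        parts = []
        cursor = 0
        offset = 0
        for pos, job in sorted(placements[cname], key=lambda x: x[0]):
            eid, spec, mode, eseq, tsd, ident, inner_info = job
            parts.append(seq[cursor:pos])
            start = pos + offset
            tsd_seq = seq[pos - 5:pos] if tsd else ""
            parts.append(eseq)
            if tsd:
                parts.append(tsd_seq)
            end = start + len(eseq)
            deg = mode if inner_info is None else f"nested({inner_info[0]})"
            records.append([eid, cname, start, end, "+", spec.family_id,
                            spec.clade, deg, tsd_seq or "none",
                            round(ident, 2) if ident == ident else ""])
            if inner_info is not None:
                in_id, in_spec, site, in_len = inner_info
                records.append([in_id, cname, start + site, start + site + in_len,
                                "+", in_spec.family_id, in_spec.clade,
                                "intact_nested", "none", 100.0])
            offset += len(eseq) + (5 if tsd else 0)
            cursor = pos
        parts.append(seq[cursor:])
        contigs[cname] = "".join(parts)

    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["contig", "start"], kind="mergesort",
                              ignore_index=True)
    return contigs, truth
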