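"""Sequence constants shared by the simulator, the classifier and the annotator.

DNA motifs
----------
Fungal GalEa elements carry no primer binding site (PBS); minus-strand priming
is instead attributed to the Conserved Hairpin Site (CHS): a 9 bp CHSeq1 that
is palindromic together with the terminal A of the 5' LTR, followed 12-41 bp
downstream by CHSeq2, the reverse complement of CHSeq1 except for a single
conserved A/A mismatch (CHSeq1 position 7 against CHSeq2 position 3, 1-based).

Protein motifs
--------------
The gag-pol polyprotein of Copia elements carries, in order: a gag zinc
finger, the protease DTG(C/A) signature, the integrase HHCC and DD(35)E
signatures, the reverse-transcriptase KSRLVI and QTDD boxes, and an RNaseH
that opens on CQPEA and closes on ADxxTK.  Fungal GalEa motifs differ from
their metazoan counterparts (KARLVA, YVDD, TRPDI, and a C(2)C(4)H(4)C zinc
finger), which is why both variants are scanned.
"""

from __future__ import annotations

import re

COMPLEMENT = str.maketrans("ACGTRYKMacgtrykm", "TGCAYRMKtgcayrmk")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC R/Y/K/M supported)."""
    return seq.translate(COMPLEMENT)[::-1]


# --- primer binding sites -------------------------------------------------
# Metazoan GalEa PBS: complementary to the 3' end of the D. melanogaster
# tRNA-Met; FunCo1 PBS: complementary to an internal region of tRNA-Lys.
PBS_GALEA_METAZOAN = "TGGTAGCAGAGC"
PBS_FUNCO1 = "ATTAAGAGTCT"

#: default primer motif table used by :func:`copiascan.annotate.find_pbs`
DEFAULT_PRIMER_DB: list[tuple[str, str]] = [
    ("tRNA-Met-3p", PBS_GALEA_METAZOAN),
    ("tRNA-Lys-int", PBS_FUNCO1),
]

# --- conserved hairpin site -----------------------------------------------
#: the two canonical CHSeq1 motifs (85% of fungal GalEa families)
CHSEQ1_CANONICAL = ("CTGATCAGT", "CTAATTAGT")
CHS_LEN = 9
CHS_INTERVAL_MIN = 12
CHS_INTERVAL_MAX = 41
#: 1-based stem positions of the conserved A/A mismatch
CHS_MISMATCH_POS1 = 7
CHS_MISMATCH_POS2 = 3


def chseq2_from_chseq1(chseq1: str) -> str:
    """CHSeq2 implied by a CHSeq1: reverse complement with an A at stem
    position 3 (producing the conserved A/A mismatch against CHSeq1
    position 7)."""
    rc = list(revcomp(chseq1))
    rc[CHS_MISMATCH_POS2 - 1] = "A"
    return "".join(rc)


# --- protein motifs -------------------------------------------------------
# (name, regex, canonical instance implanted by the simulator)
# canonical instances keep D and E confined to the DDE/DTG/QTDD/ADxxTK/CQPEA
# signatures themselves so the spaced integrase-DDE pattern cannot stitch a
# spurious match across neighbouring motifs
FUNGAL_MOTIFS: list[tuple[str, str, str]] = [
    ("gag_zf_CCCH", r"C.{2}C.{4}C.{4}H", "CAKCRQSGCWARNH"),
    ("protease_DTG", r"DTG[CA]", "DTGC"),
    ("integrase_HHCC", r"H.{3,7}H.{20,32}C.{2}C",
     "HQWSHALQRGVNSTYIPMFKWQALNRCGKC"),
    ("integrase_DDE", r"D.{5,50}?D.{32,38}E",
     "DPLGQVKRWATSMND" + "GVNSTYIPMFKWQALRGVNSTYIPMFKWQALRGVN" + "E"),
    ("rt_KSRLVI", r"KSRLVI", "KSRLVI"),
    ("rt_QTDD", r"QTDD", "QTDD"),
    ("rnaseh_CQPEA", r"CQPEA", "CQPEA"),
    ("rnaseh_ADxxTK", r"AD..TK", "ADGMTK"),
]

METAZOAN_MOTIFS: list[tuple[str, str, str]] = [
    ("gag_zf_CCHC", r"C.{2}C.{4}H.{4}C", "CAKCRQSGHWARNC"),
    ("rt_KARLVA", r"KARLVA", "KARLVA"),
    ("rt_YVDD", r"YVDD", "YVDD"),
    ("rnaseh_TRPDI", r"TRPDI", "TRPDI"),
]

#: canonical gag-PR-INT-RT-RNaseH ordering used to check motif consistency
MOTIF_ORDER = [name for name, _, _ in FUNGAL_MOTIFS]

_COMPILED = {name: re.compile(rx) for name, rx, _ in FUNGAL_MOTIFS + METAZOAN_MOTIFS}


def motif_regex(name: str) -> re.Pattern:
    return _COMPILED[name]
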