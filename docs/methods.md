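# Methods

This note documents the models and procedures implemented in `copiascan`,
the parameters that matter, what the synthetic data do and do not emulate,
and the numerical choices made where the design was genuinely open.

## The element model

A Copia LTR retrotransposon is modelled as

```
5'LTR — priming region — gag-pol ORF — filler — PPT — 3'LTR
```

* **LTRs**: identical direct repeats of 100–1000 bp (default 250 bp),
  starting `TGT` and ending `CA`. Intact insertions are flanked by a 5 bp
  target-site duplication, generated by duplicating the 5 bp immediately
  left of the insertion point.
* **Priming region**, immediately after the 5′ LTR. Either a PBS motif
  (FunCo1: `ATTAAGAGTCT`; metazoan-style GalEa: `TGGTAGCAGAGC`) or, for
  fungal GalEa elements, the CHS: CHSeq1 (9 bp, `A`+CHSeq1 a perfect
  reverse-complement palindrome), a spacer of 12–41 bp, then CHSeq2 —
  the reverse complement of CHSeq1 with an `A` substituted at stem
  position 3, producing the conserved A/A mismatch against CHSeq1
  position 7. The two canonical CHSeq1 motifs are `CTGATCAGT` and
  `CTAATTAGT`.
* **ORF**: a single long open reading frame whose polyprotein carries, in
  order: a C(2)C(4)C(4)H gag zinc finger, the protease DTG(C/A) box, the
  integrase HHCC and DD(35)E signatures, the RT KSRLVI and QTDD boxes, and
  an RNaseH opening on CQPEA and terminating on ADxxTK. Clade identity
  lives in the RT/RNaseH domain: each clade has a deterministic consensus
  domain protein; families diverge from it at 5%, copies further by their
  degradation class. Synonymous codons are drawn at random, re-drawn (up
  to 30 times) if an antisense stop-free stretch of ≥ 300 codons arises,
  so intact elements carry exactly one large ORF.
* **PPT**: a purine run (default 12 bp) just upstream of the 3′ LTR.

Degradation classes: `mutate` (i.i.d. substitutions; the two LTRs diverge
independently, which is what drives LTR-pair identity below the detection
threshold), `truncate` (5′ or 3′), `solo_ltr` (recombination remnant),
`nest` (another element inserted mid-element), and `rip` — strand-symmetric
C→T / G→A transitions applied in passes until an AT-content target
(default 0.75, matching the convention that "ripped" sequences exceed 70%
AT) is reached. RIP context dependence (CpA bias) is deliberately not
modelled; only the rate/target is exposed.

The per-site substitution rate that yields a wanted expected LTR-pair
identity *t* solves `(1−p)² + p²/3 = t` (both copies mutate independently,
uniform choice among the three alternative bases).

## What the simulator does not emulate

No gene content, no chromosome structure, no empirical base-composition or
codon-usage model, no insertion-age structure, no context-dependent RIP.
Inter-clade domain proteins are independent random sequences sharing only
the conserved motifs, so clade separation is cleaner than in real data:
passing recovery tests demonstrates correctness of the machinery under the
stated noise levels, not expected field accuracy on borderline real clades.

## Detection

Exact 12-mer seeds shared by two positions of the same contig at an
admissible distance (3000–11000 bp, start-to-start) are chained along
diagonals (gap ≤ 150 bp), extended outward by an X-drop walk (match +1,
mismatch −2, drop 12), and verified by global-alignment identity
(edlib; identity = matches / alignment columns, the stricter convention).
Same-diagonal chaining assumes substitution-dominated LTR divergence — the
regime the simulator produces; indel-rich LTR pairs would need banded
diagonals. Only the forward strand is scanned (direct repeats are
strand-symmetric); element strand is assigned later from ORF orientation.

Overlap resolution keeps the highest-identity candidate; ties prefer the
*compact* candidate, then the leftmost. The compact preference is load
bearing: when two identical copies of one family sit less than 11 kb
apart, the 3′ LTR of the first and the 5′ LTR of the second form a valid
in-window repeat pair, and preferring long candidates would let this
artifactual join displace both genuine elements. Such joins, when kept,
carry no internal ORF and are discarded at classification — the same
safety net that screens out other artifactual repeat structures.

Boundary refinement shifts both LTR spans by ≤ 15 bp onto the nearest
position where both copies start `TG(T)` and end `CA`; candidates with no
such position in range are kept unchanged and flagged. Recovery tests use
a ±10 bp tolerance, since refinement is motif-guided rather than exact.

## Classification

The reference panel is synthetic and bundled: six diverged copies (8%
substitutions, motifs protected) of each clade consensus domain for GalEa,
FunCo1 and OtherCopia, plus Gypsy and BEL/Pao decoy groups. A clade is
callable only with ≥ 5 panel entries, as the five-best-hits rule requires.

Local alignments use BLOSUM62 with gap open 11 / extend 1. Significance is
a Karlin–Altschul-style surrogate, `-log10(K·m·n·exp(−λS))` with λ = 0.267,
K = 0.041 (gapped BLOSUM62 defaults); the clade rule's gap condition is
"> 10 log10 units", the surrogate analogue of an E-value difference of
1e-10. The surrogate preserves ordering and gap semantics but is not a
database-size-calibrated E-value; the gap is configurable.

RIP/frameshift tolerance: the element is translated in 60-codon windows;
a window switches frame only when another frame beats the current one by a
margin of 8 alignment-score points (keeping the frame continuous through
gag, which the RT/RNaseH panel cannot score), and inherited-frame windows
with > 10% stops are emitted as X-runs. The stitched translation is used
only when no clean frame reaches 3× the domain score floor (default floor
50 bits-equivalent).

## Families

Pass 1: single-linkage at ≥ 70% identity with ≥ 50% *mutual* coverage.
Pass 2: leftovers join the best cluster reaching ≥ 90% identity over ≥ 10%
of the leftover's length (ties: identity, then cluster size, then cluster
index). Coverage is deliberately direction-dependent: mutual in pass 1
(a 30% fragment must not full-length-cluster — otherwise the rescue pass
could never fire), query-side in pass 2 (that is exactly what lets
fragments rejoin). Identity uses semi-global alignment of the shorter
sequence inside the longer (edlib), matches over columns.

Curation: MAFFT alignment; any internal run of > 20 alignment columns
occupied by exactly one member is excised as a private insertion (nested
TEs, microsatellites). Terminal runs are kept — they reflect truncation of
the other copies. Because excised columns are gap-only in all other
members, the remaining columns stay a valid alignment without re-aligning.

Validation: members below 80% curated identity to every other member are
expelled (the automated stand-in for manual chimera filtering); clusters
are split by re-clustering at 80% and merged when consensi exceed 80%;
the 80% family criterion is applied as *minimum* pairwise identity, the
stricter of the two readings, configurable. Consensus: column majority,
alphabetical ties, columns > 50% gapped dropped.

Orphan rescue assigns a clade (never a family) when the orphan's
RIP-tolerant translation aligns to a family domain protein over ≥ 300
columns with ≥ 50 log10 surrogate units. The 300-residue floor is the
published convention; the significance floor is rescaled to this package's
surrogate because an exact self-match of a ~340 aa domain tops out near
190 log10 units, so thresholds meaningful for full-length multi-kb
protein databases would reject every degraded orphan the operation exists
to recover.

## Masking and abundance

The masker seeds 12-mers of each family consensus (both strands) against
the genome, chains them along diagonals (±400 bp tolerance, so a solo LTR
correctly yields two consensus fragments rather than one unalignable
full-length span), aligns each consensus fragment semi-globally in a
padded genome window, and keeps hits with divergence ≤ 0.20
(edit operations / columns; no CpG or Kimura correction) and length
≥ 50 bp. Same-family hits ≤ 100 bp apart merge (reconnecting copies split
by short nested insertions); loci claimed by several families keep the
best-scoring label, mirroring best-match masking.

Copy counts per clade use merged hits ≥ 3 kb — 3 kb being the smallest
element the two-LTR detector can report, which makes the two copy-number
estimators size-comparable. Genomic proportions use the per-clade span
union of *all* hits with no size floor. Ratios are rounded half-up to two
decimals for reporting, with the sentinel `"ne"` (not estimated) when the
denominator is zero. The estimator comparison reports pairwise Pearson
correlations over genomes plus per-genome max deviations, flagging
deviations > 0.15 — the signature of a genome rich in 1–3 kb deleted
derivatives that inflate mask-based ratios relative to detector counts.

## Phylogeny

Pairwise distances are maximum-likelihood under the JTT empirical model
(exchangeabilities and frequencies of Jones–Taylor–Thornton 1992, embedded
in the source) with a continuous gamma distribution of rates; the
gamma-averaged transition matrix has the closed form
`P(t) = A·diag((1−λₖt/α)^(−α))·B` over the rate-matrix eigensystem, so no
per-category matrix exponentials are needed. Gamma shape defaults to 1.0
(a shape value is a config choice; model selection is out of scope) and
columns gapped in either member of a pair are excluded (pairwise
deletion). Pairs with no shared columns raise an error naming the pair;
saturated pairs are capped at 10 substitutions/site with a warning.

NJ follows Saitou–Nei with Studier–Keppler Q-values; negative branch
lengths are clamped to zero and the deficit moved to the sister branch,
preserving path lengths. Bootstrap resamples alignment columns with
replacement (seeded, deterministic) and scores unrooted splits; supports
are invariant to leaf order. Clades are maximal rooted subtrees (after
rooting on the designated Gypsy outgroup) with support strictly above 70
spanning ≥ 2 species; single-species subtrees are never called, and a
qualifying subtree inside a called clade is suppressed (maximality — the
natural resolution when a supported clade contains a smaller supported
clade that also meets the species rule).

## Annotation details

* CHSeq1 search window: 60 bp after the 5′ LTR (slack for boundary error);
  candidate CHSeq1 may be at most a 1-substitution derivative of a perfect
  palindrome by default (observed derivatives vary mostly at the third
  and/or sixth nucleotide; the tolerance is a parameter). A single stem
  mismatch is accepted only when it is the A/A pair — this is what holds
  the false-call rate at zero on PBS-bearing elements.
* The extended CHS (shared post-LTR block of 33–62 bp across ≥ 2 families
  of one species, ≥ 90% identity) must additionally end on a conserved
  column, otherwise the 90% allowance pads it with unconserved tail.
* PBS matching allows 1 mismatch within 30 bp of the LTR (assembly-error
  tolerance; exactness configurable). PPT: longest A/G run ≥ 8 bp within
  50 bp upstream of the 3′ LTR. ORFs: maximal stop-to-stop stretches
  ≥ 300 codons, both strands; element strand is the longest ORF's strand.
* DD(35)E is matched as D-x(5–50 lazily)-D-x(32–38)-E, i.e. a spacing
  tolerance of ±3 around the canonical 35. A larger hairpin with a bulge
  at the LTR–CHS junction is reported in part of the real elements but is
  under-specified for implementation and not modelled.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at desk scale:
genomes of 0.12–0.5 Mb, families of 3–10 copies, bootstrap with 25–100
replicates on ≤ 12 sequences — sizes at which every stage's behaviour is
fully exercised and ground truth is exactly known. All randomness flows
from explicit seeds (numpy `default_rng`; sub-seeds derived by CRC32 of
labelled strings, < 2³¹), and identical configurations reproduce
byte-identical FASTA/TSV artifacts and identical trees.

## Known limitations

* The detector's same-diagonal seed chaining assumes substitution-driven
  LTR divergence; old indel-rich elements would be under-detected.
* Identity conventions (global, gap-counting; semi-global for clustering)
  are stricter than some tool conventions; thresholds are calibrated to
  the package's own definitions.
* The E-value surrogate is not database-size calibrated; gap thresholds
  transfer in spirit, not numerically, to real BLAST screens.
* The bundled panel is synthetic; applying the classifier to real genomes
  requires swapping in a curated RT/RNaseH panel FASTA
  (`superfamily=… clade=…` header tags).
* Thermodynamic folding of the CHS hairpin is out of scope; the detector
  scores complementarity only.
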