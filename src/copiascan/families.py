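"""Two-pass clustering of element copies into families, copy curation,
the 80% family-identity rule, and a-posteriori orphan assignment.

Pass 1 single-links copies at >= 70% identity over >= 50% coverage; pass 2
rescues leftovers into the best existing cluster at >= 90% identity over
>= 10% of the leftover's length (recovering truncated or insertion-riddled
copies).  Copies are then aligned (MAFFT), copy-specific insertions longer
than 20 alignment columns are excised, and clusters are merged/split so
every family satisfies the 80% DNA-identity rule used to define
transposable-element families.  A single GalEa copy in a genome counts as a
family of its own.

Pairwise identity/coverage uses BLAST-like semantics: the shorter sequence
is the query, aligned semi-globally inside the longer one, and identity is
matches over alignment columns.  Coverage is direction-dependent by design:
pass 1 requires both sequences to be covered (a 30% fragment must not
full-length-cluster), while pass 2 measures coverage of the leftover only,
which is precisely what lets fragments rejoin their family.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .align import dna_identity_coverage, local_protein_alignment, neg_log10_evalue

PASS1_IDENTITY, PASS1_COVERAGE = 70.0, 50.0
PASS2_IDENTITY, PASS2_COVERAGE = 90.0, 10.0
FAMILY_IDENTITY = 80.0
CURATION_MAX_INSERTION = 20
ORPHAN_MIN_AA = 300
# the significance floor for orphan rescue, in -log10 units of the local
# alignment surrogate; an exact full-length match of a ~340 aa domain tops
# out near 190, so the floor admits strong partial-domain matches only
ORPHAN_MIN_NEGLOG10 = 50.0


@dataclass
class Cluster:
    members: list[str]
    pass_of_origin: dict = field(default_factory=dict)   # member -> 1 | 2
    identity: dict = field(default_factory=dict)         # member -> percent
    coverage: dict = field(default_factory=dict)         # member -> fraction


@dataclass
class Family:
    family_id: str
    members: list[str]
    alignment: dict                # member -> aligned sequence (with gaps)
    consensus: str
    clade: str
    is_orphan_singleton: bool = False


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_pass1(copies: dict[str, str], identity: float = PASS1_IDENTITY,
                  coverage: float = PASS1_COVERAGE
                  ) -> tuple[list[Cluster], list[str]]:
    """Single-linkage clusters over the (identity, coverage) pair graph.

    Returns (clusters with >= 2 members, leftover singleton ids); both in
    deterministic id order, so the partition is invariant to input order.
    """
    if not copies:
        raise ValueError("need at least one copy")
    ids = sorted(copies)
    uf = _UnionFind(ids)
    pair_stats = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident, cov = dna_identity_coverage(copies[a], copies[b],
                                               coverage_of="both")
            pair_stats[(a, b)] = (ident, cov)
            if ident >= identity and 100.0 * cov >= coverage:
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(uf.find(i), []).append(i)
    clusters, leftovers = [], []
    for root in sorted(groups):
        members = sorted(groups[root])
        if len(members) == 1:
            leftovers.append(members[0])
            continue
        cl = Cluster(members)
        for m in members:
            best = max((pair_stats.get(tuple(sorted((m, o))), (0.0, 0.0))
                        for o in members if o != m))
            cl.pass_of_origin[m] = 1
            cl.identity[m], cl.coverage[m] = round(best[0], 2), round(best[1], 3)
        clusters.append(cl)
    return clusters, leftovers


def rescue_pass2(clusters: list[Cluster], leftovers: list[str],
                 copies: dict[str, str], identity: float = PASS2_IDENTITY,
                 coverage: float = PASS2_COVERAGE
                 ) -> tuple[list[Cluster], list[str]]:
    """Attach leftovers to the best cluster reaching >= ``identity`` over
    >= ``coverage`` percent of the leftover's length; the rest are orphans.

    Best-hit semantics (not linkage); ties broken by identity, then cluster
    size, then cluster index.
    """
    orphans = []
    for lid in sorted(leftovers):
        best = None  # (identity, size, -index)
        for ci, cl in enumerate(clusters):
            for m in cl.members:
                ident, cov = dna_identity_coverage(copies[lid], copies[m])
                if ident >= identity and 100.0 * cov >= coverage:
                    key = (ident, len(cl.members), -ci)
                    if best is None or key > best[0]:
                        best = (key, ci, ident, cov)
        if best is None:
            orphans.append(lid)
        else:
            _, ci, ident, cov = best
            cl = clusters[ci]
            cl.members = sorted(cl.members + [lid])
            cl.pass_of_origin[lid] = 2
            cl.identity[lid], cl.coverage[lid] = round(ident, 2), round(cov, 3)
    return clusters, orphans


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def _mafft(seqs: dict[str, str]) -> dict[str, str]:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        with open(fa, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        res = subprocess.run(["mafft", "--quiet", "--retree", "2", str(fa)],
                             capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.upper()
    return out


def curate_copies(cluster_seqs: dict[str, str]) -> dict[str, str]:
    """Align cluster members and excise copy-specific insertions > 20 bp.

    A run of more than 20 consecutive alignment columns occupied by exactly
    one member (all others gapped) is treated as a private insertion — a
    nested TE, microsatellite expansion, etc. — and removed from that member.
    Terminal runs are kept: they reflect truncation of the *other* copies,
    not an insertion.  Because the excised columns carry gaps in every other
    member, dropping them whole keeps the remaining alignment valid, so no
    re-alignment is needed.
    """
    if len(cluster_seqs) < 2:
        raise ValueError("curation needs at least two members")
    aln = _mafft(cluster_seqs)
    names = list(aln)
    ncol = len(next(iter(aln.values())))
    cols = {n: aln[n] for n in names}
    # find private runs per member
    occupant = []
    for c in range(ncol):
        occ = [n for n in names if cols[n][c] != "-"]
        occupant.append(occ[0] if len(occ) == 1 else None)
    drop: set[int] = set()
    c = 0
    while c < ncol:
        who = occupant[c]
        if who is None:
            c += 1
            continue
        start = c
        while c < ncol and occupant[c] == who:
            c += 1
        run = range(start, c)
        internal = start > 0 and c < ncol and any(
            occupant[i] is None for i in range(0, start)) and any(
            occupant[i] is None for i in range(c, ncol))
        if len(run) > CURATION_MAX_INSERTION and internal:
            drop.update(run)
    if not drop:
        return {n: cols[n] for n in names}
    keep_cols = [c for c in range(ncol) if c not in drop]
    return {n: "".join(cols[n][c] for c in keep_cols) for n in names}


# ---------------------------------------------------------------------------
# family validation
# ---------------------------------------------------------------------------

def build_consensus(alignment: dict[str, str]) -> str:
    """Column-wise majority consensus; ties broken alphabetically; columns
    with more than 50% gaps dropped."""
    names = list(alignment)
    ncol = len(next(iter(alignment.values())))
    out = []
    for c in range(ncol):
        col = [alignment[n][c] for n in names]
        gaps = col.count("-")
        if gaps * 2 > len(col):
            continue
        residues = [b for b in col if b != "-"]
        counts: dict[str, int] = {}
        for b in residues:
            counts[b] = counts.get(b, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def _min_pair_identity(seqs: dict[str, str]) -> float:
    ids = sorted(seqs)
    worst = 100.0
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident, _ = dna_identity_coverage(seqs[a], seqs[b])
            worst = min(worst, ident)
    return worst


def validate_families(clusters: list[Cluster], copies: dict[str, str],
                      clades: dict[str, str],
                      singletons: list[str] = (),
                      threshold: float = FAMILY_IDENTITY
                      ) -> tuple[list[Family], list[str]]:
    """Curate clusters and enforce the 80% family rule.

    * members whose curated identity to every other member stays below the
      threshold are expelled as orphans (automated chimera filter);
    * clusters whose internal pairs still fall below the threshold are split
      by re-clustering at the threshold;
    * clusters whose consensi share more than the threshold identity are
      merged;
    * every singleton GalEa copy becomes a family of its own.

    Returns (families, new orphan ids).
    """
    working: list[list[str]] = [list(cl.members) for cl in clusters]
    orphans: list[str] = []

    _cache: dict[tuple, dict] = {}

    def _curate(members: list[str]) -> dict[str, str]:
        key = tuple(sorted(members))
        if key not in _cache:
            _cache[key] = curate_copies({m: copies[m] for m in members})
        return _cache[key]

    # curate, expel chimeric members, split
    final_groups: list[list[str]] = []
    for members in working:
        aln = _curate(members)
        degapped = {m: aln[m].replace("-", "") for m in members}
        keep = []
        for m in members:
            best = max((dna_identity_coverage(degapped[m], degapped[o])[0]
                        for o in members if o != m), default=0.0)
            (keep if best >= threshold else orphans).append(m)
        if len(keep) < 2:
            orphans.extend(keep)
            continue
        # split at the threshold if needed
        uf = _UnionFind(keep)
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                if dna_identity_coverage(degapped[a], degapped[b])[0] >= threshold:
                    uf.union(a, b)
        comps: dict[str, list[str]] = {}
        for m in keep:
            comps.setdefault(uf.find(m), []).append(m)
        for root in sorted(comps):
            group = sorted(comps[root])
            if len(group) == 1:
                orphans.append(group[0])
            else:
                final_groups.append(group)

    # build curated alignments + consensi, then merge above-threshold pairs
    curated: list[dict[str, str]] = []
    consensi: list[str] = []
    for group in final_groups:
        aln = _curate(group)
        curated.append(aln)
        consensi.append(build_consensus(aln))
    uf = _UnionFind(range(len(final_groups)))
    for i in range(len(final_groups)):
        for j in range(i + 1, len(final_groups)):
            ident, _ = dna_identity_coverage(consensi[i], consensi[j])
            if ident > threshold:
                uf.union(i, j)
    merged: dict[int, list[str]] = {}
    for i, group in enumerate(final_groups):
        merged.setdefault(uf.find(i), []).extend(group)

    families: list[Family] = []
    for root in sorted(merged):
        members = sorted(merged[root])
        aln = _curate(members)
        cons = build_consensus(aln)
        clade = _majority_clade(members, clades)
        families.append(Family("", members, aln, cons, clade))

    # singleton GalEa rule
    for sid in sorted(singletons):
        if clades.get(sid) == "GalEa":
            families.append(Family("", [sid], {sid: copies[sid]},
                                   copies[sid], "GalEa",
                                   is_orphan_singleton=True))
        else:
            orphans.append(sid)

    families.sort(key=lambda f: f.members[0])
    for i, fam in enumerate(families):
        fam.family_id = f"F{i + 1:03d}"
    return families, sorted(orphans)


def _majority_clade(members: list[str], clades: dict[str, str]) -> str:
    counts: dict[str, int] = {}
    for m in members:
        c = clades.get(m, "unassigned")
        counts[c] = counts.get(c, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


# ---------------------------------------------------------------------------
# orphan rescue
# ---------------------------------------------------------------------------

def assign_orphans(orphans: dict[str, str],
                   family_protein_db: dict[str, tuple[str, str]],
                   translator,
                   min_aa: int = ORPHAN_MIN_AA,
                   min_score: float = ORPHAN_MIN_NEGLOG10) -> dict[str, str]:
    """A-posteriori clade assignment of orphan copies.

    ``family_protein_db`` maps family id -> (clade, domain protein);
    ``translator`` maps orphan DNA -> protein (typically the frameshift- and
    RIP-tolerant translator).  An orphan is assigned to a *clade* (never a
    family) when its translation aligns to a family protein over at least
    ``min_aa`` columns with a significance surrogate above ``min_score``
    -log10 units; everything else stays "unassigned" and is excluded from
    diversity counts.
    """
    out = {}
    for oid in sorted(orphans):
        prot = translator(orphans[oid])
        best = None  # (neglog, clade)
        for fid in sorted(family_protein_db):
            clade, ref = family_protein_db[fid]
            aln = local_protein_alignment(prot, ref)
            if aln is None:
                continue
            score, _, _, _, _, ncols = aln
            if ncols < min_aa:
                continue
            neglog = neg_log10_evalue(score, len(prot), len(ref))
            if neglog >= min_score and (best is None or neglog > best[0]):
                best = (neglog, clade)
        out[oid] = best[1] if best else "unassigned"
    return out
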