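"""RT-domain distance matrix, neighbor-joining tree, bootstrap support and
the two-criterion clade rule.

Pairwise protein distances are maximum-likelihood estimates under the JTT
empirical substitution model (Jones-Taylor-Thornton 1992) with a continuous
gamma distribution of rates across sites; alignment columns gapped in
either member of a pair are excluded (pairwise deletion).  Trees are built
with standard neighbor joining; clade support comes from non-parametric
bootstrapping of alignment columns (100 replicates by default).  A clade is
called when (i) it holds sequences from at least two species and (ii) its
bootstrap support is strictly higher than 70.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# JTT exchangeabilities (Jones, Taylor & Thornton 1992), upper triangle
# row-wise in AA_ORDER, and the model's equilibrium frequencies.
_JTT_EXCHANGE = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
_JTT_FREQS = np.array([
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846,
    0.01980298020, 0.04075195925, 0.06182993817, 0.07315192685,
    0.02294397706, 0.05376094624, 0.09190390810, 0.05867594132,
    0.02382597617, 0.04012595987, 0.05090094910, 0.06876493124,
    0.05856494144, 0.01426098574, 0.03210196790, 0.06600493400,
])

MAX_DISTANCE = 10.0


def _jtt_eigen():
    """Eigendecomposition of the normalized JTT rate matrix.

    Returns (eigenvalues, A, B) such that P(t) = A @ diag(f(lam, t)) @ B.
    """
    s = np.zeros((20, 20))
    for (i, j), x in zip(itertools.combinations(range(20), 2), _JTT_EXCHANGE):
        s[i, j] = s[j, i] = x
    pi = _JTT_FREQS
    r = s * pi[None, :]
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(r, -r.sum(axis=1))
    r /= -(pi * np.diag(r)).sum()          # mean rate 1 substitution/site
    d_half = np.sqrt(pi)
    sym = (r * d_half[:, None]) / d_half[None, :]
    lam, v = np.linalg.eigh((sym + sym.T) / 2.0)
    a = v / d_half[:, None]
    b = v.T * d_half[None, :]
    return lam, a, b


_LAM, _A, _B = _jtt_eigen()


def _transition_matrix(t: float, gamma_shape: float | None) -> np.ndarray:
    """Expected transition matrix at distance ``t``; with a gamma rate
    distribution the eigenvalue term exp(lam*t) becomes the closed-form
    gamma average (1 - lam*t/alpha)^(-alpha)."""
    if gamma_shape is None:
        f = np.exp(_LAM * t)
    else:
        f = np.power(1.0 - _LAM * t / gamma_shape, -gamma_shape)
    p = (_A * f[None, :]) @ _B
    return np.clip(p, 1e-12, None)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    deletion: str = "pairwise"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("entries must be finite and non-negative")
        self.matrix = m


def _pair_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """20x20 substitution count matrix over columns ungapped in both."""
    ok = (x >= 0) & (y >= 0)
    codes = x[ok] * 20 + y[ok]
    return np.bincount(codes, minlength=400).reshape(20, 20)


def _ml_distance(counts: np.ndarray, gamma_shape: float | None,
                 max_distance: float = MAX_DISTANCE) -> float:
    n = counts.sum()
    if n == 0:
        raise ValueError("no shared ungapped columns")
    off = n - np.trace(counts)
    if off == 0:
        return 0.0

    def nll(t):
        return -(counts * np.log(_transition_matrix(t, gamma_shape))).sum()

    res = minimize_scalar(nll, bounds=(1e-6, max_distance), method="bounded",
                          options={"xatol": 1e-8})
    t = float(res.x)
    if t > 0.995 * max_distance:
        warnings.warn("saturated pair capped at max distance")
        return max_distance
    return t


def encode_alignment(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(msa)
    ncol = len(next(iter(msa.values())))
    if any(len(msa[l]) != ncol for l in labels):
        raise ValueError("alignment rows differ in length")
    arr = np.full((len(labels), ncol), -1, dtype=np.int16)
    for r, l in enumerate(labels):
        for c, a in enumerate(msa[l].upper()):
            arr[r, c] = _AA_INDEX.get(a, -1)
    return labels, arr


def protein_distance(msa: dict[str, str], model: str = "JTT",
                     gamma_shape: float | None = 1.0,
                     max_distance: float = MAX_DISTANCE) -> DistanceMatrix:
    """Pairwise ML distances under JTT(+gamma) with pairwise deletion.

    ``gamma_shape`` of None disables rate variation.  A pair with no shared
    ungapped columns raises an error naming the pair; saturated pairs are
    capped at ``max_distance`` with a warning.
    """
    if model.upper() != "JTT":
        raise ValueError("only the JTT model is available")
    if len(msa) < 3:
        raise ValueError("need at least three sequences")
    labels, arr = encode_alignment(msa)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pair_counts(arr[i], arr[j])
            if counts.sum() == 0:
                raise ValueError(
                    f"no shared columns between {labels[i]} and {labels[j]}")
            m[i, j] = m[j, i] = _ml_distance(counts, gamma_shape, max_distance)
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def newick(self, _top: bool = True) -> str:
        if self.is_leaf:
            s = f"{self.name}:{self.length:.6f}"
        else:
            inner = ",".join(c.newick(_top=False) for c in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            s = f"({inner}){label}:{self.length:.6f}"
        return s + ";" if _top else s

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


def nj_tree(dist: DistanceMatrix) -> Node:
    """Standard NJ agglomeration (Saitou & Nei 1987).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the pair's path length.  Returns an
    unrooted tree represented with a trifurcating (or, for 3 taxa, single
    internal) root node.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least three taxa")
    d = dist.matrix.astype(float).copy()
    nodes = [Node(name=l) for l in labels]
    active = list(range(n))
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def get(i, j):
        return 0.0 if i == j else dm[(min(i, j), max(i, j))]

    while len(active) > 3:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            q = (len(active) - 2) * get(i, j) - r[i] - r[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, i, j)
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent.children = [ni, nj]
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dm[(min(k, next_id), max(k, next_id))] = \
                0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    root = Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return root


def bipartitions(tree: Node) -> set[frozenset]:
    """Non-trivial unrooted splits, each represented by the leaf-name side
    not containing the alphabetically first leaf."""
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    splits = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(msa: dict[str, str], n_replicates: int = 100,
                      seed: int = 0, gamma_shape: float | None = 1.0,
                      max_distance: float = MAX_DISTANCE
                      ) -> tuple[Node, dict[frozenset, float]]:
    """NJ tree plus bootstrap support per internal split.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate NJ trees containing each split of the full-data
    tree.  Deterministic under ``seed``; supports are attached to the tree's
    internal nodes.
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    labels, arr = encode_alignment(msa)
    base = nj_tree(protein_distance(msa, gamma_shape=gamma_shape,
                                    max_distance=max_distance))
    base_splits = bipartitions(base)
    hits = {s: 0 for s in base_splits}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    n = len(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            cols = rng.integers(0, ncol, size=ncol)
            sub = arr[:, cols]
            m = np.zeros((n, n))
            try:
                for i in range(n):
                    for j in range(i + 1, n):
                        counts = _pair_counts(sub[i], sub[j])
                        if counts.sum() == 0:
                            raise ValueError("empty pair in replicate")
                        m[i, j] = m[j, i] = _ml_distance(counts, gamma_shape,
                                                         max_distance)
            except ValueError:
                continue
            rep = nj_tree(DistanceMatrix(labels, m))
            for s in bipartitions(rep) & base_splits:
                hits[s] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in hits.items()}
    all_leaves = base.leaf_names()
    ref = min(all_leaves)
    for node in base.postorder():
        if node is base or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.support = round(supports[side], 1)
    return base, supports


# ---------------------------------------------------------------------------
# clade calls
# ---------------------------------------------------------------------------

@dataclass
class CladeDefinition:
    clade_id: str
    members: list[str]
    species: list[str]
    support: float


def reroot(tree: Node, outgroup: str) -> Node:
    """Root the unrooted tree on the edge leading to ``outgroup``."""
    # find path from current root to the outgroup leaf
    def path_to(node, target, acc):
        if node.is_leaf:
            return acc + [node] if node.name == target else None
        for c in node.children:
            p = path_to(c, target, acc + [node])
            if p:
                return p
        return None

    path = path_to(tree, outgroup, [])
    if path is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    if len(path) == 2 and path[0] is tree:
        return tree  # already adjacent to root
    # re-hang: walk from leaf back to old root, reversing parent links
    new_root = Node()
    out_leaf = path[-1]
    new_root.children.append(out_leaf)
    prev = out_leaf
    rest = None
    for node in reversed(path[:-1]):
        node.children = [c for c in node.children if c is not prev]
        clone = Node(length=prev.length, support=node.support,
                     children=node.children)
        if rest is None:
            rest = clone
            new_root.children.append(rest)
            cursor = clone
        else:
            cursor.children.append(clone)
            cursor = clone
        prev = node
    return new_root


def call_clades(tree: Node, supports: dict[frozenset, float],
                leaf_species_map: dict[str, str], outgroup: str,
                min_support: float = 70.0, min_species: int = 2
                ) -> list[CladeDefinition]:
    """Maximal supported multi-species subtrees after rooting on the
    outgroup.

    Support must be strictly greater than ``min_support`` and the subtree
    must span at least ``min_species`` distinct species; a qualifying
    subtree nested inside an already-called clade is not reported
    (maximality).
    """
    rooted = reroot(tree, outgroup)
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    clades: list[CladeDefinition] = []

    def support_of(node) -> float:
        side = node.leaf_names()
        key = side if ref not in side else all_leaves - side
        return supports.get(key, 0.0)

    def walk(node):
        if node.is_leaf:
            return
        members = sorted(node.leaf_names())
        if outgroup not in members:
            species = sorted({leaf_species_map.get(m, m) for m in members})
            sup = support_of(node)
            if sup > min_support and len(species) >= min_species:
                clades.append(CladeDefinition("", members, species,
                                              round(sup, 1)))
                return  # maximality: do not descend into a called clade
        for c in node.children:
            walk(c)

    for c in rooted.children:
        walk(c)
    clades.sort(key=lambda c: c.members[0])
    for i, c in enumerate(clades):
        c.clade_id = f"Clade{i + 1}"
    return clades
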