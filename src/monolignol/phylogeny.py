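"""Distance phylogenies per gene family and their evolutionary class.

Distances come from aligned protein (or DNA) rows under pairwise deletion:
for each sequence pair only columns where neither row has a gap are
compared, giving the observed difference fraction p, optionally corrected
for multiple hits with the Poisson model d = -ln(1 - p). Trees are built
with neighbor joining; edge support comes from column-resampling
bootstrap. Each family tree is then classified from the placement of the
three taxon groups (herbaceous monocots, herbaceous dicots, woody
species):

* class Ia — the monocots form one side of a split while herbaceous
  dicots stay grouped with the woody taxa;
* class Ib — some internal vertex separates the tree into exactly the
  three groups (each group a clade of its own);
* class II — the groups interleave: an expanded family whose
  duplications predate the taxon splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

GROUPS = ("monocot", "herb_dicot", "woody")


@dataclass
class MSA:
    """Aligned rows of equal length ('-' is the gap character)."""

    ids: list[str]
    rows: list[str]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in MSA")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "MSA":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return MSA(ids=list(self.ids), rows=rows, group_of=dict(self.group_of))


_GAP = ord("-")


def _msa_matrix(msa: MSA) -> np.ndarray:
    return np.frombuffer(
        "".join(msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(msa.rows), -1)


def _dist_from_matrix(mat: np.ndarray, ids: list[str], model: str) -> np.ndarray:
    n = mat.shape[0]
    dist = np.zeros((n, n))
    valid = mat != _GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites for pair ({ids[i]}, {ids[j]})"
                )
            p = int(((mat[i] != mat[j]) & both).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson distance undefined (p={p:.3f}) for pair "
                        f"({ids[i]}, {ids[j]})"
                    )
                d = -math.log1p(-p)
            else:
                d = p
            dist[i, j] = dist[j, i] = d
    return dist


def pairwise_distance(msa: MSA, model: str = "poisson") -> np.ndarray:
    """Symmetric distance matrix under pairwise deletion.

    Per pair, only columns where neither row has a gap are compared;
    ``model="p"`` returns the raw difference fraction, ``"poisson"``
    applies d = -ln(1 - p). A pair with no comparable sites, or with
    p >= 1 under the Poisson model, is an error naming the pair.
    """
    if model not in ("p", "poisson"):
        raise ValueError("model must be 'p' or 'poisson'")
    return _dist_from_matrix(_msa_matrix(msa), msa.ids, model)


def nj_tree(dist: np.ndarray, ids: list[str]) -> TreeNode:
    """Neighbor joining (Saitou-Nei Q criterion).

    Returns an unrooted tree represented with a trifurcating root. For an
    additive matrix the generating topology is recovered exactly. Negative
    branch-length estimates are clamped to zero.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    d = dist.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)  # first minimum: deterministic
        if i > j:
            i, j = j, i
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        new = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = max(float(vi), 0.0)
        b.length = max(float(vj), 0.0)
        new.extend([a, b])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new

    # final star join: three-point formulas
    root = TreeNode()
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = (
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    )
    for node, length in zip(nodes, lengths):
        node.length = max(float(length), 0.0)
    root.extend(nodes)
    return root


def _subtree_leafsets(tree: TreeNode) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            out[id(node)] = frozenset([node.name])
        else:
            out[id(node)] = frozenset().union(
                *(out[id(c)] for c in node.children)
            )
    return out


def bipartitions(tree: TreeNode, trivial: bool = False) -> set[frozenset[str]]:
    """Splits of the unrooted tree, each as the leaf side away from the
    lexicographically smallest leaf. ``trivial`` includes single-leaf
    splits."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    sets = _subtree_leafsets(tree)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False) if not trivial else tree.traverse(include_self=False):
        side = sets[id(node)]
        if ref in side:
            side = leaves - side
        lo, hi = (2, len(leaves) - 2) if not trivial else (1, len(leaves) - 1)
        if lo <= len(side) <= hi:
            splits.add(side)
    return splits


def bootstrap_support(
    msa: MSA,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree from the full alignment plus column-bootstrap edge support.

    Support of an internal edge is the percentage of replicate trees
    containing the same bipartition; it is written into the internal node
    names so Newick output carries it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    mat = _msa_matrix(msa)
    tree = nj_tree(_dist_from_matrix(mat, msa.ids, model), msa.ids)
    target = bipartitions(tree)
    hits = dict.fromkeys(target, 0)
    for _ in range(n_reps):
        cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
        rep_tree = nj_tree(
            _dist_from_matrix(mat[:, cols], msa.ids, model), msa.ids
        )
        for split in bipartitions(rep_tree):
            if split in hits:
                hits[split] += 1
    support = {s: 100.0 * k / n_reps for s, k in hits.items()}
    sets = _subtree_leafsets(tree)
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = sets[id(node)]
        if ref in side:
            side = leaves - side
        if side in support:
            node.name = f"{support[side]:.0f}"
    return tree, support


def classify_family(tree: TreeNode, group_of: dict[str, str]) -> str:
    """Return ``"Ia"``, ``"Ib"`` or ``"II"`` from group placement.

    Deterministic in the tree alone: invariant to leaf order and to which
    internal vertex serves as the (trifurcating) root.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in group_of]
    if missing:
        raise ValueError(f"leaves without group label: {missing}")
    groups: dict[str, set[str]] = {}
    for leaf in leaves:
        groups.setdefault(group_of[leaf], set()).add(leaf)

    all_leaves = frozenset(leaves)
    sets = _subtree_leafsets(tree)

    # Ib: some internal vertex splits the leaves into exactly the three groups
    if set(groups) == set(GROUPS):
        target = {frozenset(g) for g in groups.values()}
        for node in tree.traverse(include_self=True):
            if node.is_tip():
                continue
            comps = [frozenset(sets[id(c)]) for c in node.children]
            if not node.is_root():
                comps.append(all_leaves - frozenset(sets[id(node)]))
            if len(comps) == 3 and set(comps) == target:
                return "Ib"

    # Ia: monocots form one side of some edge (monophyly in the unrooted tree)
    mono = frozenset(groups.get("monocot", set()))
    if mono and mono != all_leaves:
        for node in tree.traverse(include_self=False):
            side = frozenset(sets[id(node)])
            if side == mono or all_leaves - side == mono:
                return "Ia"

    return "II"


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
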