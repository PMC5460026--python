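"""Hierarchical clustering of samples: divisive (DIANA) and agglomerative
(Ward), over Euclidean distances between signature-gene profiles.

Both algorithms are implemented here from first principles because the
downstream robustness statistics depend on their exact split/merge
decisions:

* **DIANA** (divisive analysis): starting from one cluster, repeatedly take
  the cluster with the largest diameter (maximal pairwise dissimilarity),
  seed a splinter group with the object of maximal average dissimilarity to
  its cluster-mates, then iteratively move across the object whose average
  dissimilarity to the remainder (excluding itself) most exceeds its average
  dissimilarity to the splinter group, until no object prefers the splinter
  side.  The height of a split is the diameter of the cluster it divides.
  Ties (splinter seed, move candidate, cluster choice) are broken by lowest
  input index so runs are deterministic.

* **Ward**: Lance-Williams recurrence on squared Euclidean distances,
  recording heights as the square root of the updated squared distance (the
  "ward.D2" convention also used by scipy).  Merge heights are
  non-decreasing.

Both produce the same :class:`Dendrogram` structure.  A divisive tree is
stored with its splits reversed into merges, so merge heights are
non-decreasing for either kind and :func:`cut_tree` can uniformly undo the
last k-1 merges — which equals undoing the k-1 highest merges for Ward and
applying the k-1 largest-diameter splits for DIANA.  This makes cuts nested:
the (k+1)-clustering always refines the k-clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DissimilarityMatrix",
    "Dendrogram",
    "euclidean_dissimilarity",
    "diana",
    "ward_hclust",
    "cut_tree",
    "cut_labels",
    "to_newick",
    "from_newick",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities between samples."""

    ids: list[str]
    values: np.ndarray  # (n, n), zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite dissimilarities")
        if not np.allclose(d, d.T):
            raise ValueError("dissimilarity matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(d < 0):
            raise ValueError("negative dissimilarities")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class Dendrogram:
    """Full binary merge tree over samples.

    ``merges`` lists n-1 rows (left, right, height); node ids 0..n-1 are
    leaves (in ``leaf_ids`` order), and row i creates internal node n+i.
    Heights are non-decreasing along the merge sequence for both tree kinds
    (see module docstring).  ``divisive_coefficient`` is populated for
    DIANA trees only.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]
    kind: str  # "agglomerative" | "divisive"
    divisive_coefficient: float | None = None
    _leafsets: list[frozenset[int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        if self.kind not in ("agglomerative", "divisive"):
            raise ValueError(f"unknown tree kind {self.kind!r}")
        seen: set[int] = set()
        for i, (a, b, h) in enumerate(self.merges):
            limit = n + i
            if not (0 <= a < limit and 0 <= b < limit) or a == b:
                raise ValueError(f"merge {i} references invalid nodes")
            if a in seen or b in seen:
                raise ValueError(f"merge {i} reuses a merged node")
            if h < 0:
                raise ValueError(f"negative merge height at row {i}")
            seen.update((a, b))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_leafsets(self) -> list[frozenset[int]]:
        """Leaf-index set below every node (leaves first, then merge order)."""
        if not self._leafsets:
            n = self.n_leaves
            sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
            for a, b, _ in self.merges:
                sets.append(sets[a] | sets[b])
            self._leafsets = sets
        return self._leafsets


def euclidean_dissimilarity(matrix: pd.DataFrame) -> DissimilarityMatrix:
    """Euclidean distances between sample columns over all matrix rows."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    values = matrix.to_numpy(dtype=float).T
    if not np.all(np.isfinite(values)):
        raise ValueError("NaN or infinite expression values")
    d = squareform(pdist(values, metric="euclidean"))
    return DissimilarityMatrix(ids=[str(c) for c in matrix.columns], values=d)


# ---------------------------------------------------------------------------
# DIANA
# ---------------------------------------------------------------------------

def _diameter(d: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = d[np.ix_(members, members)]
    return float(sub.max())


def _splinter_split(d: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One divisive step: split ``members`` into (splinter, remainder).

    Seed = object with maximal average dissimilarity to the others (ties:
    lowest index).  Then repeatedly move the remainder object with the
    largest positive (avg dissimilarity to remainder-mates - avg
    dissimilarity to splinter); stop at the fixpoint or when the remainder
    would empty.
    """
    members = sorted(members)
    m = len(members)
    sub = d[np.ix_(members, members)]
    avg_to_rest = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg_to_rest))  # argmax takes lowest index on ties

    in_splinter = np.zeros(m, dtype=bool)
    in_splinter[seed] = True
    while in_splinter.sum() < m - 1:
        rem = np.flatnonzero(~in_splinter)
        spl = np.flatnonzero(in_splinter)
        # average dissimilarity of each remainder object to remainder-mates
        # (excluding itself) and to the splinter group
        d_rem = sub[np.ix_(rem, rem)].sum(axis=1) / (len(rem) - 1)
        d_spl = sub[np.ix_(rem, spl)].mean(axis=1)
        gain = d_rem - d_spl
        best = int(np.argmax(gain))
        if gain[best] <= 0:
            break
        in_splinter[rem[best]] = True
    splinter = [members[i] for i in np.flatnonzero(in_splinter)]
    remainder = [members[i] for i in np.flatnonzero(~in_splinter)]
    return splinter, remainder


def diana(dm: DissimilarityMatrix) -> Dendrogram:
    """Divisive analysis clustering.

    Returns a :class:`Dendrogram` (kind ``divisive``) whose merge heights
    are the diameters of the divided clusters, plus the divisive
    coefficient: DC = mean over objects of 1 - d(i)/diam(all), where d(i)
    is the diameter of the last multi-object cluster containing object i.
    """
    d = dm.values
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    # splits in execution order: (members, splinter, remainder, diameter)
    splits: list[tuple[list[int], list[int], list[int], float]] = []
    active: list[list[int]] = [list(range(n))]
    total_diam = _diameter(d, active[0])
    last_diam = np.zeros(n)  # d(i) for the divisive coefficient

    while any(len(c) > 1 for c in active):
        # largest-diameter cluster among the divisible ones; ties by the
        # lowest contained index (deterministic)
        best_idx, best_diam = -1, -1.0
        for idx, c in enumerate(active):
            if len(c) < 2:
                continue
            diam = _diameter(d, c)
            if diam > best_diam:
                best_idx, best_diam = idx, diam
        cluster = active.pop(best_idx)
        for i in cluster:
            last_diam[i] = best_diam
        splinter, remainder = _splinter_split(d, cluster)
        splits.append((sorted(cluster), splinter, remainder, best_diam))
        active.extend([splinter, remainder])

    merges = _splits_to_merges(n, splits)
    dc = float(np.mean(1.0 - last_diam / total_diam)) if total_diam > 0 else 1.0
    return Dendrogram(leaf_ids=list(dm.ids), merges=merges, kind="divisive",
                      divisive_coefficient=dc)


def _splits_to_merges(
    n: int,
    splits: list[tuple[list[int], list[int], list[int], float]],
) -> list[tuple[int, int, float]]:
    """Reverse a split sequence into a merge list.

    Splits are executed in non-increasing diameter order (the largest
    cluster is always divided next), so reversing them yields merges with
    non-decreasing heights; cutting then works identically for both kinds.
    """
    node_of: dict[frozenset[int], int] = {frozenset([i]): i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for members, splinter, remainder, diam in reversed(splits):
        a = node_of[frozenset(splinter)]
        b = node_of[frozenset(remainder)]
        left, right = (a, b) if a < b else (b, a)
        merges.append((left, right, diam))
        node_of[frozenset(members)] = n + len(merges) - 1
    return merges


# ---------------------------------------------------------------------------
# Ward
# ---------------------------------------------------------------------------

def ward_hclust(dm: DissimilarityMatrix) -> Dendrogram:
    """Agglomerative clustering with Ward's minimum-variance criterion.

    Operates on the squared input (Euclidean) distances via the
    Lance-Williams recurrence

        d2(k, i+j) = [(n_i+n_k) d2(k,i) + (n_j+n_k) d2(k,j) - n_k d2(i,j)]
                     / (n_i + n_j + n_k)

    and records sqrt(d2) as the merge height, so merging two singletons at
    Euclidean distance d happens at height d.  Pair ties are broken by the
    lexicographically smallest (older node, newer node) pair.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    d2 = dm.values.astype(float) ** 2

    size = {i: 1 for i in range(n)}
    active = list(range(n))
    # current squared inter-cluster distances, keyed by frozenset({a, b})
    cur: dict[frozenset[int], float] = {
        frozenset((i, j)): d2[i, j]
        for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []

    while len(active) > 1:
        # first pair in (creation-order, creation-order) scan wins ties
        best_pair, best_val = None, np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                v = cur[frozenset((a, b))]
                if v < best_val:
                    best_pair, best_val = (a, b), v
        a, b = best_pair  # type: ignore[misc]
        new = n + len(merges)
        merges.append((a, b, float(np.sqrt(max(best_val, 0.0)))))
        na, nb = size[a], size[b]
        for k in active:
            if k in (a, b):
                continue
            nk = size[k]
            dka = cur[frozenset((k, a))]
            dkb = cur[frozenset((k, b))]
            cur[frozenset((k, new))] = (
                (na + nk) * dka + (nb + nk) * dkb - nk * best_val
            ) / (na + nb + nk)
        active = [k for k in active if k not in (a, b)] + [new]
        size[new] = na + nb

    return Dendrogram(leaf_ids=list(dm.ids), merges=merges, kind="agglomerative")


# ---------------------------------------------------------------------------
# cutting and serialization
# ---------------------------------------------------------------------------

def cut_tree(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut a dendrogram into k groups; labels 1..k in leaf order.

    Undoes the last k-1 merges.  Because merge heights are non-decreasing
    for both tree kinds, this equals undoing the k-1 highest merges (ties
    resolved by later merge order) for Ward and applying the k-1
    largest-diameter splits for DIANA.  Successive cuts are nested.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row, (a, b, _h) in enumerate(tree.merges[: n - k]):
        new = n + row
        parent[find(a)] = new
        parent[find(b)] = new

    labels: dict[str, int] = {}
    root_order: dict[int, int] = {}
    for i, leaf in enumerate(tree.leaf_ids):
        r = find(i)
        if r not in root_order:
            root_order[r] = len(root_order) + 1
        labels[leaf] = root_order[r]
    assert len(root_order) == k
    return labels


def cut_labels(tree: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels as an array aligned with ``tree.leaf_ids``."""
    mapping = cut_tree(tree, k)
    return np.asarray([mapping[leaf] for leaf in tree.leaf_ids])


def to_newick(tree: Dendrogram) -> str:
    """Newick serialization with branch lengths = parent height - child
    height (leaves at height 0), so node heights are recoverable."""
    n = tree.n_leaves
    heights = [0.0] * n + [h for _, _, h in tree.merges]

    def render(node: int, parent_height: float) -> str:
        bl = max(parent_height - heights[node], 0.0)
        if node < n:
            return f"{_quote(tree.leaf_ids[node])}:{bl:.10g}"
        a, b, h = tree.merges[node - n]
        return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

    root = n + len(tree.merges) - 1
    a, b, h = tree.merges[-1]
    return f"({render(a, h)},{render(b, h)});"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;'\" \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def from_newick(text: str, kind: str = "agglomerative") -> Dendrogram:
    """Parse a Newick dendrogram back into the merge representation.

    Node heights are reconstructed as the maximum root-path-complement
    depth below each node; merges are emitted in ascending height order.
    Topology and heights round-trip through :func:`to_newick`.
    """
    import skbio

    t = skbio.TreeNode.read([text])
    leaves = list(t.tips())
    leaf_ids = [lf.name for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}

    entries: list[tuple[float, list[frozenset[int]]]] = []

    def height_of(node) -> float:
        if node.is_tip():
            return 0.0
        child_heights = [
            height_of(c) + (c.length or 0.0) for c in node.children
        ]
        h = max(child_heights)
        kids = [frozenset(index[id(lf)] for lf in c.tips()) if not c.is_tip()
                else frozenset([index[id(c)]]) for c in node.children]
        entries.append((h, kids))
        return h

    height_of(t)
    n = len(leaf_ids)
    entries.sort(key=lambda e: e[0])
    node_of: dict[frozenset[int], int] = {frozenset([i]): i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for h, kids in entries:
        if len(kids) != 2:
            raise ValueError("dendrogram Newick must be strictly binary")
        a, b = node_of[kids[0]], node_of[kids[1]]
        left, right = (a, b) if a < b else (b, a)
        merges.append((left, right, float(h)))
        node_of[kids[0] | kids[1]] = n + len(merges) - 1
    return Dendrogram(leaf_ids=leaf_ids, merges=merges, kind=kind)
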