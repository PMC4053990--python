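"""Agglomerative centroid-linkage clustering on correlation distance.

Distance between items (and between cluster centroids) is d = 1 − Pearson r
of their expression profiles; a merge is recorded with its correlation
r = 1 − d, which downstream stages threshold (sample groups at r >= 0.65)
and the TreeView writer emits per node. Centroid linkage re-correlates
cluster mean profiles, so merge heights are not guaranteed monotone
(inversions are logged, as in classic microarray clustering tools).

The agglomeration is deterministic: among equal-distance pairs the lowest
(i, j) cluster-index pair merges first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bundle import BundleError, ExpressionBundle

log = logging.getLogger("gemmclass")


@dataclass
class ClusterTree:
    """Binary merge tree. Leaves are 0..n-1; merge k creates node n+k.

    ``merges[k] = (left, right, r)`` with r the merge correlation in [-1, 1].
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]
    leaf_order: list[int]
    ids: list[str] = field(default_factory=list)
    linkage: str = "centroid"
    distance: str = "1-pearson"

    def __post_init__(self) -> None:
        if len(self.merges) != max(self.n_leaves - 1, 0):
            raise BundleError(f"tree with {self.n_leaves} leaves must have "
                              f"{self.n_leaves - 1} merges, got {len(self.merges)}")
        if sorted(self.leaf_order) != list(range(self.n_leaves)):
            raise BundleError("leaf order is not a permutation of the leaves")
        for left, right, r in self.merges:
            if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
                raise BundleError(f"merge correlation {r} outside [-1, 1]")

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1 if self.merges else 0

    def children(self, node: int) -> tuple[int, int]:
        if node < self.n_leaves:
            raise BundleError(f"node {node} is a leaf")
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def node_r(self, node: int) -> float:
        return self.merges[node - self.n_leaves][2]

    def leaves_of(self, node: int) -> list[int]:
        """Leaf indices under ``node`` in left-to-right order."""
        out, stack = [], [node]
        while stack:
            cur = stack.pop()
            if cur < self.n_leaves:
                out.append(cur)
            else:
                left, right, _ = self.merges[cur - self.n_leaves]
                stack.extend((right, left))
        return out

    def leaf_ids_of(self, node: int) -> list[str]:
        return [self.ids[i] for i in self.leaves_of(node)]


def _masked_corr_one_vs_many(c: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of profile ``c`` against each row of ``M``.

    Complete pairs only; rows with fewer than 2 shared observations or zero
    variance get r = 0 (distance 1).
    """
    finite_c = np.isfinite(c)
    finite_M = np.isfinite(M)
    W = finite_M & finite_c[None, :]
    n = W.sum(axis=1).astype(float)
    x = np.where(W, M, 0.0)
    y = np.where(W, c[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = x.sum(1), y.sum(1)
        sxx, syy, sxy = (x * x).sum(1), (y * y).sum(1), (x * y).sum(1)
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    bad = ~np.isfinite(r) | (n < 2)
    if bad.any():
        r = np.where(bad, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def hcluster(bundle_or_matrix, axis: str = "samples") -> ClusterTree:
    """Cluster samples (columns) or features (rows) by centroid linkage.

    Accepts an :class:`ExpressionBundle` or a plain feature x sample
    DataFrame. Zero-variance items correlate 0 with everything (distance 1),
    with a warning.
    """
    df = bundle_or_matrix.values if isinstance(bundle_or_matrix, ExpressionBundle) \
        else bundle_or_matrix
    if axis == "samples":
        X = df.to_numpy(dtype=float).T
        ids = list(df.columns)
    elif axis == "features":
        X = df.to_numpy(dtype=float)
        ids = list(df.index)
    else:
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    n = X.shape[0]
    if n < 2:
        raise BundleError("need at least 2 items to cluster")

    var = np.nanvar(X, axis=1)
    if np.any(var == 0):
        log.warning("%d zero-variance item(s); their correlations set to 0",
                    int((var == 0).sum()))

    # cluster state: running sums/counts give NaN-aware centroids
    sums = np.where(np.isfinite(X), X, 0.0)
    counts = np.isfinite(X).astype(float)
    with np.errstate(invalid="ignore"):
        centroids = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    INF = np.inf
    D = np.full((2 * n - 1, 2 * n - 1), INF)
    for i in range(n):
        r = _masked_corr_one_vs_many(centroids[i], centroids[:n])
        D[i, :n] = 1.0 - r
    D[np.diag_indices(n)] = INF
    # symmetrize exactly (masked corr is symmetric up to fp noise)
    D[:n, :n] = np.minimum(D[:n, :n], D[:n, :n].T)

    all_sums = np.zeros((2 * n - 1, X.shape[1]))
    all_counts = np.zeros((2 * n - 1, X.shape[1]))
    all_sums[:n] = sums
    all_counts[:n] = counts
    cents = np.full((2 * n - 1, X.shape[1]), np.nan)
    cents[:n] = centroids

    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    prev_d = -np.inf
    inversions = 0
    for step in range(n - 1):
        act = np.array(active)
        sub = D[np.ix_(act, act)]
        flat = np.argmin(sub)
        a, b = divmod(flat, len(act))
        dmin = sub[a, b]
        # lexicographic tie-break on (i, j), i < j, among exact-min pairs
        ties = np.argwhere(sub == dmin)
        ties = ties[ties[:, 0] < ties[:, 1]]
        a, b = min((int(i), int(j)) for i, j in ties)
        i, j = int(act[a]), int(act[b])

        new = n + step
        r_merge = float(np.clip(1.0 - dmin, -1.0, 1.0))
        if dmin < prev_d - 1e-12:
            inversions += 1
        prev_d = dmin
        merges.append((i, j, r_merge))

        all_sums[new] = all_sums[i] + all_sums[j]
        all_counts[new] = all_counts[i] + all_counts[j]
        with np.errstate(invalid="ignore"):
            cents[new] = np.where(all_counts[new] > 0,
                                  all_sums[new] / np.maximum(all_counts[new], 1),
                                  np.nan)
        active.remove(i)
        active.remove(j)
        if active:
            rvec = _masked_corr_one_vs_many(cents[new], cents[active])
            D[new, active] = 1.0 - rvec
            D[active, new] = D[new, active]
        active.append(new)
    if inversions:
        log.info("centroid linkage produced %d inversion(s)", inversions)

    # left-to-right leaf order from the root, before tree validation
    order, stack = [], [n + len(merges) - 1]
    while stack:
        cur = stack.pop()
        if cur < n:
            order.append(cur)
        else:
            left, right, _ = merges[cur - n]
            stack.extend((right, left))
    return ClusterTree(n, merges, order, ids)


def extract_groups(tree: ClusterTree, r_min: float) -> list[list[str]]:
    """Maximal subtrees whose merge correlation is >= ``r_min``.

    Top-down: the highest node with node-r >= r_min claims all its leaves;
    its descendants are not revisited, so every leaf lands in at most one
    group. Singleton leaves never form groups.
    """
    groups: list[list[str]] = []
    if tree.n_leaves < 2:
        return groups
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node < tree.n_leaves:
            continue
        if tree.node_r(node) >= r_min:
            groups.append(tree.leaf_ids_of(node))
        else:
            left, right = tree.children(node)
            stack.extend((left, right))
    return groups
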