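"""Expression class calling, model homogeneity, and latency contrasts.

Classes are called by reclustering samples on the intrinsic gene list and
walking the dendrogram top-down: a node is split when SigClust finds its
two-way partition significant (p <= alpha) and both children hold >= 2
samples; terminal nodes with at least ``class_min_size`` samples become
classes, smaller terminals stay UNASSIGNED. A model is then homogeneous /
semi-homogeneous / heterogeneous according to whether >= 80% of its tumors
fall in one class, two classes, or neither.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import BundleError, ExpressionBundle
from .cluster import ClusterTree, hcluster
from .config import PipelineConfig
from .sigclust import sigclust_test

log = logging.getLogger("gemmclass")

UNASSIGNED = "UNASSIGNED"


@dataclass
class ClassAssignment:
    labels: pd.Series                       # sample -> class name or UNASSIGNED
    node_pvalues: dict[int, float]
    tree: ClusterTree | None = None
    class_names: list[str] = field(default_factory=list)

    @property
    def class_sizes(self) -> pd.Series:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return counts.reindex(self.class_names, fill_value=0)

    @property
    def n_assigned(self) -> int:
        return int((self.labels != UNASSIGNED).sum())

    def members(self, class_name: str) -> list[str]:
        return list(self.labels.index[self.labels == class_name])

    def rename(self, mapping: dict[str, str]) -> "ClassAssignment":
        labels = self.labels.replace(mapping)
        names = [mapping.get(c, c) for c in self.class_names]
        return ClassAssignment(labels, dict(self.node_pvalues), self.tree, names)


def _node_seed(base_seed: int, sample_ids: list[str]) -> int:
    """Order-invariant per-node seed: hash of the sorted member ids."""
    key = f"{base_seed}|" + "|".join(sorted(map(str, sample_ids)))
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16)


def call_classes(bundle: ExpressionBundle, intrinsic_genes: list[str],
                 config: PipelineConfig | None = None) -> ClassAssignment:
    """Recluster on the intrinsic list and call SigClust-significant classes."""
    config = config or PipelineConfig()
    present = [g for g in intrinsic_genes if g in bundle.values.index]
    if not present:
        raise BundleError("no intrinsic gene is present in the bundle")
    if bundle.n_samples < config.class_min_size:
        raise BundleError(
            f"{bundle.n_samples} samples < class_min_size={config.class_min_size}")
    sub = bundle.subset_features(present)
    tree = hcluster(sub, axis="samples")
    X = sub.values.to_numpy(dtype=float).T      # samples x features
    if not np.isfinite(X).all():
        raise BundleError("class calling requires a complete (imputed) matrix")

    node_p: dict[int, float] = {}
    terminals: list[list[int]] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        leaves = tree.leaves_of(node)
        if node < tree.n_leaves or len(leaves) < 4:
            terminals.append(leaves)
            continue
        left, right = tree.children(node)
        nl = len(tree.leaves_of(left))
        nr = len(tree.leaves_of(right))
        if min(nl, nr) < 2:
            terminals.append(leaves)
            continue
        ids = [tree.ids[i] for i in leaves]
        res = sigclust_test(X[leaves], nsim=config.sigclust_nsim,
                            seed=_node_seed(config.seed, ids))
        node_p[node] = res.p_value
        if res.p_value <= config.sigclust_alpha:
            stack.extend((right, left))
        else:
            terminals.append(leaves)

    # deterministic naming: classes numbered left-to-right in the dendrogram
    position = {leaf: pos for pos, leaf in enumerate(tree.leaf_order)}
    terminals.sort(key=lambda lv: min(position[i] for i in lv))
    labels = pd.Series(UNASSIGNED, index=sub.sample_ids, dtype=object)
    names = []
    k = 0
    for leaves in terminals:
        if len(leaves) >= config.class_min_size:
            k += 1
            name = f"Class{k}"
            names.append(name)
            labels.iloc[leaves] = name
    log.info("called %d classes covering %d/%d samples", k,
             int((labels != UNASSIGNED).sum()), len(labels))
    return ClassAssignment(labels=labels, node_pvalues=node_p, tree=tree,
                           class_names=names)


# ---------------------------------------------------------------------------
# model homogeneity
# ---------------------------------------------------------------------------

HOMOGENEOUS = "homogeneous"
SEMI_HOMOGENEOUS = "semi-homogeneous"
HETEROGENEOUS = "heterogeneous"
INSUFFICIENT_N = "insufficient-n"


def categorize_shares(top: float, top_two: float, share: float = 0.80) -> str:
    """The 80% rule: one class, two classes, or neither."""
    if top >= share:
        return HOMOGENEOUS
    if top_two >= share:
        return SEMI_HOMOGENEOUS
    return HETEROGENEOUS


@dataclass
class HomogeneityReport:
    table: pd.DataFrame  # per model: n, top_share, top_two_share, category

    def category(self, model: str) -> str:
        return str(self.table.loc[model, "category"])


def classify_homogeneity(labels: pd.Series | ClassAssignment,
                         model_labels: pd.Series,
                         config: PipelineConfig | None = None) -> HomogeneityReport:
    """Categorize every model by how its tumors distribute over classes.

    ``labels`` maps sample -> class (UNASSIGNED allowed; unassigned tumors
    count in the denominator but cannot carry a share). Models with < 2
    tumors are reported as insufficient-n.
    """
    config = config or PipelineConfig()
    if isinstance(labels, ClassAssignment):
        labels = labels.labels
    missing = [s for s in labels.index if s not in model_labels.index]
    if missing:
        raise BundleError(f"sample(s) without model label: {missing[:5]}")
    rows = []
    for model, samples in labels.groupby(model_labels.loc[labels.index]).groups.items():
        classes = labels.loc[samples]
        n = len(classes)
        counts = classes[classes != UNASSIGNED].value_counts()
        top = float(counts.iloc[0]) / n if len(counts) else 0.0
        top_two = float(counts.iloc[:2].sum()) / n if len(counts) else 0.0
        if n < 2:
            cat = INSUFFICIENT_N
        else:
            cat = categorize_shares(top, top_two, config.homogeneity_share)
        rows.append((model, n, top, top_two, cat))
    table = pd.DataFrame(rows, columns=["model", "n", "top_share",
                                        "top_two_share", "category"]
                         ).set_index("model")
    return HomogeneityReport(table=table)


# ---------------------------------------------------------------------------
# latency contrast
# ---------------------------------------------------------------------------

def latency_contrast(assignment: ClassAssignment | pd.Series,
                     latencies: pd.Series, class_a: str, class_b: str,
                     max_exact: int = 100_000) -> tuple[float, float, float]:
    """Median latencies of two classes and a two-sided rank-sum p-value.

    Exact p by enumeration of group assignments when the number of
    combinations is tractable, otherwise the tie-corrected normal
    approximation.
    """
    labels = assignment.labels if isinstance(assignment, ClassAssignment) else assignment
    lat = latencies.dropna()
    a = lat[labels.index[labels == class_a].intersection(lat.index)].to_numpy(float)
    b = lat[labels.index[labels == class_b].intersection(lat.index)].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise BundleError(f"no latency data for class "
                          f"{class_a if len(a) == 0 else class_b!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, n = len(a), len(pooled)
    t_obs = ranks[:na].sum()
    mu = na * (n + 1) / 2.0

    if math.comb(n, na) <= max_exact:
        extreme = total = 0
        for combo in itertools.combinations(range(n), na):
            t = ranks[list(combo)].sum()
            total += 1
            if abs(t - mu) >= abs(t_obs - mu) - 1e-9:
                extreme += 1
        p = extreme / total
    else:
        _, counts = np.unique(pooled, return_counts=True)
        nb = n - na
        tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1))
        var = na * nb / 12.0 * (n + 1 - tie_term)
        z = (t_obs - mu) / math.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    return float(np.median(a)), float(np.median(b)), float(min(p, 1.0))
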