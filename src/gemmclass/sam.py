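"""Two-class significance analysis of microarrays (SAM) with permutation FDR.

The moderated statistic is d(g) = (mean_in − mean_out) / (s(g) + s0) with
s(g) the pooled standard error and s0 a fudge constant chosen to minimize
the coefficient of variation of the d spread across windows of the s
distribution. q-values come from the plug-in estimator: for each feature's
|d| threshold, the median over label permutations of the number of
permuted |d| values at or beyond it, scaled by the null-proportion
estimate pi0 and divided by the observed count, monotonized from the top.
A feature reaches q = 0 only when the typical (median) permutation places
no feature beyond its threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import BundleError, ExpressionBundle, GeneSet
from .classes import ClassAssignment
from .config import PipelineConfig

log = logging.getLogger("gemmclass")


@dataclass
class SAMResult:
    d: pd.Series
    numerator: pd.Series
    s: pd.Series
    s0: float
    q: pd.Series
    nperm: int
    seed: int | None

    def significant_up(self, fdr: float = 0.0) -> list[str]:
        mask = (self.d > 0) & (self.q <= fdr)
        return list(self.d.index[mask])


def _group_stats(X: np.ndarray, members: np.ndarray):
    """Per-feature numerator and pooled SE for one or many membership vectors.

    X: (m, n) features x samples; members: (B, n) boolean. Returns
    (numerator, s) each of shape (m, B).
    """
    M = members.astype(float).T                    # (n, B)
    n1 = M.sum(axis=0)                             # (B,)
    n = X.shape[1]
    n2 = n - n1
    sum1 = X @ M                                   # (m, B)
    sumsq1 = (X ** 2) @ M
    sum_all = X.sum(axis=1, keepdims=True)
    sumsq_all = (X ** 2).sum(axis=1, keepdims=True)
    sum2 = sum_all - sum1
    sumsq2 = sumsq_all - sumsq1
    mean1, mean2 = sum1 / n1, sum2 / n2
    ss1 = sumsq1 - sum1 ** 2 / n1
    ss2 = sumsq2 - sum2 ** 2 / n2
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    s = np.sqrt(np.maximum((1.0 / n1 + 1.0 / n2) * pooled, 0.0))
    return mean1 - mean2, s


def _choose_s0(numer: np.ndarray, s: np.ndarray) -> float:
    """Fudge constant minimizing the CV of the d spread across s-windows.

    Candidates are the 0,5,...,100 percentiles of s; the spread of d within
    each of 100 s-quantile windows is measured by the scaled MAD.
    """
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    m = len(s)
    edges = np.linspace(0, m, 101).astype(int)
    windows = [order[edges[i]:edges[i + 1]] for i in range(100)
               if edges[i + 1] > edges[i]]
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in np.unique(candidates):
        d = numer / (s + s0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) * 1.4826
                         for w in windows])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=1) / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutations(n: int, n1: int, nperm: int, rng: np.random.Generator) -> np.ndarray:
    """(B, n) boolean membership vectors; full enumeration when tractable."""
    total = math.comb(n, n1)
    if total <= nperm:
        out = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n1)):
            out[i, list(combo)] = True
        return out
    out = np.zeros((nperm, n), dtype=bool)
    for i in range(nperm):
        out[i, rng.choice(n, size=n1, replace=False)] = True
    return out


def sam_two_class(bundle: ExpressionBundle | pd.DataFrame, labels,
                  nperm: int = 1000, seed: int | None = None,
                  s0: float | None = None) -> SAMResult:
    """SAM for a binary contrast (labels True = in-group).

    ``labels`` is a boolean sequence/Series aligned to the samples. The
    permutation scheme redraws the in-group membership uniformly among all
    samples (full enumeration when C(n, n1) <= nperm).
    """
    values = bundle.values if isinstance(bundle, ExpressionBundle) else bundle
    y = np.asarray(pd.Series(labels).reindex(values.columns) if isinstance(labels, pd.Series)
                   else labels, dtype=bool)
    if y.shape[0] != values.shape[1]:
        raise BundleError("label vector length does not match sample count")
    n1 = int(y.sum())
    n = len(y)
    if n1 < 2 or n - n1 < 2:
        raise BundleError(f"need >= 2 samples per group, got {n1} vs {n - n1}")
    X = values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise BundleError("SAM requires a complete matrix; impute first")
    rng = np.random.default_rng(seed)

    numer, s = _group_stats(X, y[None, :])
    numer, s = numer[:, 0], s[:, 0]
    if s0 is None:
        s0 = _choose_s0(numer, s)
    with np.errstate(divide="ignore"):
        d = numer / (s + s0)

    perms = _permutations(n, n1, nperm, rng)
    numer_p, s_p = _group_stats(X, perms)
    with np.errstate(divide="ignore"):
        d_perm = numer_p / (s_p + s0)              # (m, B)
    B = d_perm.shape[1]

    # plug-in FDR with per-feature |d| thresholds
    abs_obs = np.abs(d)
    abs_perm_sorted = np.sort(np.abs(d_perm), axis=0)
    m = len(d)
    # count per permutation of |d*| >= t, for every feature threshold t
    counts = m - np.apply_along_axis(
        np.searchsorted, 0, abs_perm_sorted, abs_obs, side="left")  # (m, B)
    median_fp = np.median(counts, axis=1)
    observed = m - np.searchsorted(np.sort(abs_obs), abs_obs, side="left")

    q25, q75 = np.percentile(d_perm, [25, 75])
    pi0 = min(1.0, ((d > q25) & (d < q75)).sum() / (0.5 * m))

    with np.errstate(divide="ignore", invalid="ignore"):
        raw_q = np.minimum(1.0, pi0 * median_fp / observed)
    # q_i = min FDR over rejection regions containing i, i.e. over all
    # thresholds at or below |d_i|: cumulative min along ascending |d|
    order = np.argsort(abs_obs, kind="stable")
    running = np.minimum.accumulate(raw_q[order])
    q = np.empty(m)
    q[order] = running

    return SAMResult(
        d=pd.Series(d, index=values.index, name="d"),
        numerator=pd.Series(numer, index=values.index, name="numerator"),
        s=pd.Series(s, index=values.index, name="s"),
        s0=float(s0),
        q=pd.Series(q, index=values.index, name="q"),
        nperm=B, seed=seed)


def class_signature(bundle: ExpressionBundle, assignment: ClassAssignment,
                    class_id: str, config: PipelineConfig | None = None,
                    seed: int | None = None) -> GeneSet:
    """Genes up-regulated in ``class_id`` versus all other samples at the
    configured SAM FDR (default 0%)."""
    config = config or PipelineConfig()
    members = set(assignment.members(class_id))
    if len(members) < 2:
        raise BundleError(f"class {class_id!r} has fewer than 2 members")
    labels = pd.Series([s in members for s in bundle.sample_ids],
                       index=bundle.sample_ids)
    res = sam_two_class(bundle, labels, nperm=config.sam_nperm,
                        seed=config.seed if seed is None else seed)
    genes = res.significant_up(config.sam_fdr_select)
    if not genes:
        log.warning("class %s: empty signature at FDR <= %s",
                    class_id, config.sam_fdr_select)
    return GeneSet(set_id=class_id, description=f"up in {class_id} vs rest",
                   genes=genes)
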