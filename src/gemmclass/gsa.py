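"""Gene set analysis with the maxmean statistic and restandardization.

A set is scored by the larger (in magnitude) of the mean positive part and
the mean negative part of its members' two-sample t statistics. Raw scores
are restandardized against the whole gene catalogue — the genome-wide mean
and SD of the per-gene positive/negative parts, scaled for set size — so a
set must beat what a random set of equal size drawn from the same data
would do. Inference is by column-label permutation, each permutation
restandardized against its own catalogue; the p-value reported here is
one-sided for positive enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bundle import BundleError, ExpressionBundle, GeneSetCollection

log = logging.getLogger("gemmclass")


@dataclass
class GSAResult:
    table: pd.DataFrame          # per set: score, p, fdr, n_present
    nperm: int
    seed: int | None
    skipped: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["p"] <= alpha])


def _t_stats(X: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Pooled two-sample t per feature for each membership vector.

    X: (m, n); members: (B, n) boolean -> (m, B).
    """
    M = members.astype(float).T
    n1 = M.sum(axis=0)
    n = X.shape[1]
    n2 = n - n1
    sum1 = X @ M
    sumsq1 = (X ** 2) @ M
    sum2 = X.sum(axis=1, keepdims=True) - sum1
    sumsq2 = (X ** 2).sum(axis=1, keepdims=True) - sumsq1
    mean1, mean2 = sum1 / n1, sum2 / n2
    ss = (sumsq1 - sum1 ** 2 / n1) + (sumsq2 - sum2 ** 2 / n2)
    pooled_var = ss / (n1 + n2 - 2)
    denom = np.sqrt(np.maximum(pooled_var * (1.0 / n1 + 1.0 / n2), 1e-300))
    return (mean1 - mean2) / denom


def _maxmean_restandardized(z: np.ndarray, set_indices: list[np.ndarray]) -> np.ndarray:
    """Restandardized maxmean score per set for each column of z.

    z: (m, B) gene scores. The positive part a = max(z,0) and negative
    part b = max(-z,0) are averaged within the set and standardized by the
    catalogue moments mean(a), sd(a)/sqrt(k) (likewise b); the score is
    the signed larger of the two.
    """
    a = np.maximum(z, 0.0)
    b = np.maximum(-z, 0.0)
    mu_a, sd_a = a.mean(axis=0), a.std(axis=0, ddof=1)
    mu_b, sd_b = b.mean(axis=0), b.std(axis=0, ddof=1)
    sd_a = np.where(sd_a == 0, 1e-300, sd_a)
    sd_b = np.where(sd_b == 0, 1e-300, sd_b)
    out = np.empty((len(set_indices), z.shape[1]))
    for i, idx in enumerate(set_indices):
        k = len(idx)
        s_plus = a[idx].mean(axis=0)
        s_minus = b[idx].mean(axis=0)
        z_plus = (s_plus - mu_a) / (sd_a / np.sqrt(k))
        z_minus = (s_minus - mu_b) / (sd_b / np.sqrt(k))
        out[i] = np.where(z_plus >= z_minus, z_plus, -z_minus)
    return out


def gsa_maxmean(bundle: ExpressionBundle | pd.DataFrame, contrast,
                collection: GeneSetCollection, nperm: int = 1000,
                seed: int | None = None, min_present: int = 5) -> GSAResult:
    """Score every gene set against a subtype-vs-rest contrast.

    ``contrast`` is a boolean vector/Series (True = samples of the
    subtype). Sets with fewer than ``min_present`` member genes in the
    matrix are skipped with a warning; FDR (Benjamini-Hochberg) is
    computed across all sets actually tested.
    """
    values = bundle.values if isinstance(bundle, ExpressionBundle) else bundle
    y = np.asarray(pd.Series(contrast).reindex(values.columns)
                   if isinstance(contrast, pd.Series) else contrast, dtype=bool)
    n1, n = int(y.sum()), len(y)
    if n1 < 2 or n - n1 < 2:
        raise BundleError(f"need >= 2 samples per side, got {n1} vs {n - n1}")
    X = values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise BundleError("GSA requires a complete matrix")
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(values.index)}

    tested_ids, set_indices, n_present, skipped = [], [], [], []
    for s in collection:
        idx = np.array([gene_pos[g] for g in s.genes if g in gene_pos], dtype=int)
        if len(idx) == 0:
            skipped.append(s.set_id)
            log.warning("set %s: no member gene present; untested", s.set_id)
        elif len(idx) < min_present:
            skipped.append(s.set_id)
            log.warning("set %s: only %d member(s) present (< %d); skipped",
                        s.set_id, len(idx), min_present)
        else:
            tested_ids.append(s.set_id)
            set_indices.append(idx)
            n_present.append(len(idx))
    if not tested_ids:
        raise BundleError("no gene set has enough members present")

    z_obs = _t_stats(X, y[None, :])
    score_obs = _maxmean_restandardized(z_obs, set_indices)[:, 0]

    exceed = np.zeros(len(tested_ids))
    done = 0
    chunk = max(1, min(nperm, int(2e8 / (X.shape[0] * max(n, 1)))))
    while done < nperm:
        bsize = min(chunk, nperm - done)
        perms = np.zeros((bsize, n), dtype=bool)
        for i in range(bsize):
            perms[i, rng.choice(n, size=n1, replace=False)] = True
        z_perm = _t_stats(X, perms)
        scores = _maxmean_restandardized(z_perm, set_indices)
        exceed += (scores >= score_obs[:, None]).sum(axis=1)
        done += bsize
    p = (1.0 + exceed) / (nperm + 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"score": score_obs, "p": p, "fdr": fdr,
                          "n_present": n_present}, index=tested_ids)
    table.index.name = "set_id"
    return GSAResult(table=table, nperm=nperm, seed=seed, skipped=skipped)
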