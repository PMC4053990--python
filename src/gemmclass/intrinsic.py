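"""Intrinsic gene list derivation.

A gene is "intrinsic" when it varies little within groups of related tumors
but strongly between groups. Groups come from an unsupervised cluster of
the most variable probes (correlation threshold on dendrogram nodes); each
gene is then scored by the ratio of its mean within-group variance to its
variance across all grouped samples, and genes scoring more than
``intrinsic_sd_cutoff`` standard deviations below the mean score are kept.
Lower score = more intrinsic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import BundleError, ExpressionBundle

log = logging.getLogger("gemmclass")


class FilterError(ValueError):
    pass


def unsupervised_filter(bundle: ExpressionBundle, min_obs: int = 3,
                        abs_log2: float = 3.0) -> ExpressionBundle:
    """Keep features with >= ``min_obs`` observations of |log2 ratio| > ``abs_log2``."""
    vals = bundle.values.to_numpy()
    with np.errstate(invalid="ignore"):
        qualifying = (np.abs(vals) > abs_log2) & np.isfinite(vals)
    keep = qualifying.sum(axis=1) >= min_obs
    if not keep.any():
        raise FilterError(
            f"no feature has {min_obs} observations with |log2| > {abs_log2}; "
            "relax unsup_min_obs / unsup_abs_log2")
    log.info("unsupervised filter kept %d/%d features", int(keep.sum()), len(keep))
    return bundle.with_values(bundle.values.loc[keep])


def adaptive_group_threshold(tree, r_min: float) -> tuple[float, list[list[str]]]:
    """Sample groups for intrinsic scoring, with a principled fallback.

    Uses the configured node-correlation threshold when it yields at least
    two usable groups (>= 2 members). Otherwise — on data whose
    correlation scale sits below the configured cutoff, where dendrogram
    nodes form by single-sample absorption and never reach it — falls back
    to the threshold that maximizes the number of usable groups (ties go
    to the highest threshold). The fallback is logged.
    """
    from .cluster import extract_groups  # local import to avoid a cycle

    groups = extract_groups(tree, r_min)
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) >= 2:
        return r_min, groups

    def key(gs):
        us = [g for g in gs if len(g) >= 2]
        return len(us), sum(len(g) for g in us)

    candidates = sorted({round(r, 12) for _, _, r in tree.merges}, reverse=True)
    best_t, best_groups, best_key = r_min, groups, key(groups)
    for t in candidates:
        if t >= r_min:
            continue
        g = extract_groups(tree, t)
        k = key(g)
        if k > best_key:
            best_t, best_groups, best_key = t, g, k
    if best_t != r_min:
        log.warning("no sample group at node r >= %.2f; falling back to "
                    "r >= %.4f (%d usable groups over %d samples)",
                    r_min, best_t, *best_key)
    return best_t, best_groups


@dataclass
class IntrinsicResult:
    """Per-gene intrinsic scores and the mean − k·SD selection."""

    groups: list[list[str]]
    scores: pd.Series
    score_mean: float
    score_sd: float
    sd_cutoff: float
    selected: list[str] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        return self.score_mean - self.sd_cutoff * self.score_sd


def intrinsic_scores(bundle: ExpressionBundle, groups: list[list[str]],
                     sd_cutoff: float = 1.0) -> IntrinsicResult:
    """Score genes by within-group / between-group variability over ``groups``.

    For gene g: W(g) = mean over groups (with >= 2 members) of the
    within-group sample variance; B(g) = variance of g over all grouped
    samples; score(g) = W(g)/B(g). Genes with B(g) = 0 are scored 1
    (uninformative). Selection keeps score < mean − sd_cutoff·SD.
    """
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) < 2:
        raise BundleError("need >= 2 groups with >= 2 members to score genes")
    grouped_samples = [s for g in usable for s in g]
    if len(set(grouped_samples)) != len(grouped_samples):
        raise BundleError("groups are not disjoint")

    X = bundle.values[grouped_samples].to_numpy(dtype=float)
    within = np.zeros(X.shape[0])
    start = 0
    for g in usable:
        block = X[:, start:start + len(g)]
        within += np.nanvar(block, axis=1, ddof=1)
        start += len(g)
    within /= len(usable)
    between = np.nanvar(X, axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        score = within / between
    degenerate = ~np.isfinite(score)
    if degenerate.any():
        log.warning("%d gene(s) with zero overall variance scored 1",
                    int(degenerate.sum()))
        score = np.where(degenerate, 1.0, score)

    scores = pd.Series(score, index=bundle.values.index, name="intrinsic_score")
    mean, sd = float(scores.mean()), float(scores.std(ddof=1))
    threshold = mean - sd_cutoff * sd
    selected = list(scores.index[scores < threshold])
    log.info("intrinsic selection: %d/%d genes below %.4f",
             len(selected), len(scores), threshold)
    return IntrinsicResult(groups=usable, scores=scores, score_mean=mean,
                           score_sd=sd, sd_cutoff=sd_cutoff, selected=selected)
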