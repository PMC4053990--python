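"""Multi-platform assembly: intensity filtering, KNN imputation, probe
intersection, bridge normalization, and median centering.

Arrays from different two-color platforms are made comparable through
"bridge" samples — tumors from two homogeneous models hybridized on every
platform. Per probe and platform, an additive (log2) normalization factor
shifts that platform's columns so the median over its bridge arrays equals
a common per-probe target; a PCA check then verifies that platform no
longer explains the leading variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer

from .bundle import BundleError, ExpressionBundle

log = logging.getLogger("gemmclass")


def filter_probes(bundle: ExpressionBundle, intensity_min: float = 10.0,
                  presence_min: float = 0.70) -> ExpressionBundle:
    """Mask entries whose channel intensities are not both > ``intensity_min``,
    then drop probes present on <= ``presence_min`` of the arrays."""
    if bundle.cy5 is None or bundle.cy3 is None:
        raise BundleError(
            "no channel intensities: this stage applies to raw two-color "
            "array data; skip it for gene-level matrices")
    ok = (bundle.cy5.to_numpy() > intensity_min) & (bundle.cy3.to_numpy() > intensity_min)
    vals = bundle.values.to_numpy(dtype=float).copy()
    vals[~ok] = np.nan
    present = np.isfinite(vals).mean(axis=1)
    keep = present > presence_min
    log.info("intensity filter: masked %d entries, dropped %d/%d probes",
             int((~ok & np.isfinite(bundle.values.to_numpy())).sum()),
             int((~keep).sum()), len(keep))
    values = pd.DataFrame(vals, index=bundle.values.index,
                          columns=bundle.values.columns).loc[keep]
    out = ExpressionBundle(values, bundle.sample_annotations.copy(),
                           bundle.cy5.loc[keep], bundle.cy3.loc[keep])
    return out


def impute_knn(bundle: ExpressionBundle, k: int = 10) -> ExpressionBundle:
    """Fill missing entries with the unweighted mean of the ``k`` nearest
    features (Euclidean distance over mutually observed samples, scaled by
    the number of shared observations)."""
    X = bundle.values.to_numpy(dtype=float)
    all_missing = ~np.isfinite(X).any(axis=1)
    if all_missing.any():
        bad = [str(f) for f, m in zip(bundle.feature_ids, all_missing) if m]
        raise BundleError(f"feature(s) entirely missing, cannot impute: "
                          f"{', '.join(bad[:10])}")
    if np.isfinite(X).all():
        return bundle.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(X)  # rows = features, imputes along samples
    n_imputed = int((~np.isfinite(X)).sum())
    log.info("imputed %d missing entries with %d-NN", n_imputed, k)
    values = pd.DataFrame(filled, index=bundle.values.index,
                          columns=bundle.values.columns)
    return ExpressionBundle(values, bundle.sample_annotations.copy(),
                            bundle.cy5, bundle.cy3)


def intersect_platforms(bundles: list[ExpressionBundle]) -> list[ExpressionBundle]:
    """Restrict every bundle to the probes present on all platforms.

    Feature order follows the first bundle.
    """
    if len(bundles) < 2:
        raise BundleError("need at least 2 platform bundles to intersect")
    common = set(bundles[0].feature_ids)
    for b in bundles[1:]:
        common &= set(b.feature_ids)
    if not common:
        raise BundleError("no probe is shared by all platforms")
    order = [f for f in bundles[0].feature_ids if f in common]
    log.info("probe intersection: %d common probes", len(order))
    return [b.subset_features(order) for b in bundles]


@dataclass
class BridgeNormResult:
    combined: ExpressionBundle
    normalization_factor: pd.DataFrame  # probe x platform additive shifts
    target_median: pd.Series            # per-probe common bridge median
    pca_report: dict


def bridge_normalize(bundles: list[ExpressionBundle],
                     bridge_ids: list[list[str]],
                     pca_r2_max: float = 0.25) -> BridgeNormResult:
    """Equalize per-probe bridge medians across platforms and merge.

    For probe p on platform t the shift is NF(p,t) = target(p) − median of
    p over platform t's bridge arrays, where target(p) is the median of the
    per-platform bridge medians. All of platform t's columns move by
    NF(p,t); afterwards each platform's bridge median equals target(p)
    exactly.
    """
    if len(bundles) != len(bridge_ids):
        raise BundleError("one bridge id list per platform bundle required")
    features = bundles[0].feature_ids
    for b in bundles[1:]:
        if b.feature_ids != features:
            raise BundleError("bundles must share an identical probe list; "
                              "run intersect_platforms first")
    platform_names = []
    medians = []
    for b, ids in zip(bundles, bridge_ids):
        if not ids:
            raise BundleError("every platform needs at least one bridge array")
        missing = [s for s in ids if s not in b.values.columns]
        if missing:
            raise BundleError(f"bridge id(s) not in platform: {missing[:5]}")
        bridge = b.values[ids].to_numpy(dtype=float)
        all_nan = ~np.isfinite(bridge).any(axis=1)
        if all_nan.any():
            bad = [features[i] for i in np.where(all_nan)[0][:10]]
            raise BundleError(f"probe(s) with all-missing bridge values: {bad}")
        medians.append(np.nanmedian(bridge, axis=1))
        platform_names.append(str(b.sample_annotations["platform"].iloc[0]))
    med = np.column_stack(medians)                    # probe x platform
    target = np.median(med, axis=1)
    nf = target[:, None] - med

    shifted = []
    for t, b in enumerate(bundles):
        vals = b.values.add(pd.Series(nf[:, t], index=b.values.index), axis=0)
        shifted.append(ExpressionBundle(vals, b.sample_annotations.copy()))
    combined_values = pd.concat([s.values for s in shifted], axis=1)
    combined_ann = pd.concat([s.sample_annotations for s in shifted], axis=0)
    combined = ExpressionBundle(combined_values, combined_ann)

    nf_df = pd.DataFrame(nf, index=features, columns=platform_names)
    log.info("bridge normalization: mean |NF| = %.4f", float(np.abs(nf).mean()))
    report = pca_verify(combined, r2_max=pca_r2_max)
    return BridgeNormResult(combined=combined, normalization_factor=nf_df,
                            target_median=pd.Series(target, index=features),
                            pca_report=report)


def median_center_rows(bundle: ExpressionBundle) -> ExpressionBundle:
    """Subtract each feature's median; idempotent."""
    vals = bundle.values.to_numpy(dtype=float)
    centered = vals - np.nanmedian(vals, axis=1, keepdims=True)
    values = pd.DataFrame(centered, index=bundle.values.index,
                          columns=bundle.values.columns)
    return ExpressionBundle(values, bundle.sample_annotations.copy(),
                            bundle.cy5, bundle.cy3)


def pca_verify(bundle: ExpressionBundle, n_components: int = 2,
               r2_max: float = 0.25) -> dict:
    """How much of the leading principal components does platform explain?

    Projects samples onto the first two PCs and reports the variance-
    weighted one-way R² of platform label on the scores. A value above
    ``r2_max`` flags residual platform structure.
    """
    if bundle.n_samples < 3:
        raise BundleError("PCA verification needs >= 3 samples")
    X = bundle.values.to_numpy(dtype=float).T  # samples x features
    if not np.isfinite(X).all():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isfinite(X), X, col_means[None, :])
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    platforms = bundle.sample_annotations["platform"].to_numpy()
    labels = pd.unique(platforms)
    if len(labels) < 2:
        r2_combined = 0.0
        r2_per_pc = [0.0] * n_components
    else:
        r2_per_pc = []
        for j in range(n_components):
            s = scores[:, j]
            total = np.sum((s - s.mean()) ** 2)
            between = sum(len(s[platforms == g]) * (s[platforms == g].mean() - s.mean()) ** 2
                          for g in labels)
            r2_per_pc.append(0.0 if total == 0 else float(between / total))
        weights = pca.explained_variance_[:n_components]
        if weights.sum() == 0:
            r2_combined = float(np.mean(r2_per_pc))
        else:
            r2_combined = float(np.average(r2_per_pc, weights=weights))
    report = {
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio_],
        "platform_r2_per_pc": r2_per_pc,
        "platform_r2": r2_combined,
        "flag": bool(r2_combined > r2_max),
        "threshold": r2_max,
    }
    if report["flag"]:
        log.warning("PCA check: platform explains %.2f of leading PCs "
                    "(threshold %.2f)", r2_combined, r2_max)
    return report
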