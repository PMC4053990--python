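"""Cross-species integration and human-subtype counterpart calling.

Mouse and human matrices are collapsed to shared 1:1 ortholog identifiers
(probe rows averaged per gene), standardized per species (tumors, then
genes, to mean 0 / SD 1), merged over the ortholog intersection and
median-centered per gene. Counterparts are then called by scoring each
mouse class's ortholog signature against every human subtype-vs-rest
contrast with GSA in each human cohort: a mouse class is a counterpart of
a subtype when the enrichment is significant (p <= alpha) in at least
``counterpart_min_datasets`` of the cohorts; set-level FDR is reported as
a strength qualifier, not a gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import (BundleError, ExpressionBundle, FeatureMap, GeneSet,
                     GeneSetCollection)
from .config import PipelineConfig
from .gsa import GSAResult, gsa_maxmean

log = logging.getLogger("gemmclass")


def collapse_orthologs(bundle: ExpressionBundle, feature_map: FeatureMap) -> ExpressionBundle:
    """Average feature rows to one row per shared ortholog identifier.

    Mouse features pass through probe→gene first (features not in the
    probe map are taken as gene symbols), then gene→ortholog; human
    features must be gene symbols on the human side of the ortholog map.
    Unmapped features are dropped (count logged).
    """
    species = str(bundle.sample_annotations["species"].iloc[0])
    if species == "mouse":
        def to_ortholog(feature: str) -> str | None:
            gene = feature_map.probe_to_gene.get(feature, feature)
            return feature_map.orthologs.get(gene)
    else:
        human_side = set(feature_map.orthologs.values())

        def to_ortholog(feature: str) -> str | None:
            gene = feature_map.probe_to_gene.get(feature, feature)
            return gene if gene in human_side else None

    mapped = {f: to_ortholog(f) for f in bundle.feature_ids}
    kept = {f: o for f, o in mapped.items() if o is not None}
    if not kept:
        raise BundleError("no feature maps to a shared ortholog")
    dropped = len(mapped) - len(kept)
    if dropped:
        log.info("ortholog collapse (%s): dropped %d unmapped feature(s)",
                 species, dropped)
    sub = bundle.values.loc[list(kept)]
    collapsed = sub.groupby(pd.Series(kept), sort=True).mean()
    collapsed.index.name = "ortholog"
    return ExpressionBundle(collapsed, bundle.sample_annotations.copy())


def standardize_species(bundle: ExpressionBundle, iterate: bool = False,
                        tol: float = 1e-6, max_iter: int = 100) -> ExpressionBundle:
    """Standardize tumors (columns) then genes (rows) to mean 0 / SD 1.

    One pass by default; ``iterate=True`` alternates column and row
    standardization until the largest deviation from N(0,1) moments falls
    below ``tol``. Zero-variance rows or columns are an error.
    """
    if bundle.n_features < 2 or bundle.n_samples < 2:
        raise BundleError("standardization needs >= 2 genes and >= 2 samples")
    X = bundle.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise BundleError("standardization requires a complete matrix")
    col_sd = X.std(axis=0, ddof=0)
    row_sd = X.std(axis=1, ddof=0)
    zero_cols = [str(c) for c, s in zip(bundle.sample_ids, col_sd) if s == 0]
    zero_rows = [str(r) for r, s in zip(bundle.feature_ids, row_sd) if s == 0]
    if zero_cols or zero_rows:
        raise BundleError(f"zero-variance rows {zero_rows[:5]} / "
                          f"columns {zero_cols[:5]}")

    def one_pass(A: np.ndarray) -> np.ndarray:
        A = (A - A.mean(axis=0)) / A.std(axis=0, ddof=0)
        A = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, ddof=0, keepdims=True)
        return A

    X = one_pass(X)
    if iterate:
        for _ in range(max_iter):
            dev = max(np.abs(X.mean(axis=0)).max(), np.abs(X.std(axis=0, ddof=0) - 1).max(),
                      np.abs(X.mean(axis=1)).max(), np.abs(X.std(axis=1, ddof=0) - 1).max())
            if dev < tol:
                break
            X = one_pass(X)
    assert np.abs(X.mean(axis=1)).max() < 1e-8
    assert np.abs(X.std(axis=1, ddof=0) - 1).max() < 1e-8
    values = pd.DataFrame(X, index=bundle.values.index, columns=bundle.values.columns)
    return ExpressionBundle(values, bundle.sample_annotations.copy())


def merge_species(mouse: ExpressionBundle, human: ExpressionBundle) -> ExpressionBundle:
    """Concatenate species over their ortholog intersection; median-center rows."""
    common = mouse.values.index.intersection(human.values.index)
    if len(common) == 0:
        raise BundleError("no ortholog shared between the species matrices")
    log.info("species merge: %d shared ortholog genes", len(common))
    values = pd.concat([mouse.values.loc[common], human.values.loc[common]], axis=1)
    values = values.sub(values.median(axis=1), axis=0)
    ann = pd.concat([mouse.sample_annotations, human.sample_annotations])
    return ExpressionBundle(values, ann)


def combined_intrinsic_union(mouse_list, human_list) -> list[str]:
    """Set union of the two species' intrinsic lists on ortholog ids."""
    return sorted(set(mouse_list) | set(human_list))


# ---------------------------------------------------------------------------
# counterpart calling
# ---------------------------------------------------------------------------

@dataclass
class CounterpartTable:
    """Per (mouse class, human subtype, dataset) GSA evidence and the calls."""

    table: pd.DataFrame                 # columns: class, subtype, dataset, p, fdr, significant
    calls: dict[str, list[str]]         # mouse class -> counterpart subtypes
    support: pd.DataFrame               # class x subtype count of significant datasets
    strong: pd.DataFrame | None = None  # class x subtype count also passing FDR

    def called_pairs(self) -> list[tuple[str, str]]:
        return [(c, s) for c, subs in sorted(self.calls.items()) for s in subs]

    def to_tsv(self, path) -> None:
        wide = self.table.pivot_table(index="class", columns=["subtype", "dataset"],
                                      values="p", sort=False)
        wide["counterpart"] = [" and ".join(self.calls.get(c, [])) for c in wide.index]
        wide.to_csv(path, sep="\t", float_format="%.4g")


def call_counterparts(gsa_pvalues: dict[str, pd.DataFrame],
                      config: PipelineConfig | None = None,
                      gsa_fdr_values: dict[str, pd.DataFrame] | None = None
                      ) -> CounterpartTable:
    """Apply the replication rule to per-dataset GSA p-values.

    ``gsa_pvalues[dataset]`` is a class x subtype DataFrame of one-sided
    enrichment p-values; NaN marks an untested cell, which counts as
    non-significant. A counterpart is called when p <= gsa_alpha in at
    least ``counterpart_min_datasets`` datasets. FDR values, when given,
    feed the ``strong`` qualifier table only.
    """
    config = config or PipelineConfig()
    if len(gsa_pvalues) < 2:
        raise BundleError("counterpart calling needs >= 2 human datasets")
    datasets = list(gsa_pvalues)
    classes = list(gsa_pvalues[datasets[0]].index)
    subtypes = list(gsa_pvalues[datasets[0]].columns)

    rows = []
    support = pd.DataFrame(0, index=classes, columns=subtypes)
    strong = pd.DataFrame(0, index=classes, columns=subtypes)
    for ds in datasets:
        pv = gsa_pvalues[ds]
        fv = gsa_fdr_values.get(ds) if gsa_fdr_values else None
        for c in classes:
            for s in subtypes:
                p = pv.loc[c, s] if (c in pv.index and s in pv.columns) else np.nan
                sig = bool(np.isfinite(p) and p <= config.gsa_alpha)
                f = fv.loc[c, s] if fv is not None and c in fv.index else np.nan
                rows.append((c, s, ds, p, f, sig))
                if sig:
                    support.loc[c, s] += 1
                    if np.isfinite(f) and f <= config.gsa_fdr:
                        strong.loc[c, s] += 1
    table = pd.DataFrame(rows, columns=["class", "subtype", "dataset",
                                        "p", "fdr", "significant"])
    calls = {c: [s for s in subtypes
                 if support.loc[c, s] >= config.counterpart_min_datasets]
             for c in classes}
    calls = {c: subs for c, subs in calls.items() if subs}
    return CounterpartTable(table=table, calls=calls, support=support,
                            strong=strong if gsa_fdr_values else None)


def counterpart_gsa(mouse_signatures: dict[str, GeneSet],
                    human_bundles: dict[str, ExpressionBundle],
                    config: PipelineConfig | None = None,
                    seed: int | None = None) -> tuple[CounterpartTable, dict[str, GSAResult]]:
    """Score mouse class signatures against every human subtype contrast.

    Signatures must already be on ortholog identifiers shared with the
    human matrices (collapse_orthologs). Subtype labels are taken from
    each human bundle's ``model_or_subtype`` annotation.
    """
    config = config or PipelineConfig()
    base_seed = config.seed if seed is None else seed
    collection = GeneSetCollection(
        [s for s in mouse_signatures.values() if s.genes])
    pvals: dict[str, pd.DataFrame] = {}
    fdrs: dict[str, pd.DataFrame] = {}
    details: dict[str, GSAResult] = {}
    for k, (ds, bundle) in enumerate(sorted(human_bundles.items())):
        subtypes = sorted(bundle.sample_annotations["model_or_subtype"].unique())
        pv = pd.DataFrame(np.nan, index=list(mouse_signatures), columns=subtypes)
        fv = pd.DataFrame(np.nan, index=list(mouse_signatures), columns=subtypes)
        for j, subtype in enumerate(subtypes):
            contrast = bundle.sample_annotations["model_or_subtype"] == subtype
            res = gsa_maxmean(bundle, contrast, collection,
                              nperm=config.gsa_nperm,
                              seed=base_seed + 1009 * k + 31 * j)
            details[f"{ds}:{subtype}"] = res
            for c in res.table.index:
                pv.loc[c, subtype] = res.table.loc[c, "p"]
                fv.loc[c, subtype] = res.table.loc[c, "fdr"]
        pvals[ds] = pv
        fdrs[ds] = fv
    return call_counterparts(pvals, config, fdrs), details
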