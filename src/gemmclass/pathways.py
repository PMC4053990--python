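"""Pathway signature scoring, class-enriched pathways, meta-signatures, and
cross-species conserved pathways.

A pathway's score in a sample is the median expression of its member genes
present in the gene-collapsed, cross-species-common matrix. Pathways
enriched in a class or subtype are found by running two-class SAM on the
pathway-score matrix (up-regulated at FDR 0%); the enriched pathways of a
mouse class form its meta-signature, whose per-sample average is compared
across human subtypes. A pathway is conserved for a counterpart pair when
it is enriched in the mouse class and in the human subtype in every human
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import BundleError, ExpressionBundle, GeneSet, GeneSetCollection
from .config import PipelineConfig
from .sam import sam_two_class

log = logging.getLogger("gemmclass")


@dataclass
class SignatureScoreMatrix:
    scores: pd.DataFrame          # signature x sample medians
    n_genes_found: pd.Series
    skipped: list[str] = field(default_factory=list)
    low_confidence: list[str] = field(default_factory=list)


def score_signatures(bundle: ExpressionBundle, collection: GeneSetCollection,
                     low_confidence_min: int = 3) -> SignatureScoreMatrix:
    """Median expression of each signature's present genes, per sample.

    Signatures with no gene present are skipped (logged); those with fewer
    than ``low_confidence_min`` present genes are scored but flagged.
    """
    if len(collection) == 0:
        raise BundleError("empty signature collection")
    values = bundle.values
    index = set(values.index)
    rows, found, ids, skipped, low = [], [], [], [], []
    for s in collection:
        present = [g for g in s.genes if g in index]
        if not present:
            skipped.append(s.set_id)
            log.warning("signature %s: no gene present; skipped", s.set_id)
            continue
        if len(present) < low_confidence_min:
            low.append(s.set_id)
        rows.append(values.loc[present].median(axis=0).to_numpy())
        found.append(len(present))
        ids.append(s.set_id)
    if not ids:
        raise BundleError("no signature has a member gene in the matrix")
    scores = pd.DataFrame(rows, index=ids, columns=values.columns)
    scores.index.name = "signature"
    return SignatureScoreMatrix(scores=scores,
                                n_genes_found=pd.Series(found, index=ids),
                                skipped=skipped, low_confidence=low)


def enriched_pathways(score_matrix: SignatureScoreMatrix | pd.DataFrame,
                      labels, config: PipelineConfig | None = None,
                      seed: int | None = None,
                      set_id: str = "enriched") -> GeneSet:
    """Pathways up-regulated in the labeled group at the configured SAM FDR."""
    config = config or PipelineConfig()
    scores = score_matrix.scores if isinstance(score_matrix, SignatureScoreMatrix) \
        else score_matrix
    res = sam_two_class(scores, labels, nperm=config.sam_nperm,
                        seed=config.seed if seed is None else seed)
    ids = res.significant_up(config.sam_fdr_select)
    if not ids:
        log.warning("%s: no pathway enriched at FDR <= %s",
                    set_id, config.sam_fdr_select)
    return GeneSet(set_id=set_id, description="pathways up at SAM FDR cutoff",
                   genes=ids)


@dataclass
class MetaSignature:
    class_id: str
    members: list[str]
    values: pd.Series              # standardized per-sample averages

    def subtype_summary(self, subtype_labels: pd.Series) -> pd.DataFrame:
        """Median and quartiles of the meta-signature per subtype."""
        df = pd.DataFrame({"value": self.values,
                           "subtype": subtype_labels.loc[self.values.index]})
        return df.groupby("subtype")["value"].quantile([0.25, 0.5, 0.75]).unstack()


def meta_signature(human_scores: SignatureScoreMatrix | pd.DataFrame,
                   pathway_set: GeneSet | list[str],
                   class_id: str | None = None) -> MetaSignature:
    """Average the member pathways' score rows per sample, standardized."""
    scores = human_scores.scores if isinstance(human_scores, SignatureScoreMatrix) \
        else human_scores
    ids = pathway_set.genes if isinstance(pathway_set, GeneSet) else list(pathway_set)
    present = [p for p in ids if p in scores.index]
    if not present:
        raise BundleError("no member pathway present in the score matrix")
    avg = scores.loc[present].mean(axis=0)
    sd = avg.std(ddof=0)
    if sd == 0:
        raise BundleError("meta-signature is constant across samples")
    std = (avg - avg.mean()) / sd
    name = class_id or (pathway_set.set_id if isinstance(pathway_set, GeneSet)
                        else "meta")
    return MetaSignature(class_id=name, members=present, values=std)


def conserved_pathways(mouse_enriched: dict[str, GeneSet | list[str]],
                       human_enriched: dict[str, dict[str, GeneSet | list[str]]],
                       counterparts: list[tuple[str, str]]
                       ) -> dict[tuple[str, str], list[str]]:
    """Pathways enriched in a mouse class AND in its counterpart subtype in
    every human dataset.

    ``human_enriched[dataset][subtype]`` holds each dataset's enriched
    pathway ids. Pairs lacking the subtype in some dataset yield an empty
    intersection for that pair.
    """
    def as_set(x) -> set[str]:
        return set(x.genes if isinstance(x, GeneSet) else x)

    out: dict[tuple[str, str], list[str]] = {}
    for mouse_class, subtype in counterparts:
        conserved = as_set(mouse_enriched.get(mouse_class, []))
        for ds, per_subtype in human_enriched.items():
            conserved &= as_set(per_subtype.get(subtype, []))
        out[(mouse_class, subtype)] = sorted(conserved)
    return out
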