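"""Shared fixtures: a small synthetic world reused by cross-module tests."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import gemmclass as gc
from gemmclass.synthetic import ModelSpec

logging.getLogger("gemmclass").setLevel(logging.ERROR)


def small_synth_config(seed: int = 3) -> gc.SyntheticConfig:
    """A three-class, reduced-scale cohort for fast structural tests."""
    return gc.SyntheticConfig(
        n_genes=400, class_signature_size=25, mouse_classes=3, n_pathways=40,
        planted_per_class=2, pathway_size=20, planted_signature_members=12,
        models=[ModelSpec("A", (1.0, 0, 0), 8), ModelSpec("B", (0, 1.0, 0), 8),
                ModelSpec("C", (0, 0, 1.0), 8), ModelSpec("D", (0.5, 0.3, 0.2), 9)],
        bridge_models=("A", "B"), n_bridge_per_platform=(3, 3),
        human_datasets=(("humanA", 48), ("humanB", 48), ("humanC", 48)),
        shared_programs=((0, 0, 15), (1, 1, 15)), seed=seed)


@pytest.fixture(scope="session")
def small_world():
    """Mouse + human cohorts, pathways, and truth at reduced scale."""
    return gc.generate_all(small_synth_config())


@pytest.fixture(scope="session")
def small_config():
    return gc.PipelineConfig(seed=3, sigclust_nsim=200, sam_nperm=300,
                             gsa_nperm=300)


@pytest.fixture(scope="session")
def mouse_gene_bundle(small_world):
    """Imputed, ortholog-collapsed mouse matrix with planted class labels."""
    truth = small_world["truth"]
    comb = pd.concat([b.values for b in small_world["mouse"]], axis=1)
    ann = pd.concat([b.sample_annotations for b in small_world["mouse"]])
    bundle = gc.impute_knn(gc.ExpressionBundle(comb, ann), 10)
    genes = gc.collapse_orthologs(bundle, truth.feature_map)
    labels = pd.Series({s: truth.class_of_sample[s] for s in genes.sample_ids})
    return genes, labels


def toy_bundle(values, feature_ids=None, sample_ids=None, **ann_cols):
    m, n = np.asarray(values).shape
    features = feature_ids or [f"f{i}" for i in range(m)]
    samples = sample_ids or [f"s{j}" for j in range(n)]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=features,
                      columns=samples)
    ann = pd.DataFrame(index=samples)
    for k, v in ann_cols.items():
        ann[k] = v
    return gc.ExpressionBundle(df, ann if ann_cols else None)
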