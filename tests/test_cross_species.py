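"""Ortholog collapsing, standardization, merging, GSA, counterpart calls."""

import numpy as np
import pandas as pd
import pytest

import gemmclass as gc
from gemmclass.bundle import BundleError, FeatureMap, GeneSet, GeneSetCollection
from conftest import toy_bundle


def _mouse_bundle(values, feature_ids):
    return toy_bundle(values, feature_ids=feature_ids, species="mouse")


class TestCollapseOrthologs:
    FMAP = FeatureMap(probe_to_gene={"p1": "mA", "p2": "mA", "p3": "mB"},
                      orthologs={"mA": "hA", "mB": "hB"})

    def test_single_probe_row_unchanged(self):
        b = _mouse_bundle([[1.0, 2.0], [9.0, 9.0]], ["p3", "junk"])
        out = gc.collapse_orthologs(b, self.FMAP)
        assert out.feature_ids == ["hB"]
        np.testing.assert_allclose(out.values.loc["hB"], [1.0, 2.0])

    def test_two_probes_averaged_elementwise(self):
        b = _mouse_bundle([[1.0, 2.0], [3.0, 6.0]], ["p1", "p2"])
        out = gc.collapse_orthologs(b, self.FMAP)
        np.testing.assert_allclose(out.values.loc["hA"], [2.0, 4.0])

    def test_row_count_equals_distinct_orthologs(self, small_world):
        truth = small_world["truth"]
        b = small_world["mouse"][0]
        out = gc.collapse_orthologs(gc.impute_knn(b, 5), truth.feature_map)
        expected = {truth.feature_map.orthologs[truth.feature_map.probe_to_gene[p]]
                    for p in b.feature_ids
                    if truth.feature_map.probe_to_gene[p] in truth.feature_map.orthologs}
        assert set(out.feature_ids) == expected

    def test_human_side_passthrough(self, small_world):
        h = small_world["human"][0]
        out = gc.collapse_orthologs(h, small_world["truth"].feature_map)
        # human-only genes dropped, ortholog genes kept unchanged
        assert all(g.startswith("HGENE") for g in out.feature_ids)
        kept = out.feature_ids[0]
        np.testing.assert_allclose(out.values.loc[kept], h.values.loc[kept])

    def test_empty_overlap_rejected(self):
        b = _mouse_bundle([[1.0, 2.0]], ["junk"])
        with pytest.raises(BundleError):
            gc.collapse_orthologs(b, self.FMAP)


class TestStandardize:
    def test_three_by_three_hand_computed(self):
        vals = np.array([[1.0, 2.0, 3.0],
                         [4.0, 6.0, 8.0],
                         [9.0, 7.0, 2.0]])
        # columns first, then rows, population SD
        c = (vals - vals.mean(0)) / vals.std(0)
        expected = (c - c.mean(1, keepdims=True)) / c.std(1, keepdims=True)
        out = gc.standardize_species(toy_bundle(vals))
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-12)

    def test_postconditions_on_random_input(self):
        rng = np.random.default_rng(0)
        out = gc.standardize_species(toy_bundle(rng.normal(size=(40, 25))))
        X = out.values.to_numpy()
        assert np.abs(X.mean(axis=1)).max() < 1e-8
        assert np.abs(X.std(axis=1) - 1).max() < 1e-8

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        first = gc.standardize_species(toy_bundle(rng.normal(size=(30, 20))),
                                       iterate=True)
        again = gc.standardize_species(first)
        np.testing.assert_allclose(first.values.to_numpy(),
                                   again.values.to_numpy(), atol=1e-5)

    def test_zero_variance_listed(self):
        vals = np.random.default_rng(2).normal(size=(5, 4))
        vals[2] = 7.0
        with pytest.raises(BundleError, match="f2"):
            gc.standardize_species(toy_bundle(vals))


class TestMergeSpecies:
    def _pair(self):
        rng = np.random.default_rng(3)
        m = toy_bundle(rng.normal(size=(6, 8)),
                       feature_ids=[f"h{i}" for i in range(6)], species="mouse")
        h = toy_bundle(rng.normal(size=(5, 10)),
                       feature_ids=[f"h{i}" for i in range(2, 7)], species="human",
                       sample_ids=[f"hs{j}" for j in range(10)])
        return gc.standardize_species(m), gc.standardize_species(h)

    def test_intersection_and_median_centering(self):
        m, h = self._pair()
        out = gc.merge_species(m, h)
        assert out.feature_ids == [f"h{i}" for i in range(2, 6)]
        assert out.n_samples == 18
        assert np.abs(np.median(out.values.to_numpy(), axis=1)).max() < 1e-12
        assert set(out.sample_annotations["species"]) == {"mouse", "human"}

    def test_disjoint_genes_rejected(self):
        rng = np.random.default_rng(4)
        m = gc.standardize_species(toy_bundle(rng.normal(size=(4, 6)),
                                              feature_ids=list("abcd")))
        h = gc.standardize_species(toy_bundle(rng.normal(size=(4, 6)),
                                              feature_ids=list("wxyz")))
        with pytest.raises(BundleError):
            gc.merge_species(m, h)

    def test_pipeline_invariant_to_affine_rescaling(self, small_world):
        """collapse -> standardize -> merge ignores per-species affine scale."""
        truth = small_world["truth"]
        mouse = gc.impute_knn(small_world["mouse"][0], 5)
        human = small_world["human"][0]

        def run(mb, hb):
            m = gc.standardize_species(gc.collapse_orthologs(mb, truth.feature_map))
            h = gc.standardize_species(gc.collapse_orthologs(hb, truth.feature_map))
            return gc.merge_species(m, h).values

        base = run(mouse, human)
        mouse2 = mouse.with_values(mouse.values * 3.0 + 1.5)
        human2 = human.with_values(human.values * 0.25 - 2.0)
        rescaled = run(mouse2, human2)
        np.testing.assert_allclose(base.to_numpy(), rescaled.to_numpy(),
                                   atol=1e-8)

    def test_shared_programs_correlate_across_species(self, small_world,
                                                      mouse_gene_bundle):
        truth = small_world["truth"]
        genes, labels = mouse_gene_bundle
        m = gc.standardize_species(genes)
        h = gc.standardize_species(
            gc.collapse_orthologs(small_world["human"][0], truth.feature_map))
        merged = gc.merge_species(m, h)
        ann = merged.sample_annotations
        (cname, sname), _ = next(iter(truth.shared_program_genes.items()))
        mouse_cols = [s for s in labels.index if labels[s] == cname]
        human_ids = list(ann.index[ann["species"] == "human"])
        linked_cols = [s for s in human_ids
                       if ann.loc[s, "model_or_subtype"] == sname]
        C = pd.DataFrame(np.corrcoef(merged.values.to_numpy().T),
                         index=merged.sample_ids, columns=merged.sample_ids)
        cross = C.loc[mouse_cols, linked_cols].to_numpy().mean()
        # null: the same mouse class against random human subsets
        rng = np.random.default_rng(0)
        null = [C.loc[mouse_cols,
                      rng.choice(human_ids, size=len(linked_cols),
                                 replace=False)].to_numpy().mean()
                for _ in range(200)]
        assert cross > np.quantile(null, 0.99)


class TestIntrinsicUnion:
    def test_union_examples(self):
        assert gc.combined_intrinsic_union(["A", "B"], ["B", "C"]) == ["A", "B", "C"]
        assert gc.combined_intrinsic_union([], ["X"]) == ["X"]


class TestGSA:
    def test_planted_set_significant(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(600)]
        y = np.array([True] * 15 + [False] * 30)
        X = rng.normal(size=(600, 45))
        X[:40][:, y] += 2.0
        df = pd.DataFrame(X, index=genes, columns=[f"s{j}" for j in range(45)])
        col = GeneSetCollection([GeneSet("P", "", genes[:40]),
                                 GeneSet("N", "", genes[100:140])])
        res = gc.gsa_maxmean(df, y, col, nperm=300, seed=1)
        assert res.table.loc["P", "p"] <= 0.05
        assert res.table.loc["N", "p"] > 0.05

    def test_restandardization_ignores_catalogue_padding(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(500)]
        y = np.array([True] * 12 + [False] * 24)
        X = rng.normal(size=(500, 36))
        X[:30][:, y] += 2.0
        df = pd.DataFrame(X, index=genes, columns=[f"s{j}" for j in range(36)])
        planted = GeneSet("P", "", genes[:30])
        noise_sets = [GeneSet(f"N{k}", "", list(
            np.random.default_rng(70 + k).choice(genes[30:], 30, replace=False)))
            for k in range(15)]
        r1 = gc.gsa_maxmean(df, y, GeneSetCollection([planted]), nperm=200, seed=2)
        r2 = gc.gsa_maxmean(df, y, GeneSetCollection([planted] + noise_sets),
                            nperm=200, seed=2)
        assert r1.table.loc["P", "score"] == pytest.approx(
            r2.table.loc["P", "score"])
        assert r1.table.loc["P", "p"] == r2.table.loc["P", "p"]

    def test_sparse_sets_skipped(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(50, 20)),
                          index=[f"g{i}" for i in range(50)])
        col = GeneSetCollection([GeneSet("ok", "", [f"g{i}" for i in range(10)]),
                                 GeneSet("thin", "", ["g0", "nope1", "nope2"]),
                                 GeneSet("absent", "", ["x1", "x2", "x3"])])
        res = gc.gsa_maxmean(df, [True] * 10 + [False] * 10, col,
                             nperm=50, seed=0)
        assert list(res.table.index) == ["ok"]
        assert sorted(res.skipped) == ["absent", "thin"]


class TestCallCounterparts:
    def _frames(self, cells):
        """cells: {(cls, sub): (pU, pC, pT)} -> per-dataset frames."""
        classes = sorted({c for c, _ in cells})
        subs = sorted({s for _, s in cells})
        frames = {}
        for d, ds in enumerate(["U", "C", "T"]):
            df = pd.DataFrame(np.nan, index=classes, columns=subs)
            for (c, s), ps in cells.items():
                df.loc[c, s] = ps[d]
            frames[ds] = df
        return frames

    def test_three_dataset_support(self):
        frames = self._frames({("Erbb2", "HER2"): (1e-4, 0.01, 0.01)})
        table = gc.call_counterparts(frames)
        assert table.calls == {"Erbb2": ["HER2"]}
        assert table.support.loc["Erbb2", "HER2"] == 3

    def test_two_of_three_called(self):
        frames = self._frames({("p53B", "Basal"): (0.04, 0.05, 0.06)})
        table = gc.call_counterparts(frames)
        assert table.calls == {"p53B": ["Basal"]}
        assert table.support.loc["p53B", "Basal"] == 2

    def test_single_support_not_called(self):
        frames = self._frames({("PyMT", "LumB"): (0.02, 0.10, 0.12)})
        table = gc.call_counterparts(frames)
        assert table.calls == {}

    def test_nan_counts_as_non_significant(self):
        frames = self._frames({("X", "S"): (0.01, np.nan, 0.20)})
        assert gc.call_counterparts(frames).calls == {}

    def test_fewer_than_two_datasets_rejected(self):
        frames = self._frames({("X", "S"): (0.01, 0.01, 0.01)})
        with pytest.raises(BundleError):
            gc.call_counterparts({"U": frames["U"]})
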