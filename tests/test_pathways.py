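"""Pathway scoring, enrichment, meta-signatures, conserved intersections."""

import numpy as np
import pandas as pd
import pytest

import gemmclass as gc
from gemmclass.bundle import BundleError, GeneSet, GeneSetCollection
from conftest import toy_bundle


class TestScoreSignatures:
    def test_single_gene_signature_equals_gene_row(self):
        b = toy_bundle([[1.0, -2.0, 0.5], [4.0, 4.0, 4.0]],
                       feature_ids=["gA", "gB"])
        col = GeneSetCollection([GeneSet("S", "", ["gA"])])
        out = gc.score_signatures(b, col, low_confidence_min=1)
        np.testing.assert_allclose(out.scores.loc["S"], b.values.loc["gA"])

    def test_median_of_three(self):
        b = toy_bundle([[1.0], [2.0], [9.0]], feature_ids=["A", "B", "C"])
        col = GeneSetCollection([GeneSet("S", "", ["A", "B", "C"])])
        out = gc.score_signatures(b, col)
        assert out.scores.loc["S"].iloc[0] == 2.0

    def test_matches_brute_force_with_absent_genes(self):
        rng = np.random.default_rng(0)
        b = toy_bundle(rng.normal(size=(50, 12)),
                       feature_ids=[f"g{i}" for i in range(50)])
        sets = []
        for k in range(10):
            members = list(rng.choice([f"g{i}" for i in range(55)], 12,
                                      replace=False))  # ~10% absent ids
            sets.append(GeneSet(f"S{k}", "", members))
        out = gc.score_signatures(b, GeneSetCollection(sets))
        for s in sets:
            present = [g for g in s.genes if g in b.values.index]
            expected = np.median(b.values.loc[present].to_numpy(), axis=0)
            np.testing.assert_array_equal(out.scores.loc[s.set_id].to_numpy(),
                                          expected)
            assert out.n_genes_found[s.set_id] == len(present)

    def test_no_gene_present_skipped_and_empty_collection_rejected(self):
        b = toy_bundle([[1.0, 2.0]], feature_ids=["gA"])
        col = GeneSetCollection([GeneSet("S", "", ["gA"]),
                                 GeneSet("gone", "", ["zz"])])
        out = gc.score_signatures(b, col, low_confidence_min=1)
        assert out.skipped == ["gone"]
        with pytest.raises(BundleError):
            gc.score_signatures(b, GeneSetCollection([]))


class TestEnrichedPathways:
    def test_planted_recovery_and_null(self, small_world, small_config,
                                       mouse_gene_bundle):
        truth = small_world["truth"]
        genes, labels = mouse_gene_bundle
        common = genes.values.index
        for h in small_world["human"]:
            common = common.intersection(h.values.index)
        scores = gc.score_signatures(genes.subset_features(common),
                                     small_world["pathways"])
        enr = gc.enriched_pathways(scores, (labels == "mclass1").to_numpy(),
                                   small_config, seed=1, set_id="mclass1")
        planted = set(truth.enriched_pathways["mclass1"])
        assert len(set(enr.genes) & planted) / len(planted) >= 0.8

        sizes = []
        for s in range(10):
            y = np.random.default_rng(s).permutation(
                (labels == "mclass1").to_numpy())
            sizes.append(len(gc.enriched_pathways(scores, y, small_config,
                                                  seed=s, set_id="null").genes))
        # shuffled labels retain residual class structure in the score
        # matrix, so an occasional single pathway reaches q=0
        assert np.median(sizes) <= 1
        assert max(sizes) < 0.2 * len(scores.scores)


class TestMetaSignature:
    def _scores(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame(rng.normal(size=(6, 10)),
                            index=[f"P{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(10)])

    def test_single_pathway_standardized_copy(self):
        scores = self._scores()
        ms = gc.meta_signature(scores, ["P0"], "c")
        row = scores.loc["P0"]
        np.testing.assert_allclose(ms.values,
                                   (row - row.mean()) / row.std(ddof=0),
                                   atol=1e-12)

    def test_duplicate_members_idempotent(self):
        scores = self._scores()
        a = gc.meta_signature(scores, ["P1"], "c")
        dup = pd.concat([scores, scores.loc[["P1"]].rename(index={"P1": "P1b"})])
        b = gc.meta_signature(dup, ["P1", "P1b"], "c")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_shift_invariance(self):
        scores = self._scores()
        a = gc.meta_signature(scores, ["P0", "P2"], "c")
        b = gc.meta_signature(scores + 5.0, ["P0", "P2"], "c")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_absent_members_rejected(self):
        with pytest.raises(BundleError):
            gc.meta_signature(self._scores(), ["nope"], "c")

    def test_linked_subtype_has_highest_median(self, small_world, small_config,
                                               mouse_gene_bundle):
        truth = small_world["truth"]
        genes, labels = mouse_gene_bundle
        h = small_world["human"][0]
        common = genes.values.index.intersection(h.values.index)
        hscores = gc.score_signatures(h.subset_features(common),
                                      small_world["pathways"])
        (cname, sname) = truth.linked_pairs()[0]
        ms = gc.meta_signature(hscores, truth.enriched_pathways[cname], cname)
        summary = ms.subtype_summary(h.sample_annotations["model_or_subtype"])
        assert summary[0.5].idxmax() == sname


class TestConservedPathways:
    MOUSE = {"c1": ["P1", "P2", "P3"]}
    HUMAN = {
        "U": {"s1": ["P1", "P2", "P9"]},
        "C": {"s1": ["P1", "P2"]},
        "T": {"s1": ["P1", "P8"]},
    }

    def test_all_three_datasets_required(self):
        out = gc.conserved_pathways(self.MOUSE, self.HUMAN, [("c1", "s1")])
        assert out[("c1", "s1")] == ["P1"]  # P2 enriched in only 2/3

    def test_nesting_monotone_in_required_datasets(self):
        sets = [set(per["s1"]) for per in self.HUMAN.values()]
        mouse = set(self.MOUSE["c1"])
        from itertools import combinations
        at_least = {k: set() for k in (1, 2, 3)}
        for k in at_least:
            for combo in combinations(sets, k):
                inter = mouse.intersection(*combo)
                at_least[k] |= inter
        assert at_least[3] <= at_least[2] <= at_least[1]

    def test_planted_conserved_recovered(self, small_world, small_config,
                                         mouse_gene_bundle):
        truth = small_world["truth"]
        genes, labels = mouse_gene_bundle
        common = genes.values.index
        for h in small_world["human"]:
            common = common.intersection(h.values.index)
        mscores = gc.score_signatures(genes.subset_features(common),
                                      small_world["pathways"])
        mouse_enr = {c: gc.enriched_pathways(
            mscores, (labels == c).to_numpy(), small_config, seed=10 + i,
            set_id=c).genes for i, c in enumerate(truth.class_names)}
        human_enr = {}
        for k, h in enumerate(small_world["human"]):
            ds = str(h.sample_annotations["platform"].iloc[0])
            hs = gc.score_signatures(h.subset_features(common),
                                     small_world["pathways"])
            per = {}
            for j, sub in enumerate(sorted(
                    h.sample_annotations["model_or_subtype"].unique())):
                y = (h.sample_annotations["model_or_subtype"] == sub).to_numpy()
                per[sub] = gc.enriched_pathways(hs, y, small_config,
                                                seed=100 + 10 * k + j,
                                                set_id=sub).genes
            human_enr[ds] = per
        pairs = truth.linked_pairs()
        out = gc.conserved_pathways(mouse_enr, human_enr, pairs)
        for (c, s), found in out.items():
            planted = set(truth.enriched_pathways[c])
            assert found  # something conserved for every linked pair
            assert len(set(found) & planted) / len(found) >= 0.8
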