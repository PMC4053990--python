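"""Intensity filtering, imputation, bridge normalization, centering, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gemmclass as gc
from gemmclass.bundle import BundleError
from conftest import toy_bundle


def _with_intensities(values, cy5, cy3, platform="p1"):
    b = toy_bundle(values, platform=platform)
    b.cy5 = pd.DataFrame(np.asarray(cy5, float), index=b.values.index,
                         columns=b.values.columns)
    b.cy3 = pd.DataFrame(np.asarray(cy3, float), index=b.values.index,
                         columns=b.values.columns)
    return b


class TestFilterProbes:
    def test_bright_probe_fully_retained(self):
        b = _with_intensities([[1.0, 2.0]], [[12, 12]], [[11, 11]])
        out = gc.filter_probes(b, 10, 0.7)
        assert out.feature_ids == ["f0"]
        assert not out.values.isna().any().any()

    def test_presence_at_65_percent_dropped(self):
        # 20 arrays, 13 passing (65%) <= 0.70 -> dropped
        n = 20
        cy = np.full((1, n), 20.0)
        cy[0, 13:] = 5.0
        b = _with_intensities(np.ones((1, n)), cy, np.full((1, n), 20.0))
        out = gc.filter_probes(b, 10, 0.70)
        assert out.n_features == 0

    def test_planted_failures_enumerated(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(100, 10))
        cy5 = np.full((100, 10), 50.0)
        cy5[:30] = 4.0  # 30 probes fail everywhere
        b = _with_intensities(vals, cy5, np.full((100, 10), 50.0))
        out = gc.filter_probes(b, 10, 0.7)
        assert out.n_features == 70
        assert out.feature_ids == [f"f{i}" for i in range(30, 100)]

    def test_gene_level_data_instructs_to_skip(self):
        b = toy_bundle([[1.0, 2.0]])
        with pytest.raises(BundleError, match="skip"):
            gc.filter_probes(b)


class TestImputeKNN:
    def test_complete_matrix_identity(self):
        b = toy_bundle(np.arange(12.0).reshape(3, 4))
        out = gc.impute_knn(b, 2)
        pd.testing.assert_frame_equal(out.values, b.values)

    def test_identical_neighbors_give_their_value(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (4, 1))
        vals[0, 2] = np.nan
        out = gc.impute_knn(toy_bundle(vals), 3)
        assert out.values.iloc[0, 2] == pytest.approx(3.0)
        # observed entries unchanged
        assert out.values.iloc[1:, :].to_numpy() == pytest.approx(vals[1:, :])

    def test_mask_and_recover_beats_baseline(self, small_world):
        """Recovered values track the truth near the noise floor.

        KNN imputation cannot beat the per-entry noise SD itself (the
        neighbor average carries independent noise of its own, adding
        sd^2/k), so the bound is noise_sd * sqrt(1 + 2/k); the row-median
        baseline is clearly worse on signature genes.
        """
        b = small_world["mouse"][0]
        full = b.values.dropna(how="any")
        rng = np.random.default_rng(4)
        mask = rng.random(full.shape) < 0.02
        masked = full.copy()
        masked[mask] = np.nan
        keep = np.isfinite(masked.to_numpy()).any(axis=1)
        masked, full, mask = masked[keep], full[keep], mask[keep]
        out = gc.impute_knn(toy_bundle(masked.to_numpy()), 10)
        err = out.values.to_numpy()[mask] - full.to_numpy()[mask]
        rmse = float(np.sqrt(np.mean(err ** 2)))
        assert rmse < 1.0 * np.sqrt(1 + 2 / 10)
        med = np.nanmedian(masked.to_numpy(), axis=1, keepdims=True)
        base = np.broadcast_to(med, full.shape)[mask] - full.to_numpy()[mask]
        assert rmse < np.sqrt(np.mean(base ** 2)) + 0.05

    def test_entirely_missing_feature_listed(self):
        vals = np.ones((3, 4))
        vals[1] = np.nan
        with pytest.raises(BundleError, match="f1"):
            gc.impute_knn(toy_bundle(vals), 2)


class TestIntersect:
    def test_identical_sets_unchanged(self):
        a = toy_bundle(np.ones((3, 2)))
        b = toy_bundle(np.zeros((3, 2)))
        out = gc.intersect_platforms([a, b])
        assert out[0].feature_ids == a.feature_ids

    def test_three_way_intersection(self):
        a = toy_bundle(np.ones((3, 2)), feature_ids=["A", "B", "C"])
        b = toy_bundle(np.ones((3, 2)), feature_ids=["B", "C", "D"])
        c = toy_bundle(np.ones((2, 2)), feature_ids=["B", "C"])
        out = gc.intersect_platforms([a, b, c])
        assert [o.feature_ids for o in out] == [["B", "C"]] * 3

    def test_empty_intersection_rejected(self):
        a = toy_bundle(np.ones((1, 2)), feature_ids=["A"])
        b = toy_bundle(np.ones((1, 2)), feature_ids=["B"])
        with pytest.raises(BundleError):
            gc.intersect_platforms([a, b])


class TestBridgeNormalize:
    def _two_platforms(self):
        rng = np.random.default_rng(1)
        a = toy_bundle(rng.normal(1.0, 0.1, (4, 6)), platform="p1",
                       sample_ids=[f"a{j}" for j in range(6)])
        b = toy_bundle(rng.normal(3.0, 0.1, (4, 6)), platform="p2",
                       sample_ids=[f"b{j}" for j in range(6)])
        return a, b

    def test_two_point_example(self):
        # per-probe bridge medians {1.0, 3.0} -> target 2.0, NF = {+1, -1}
        a = toy_bundle(np.full((2, 3), 1.0), platform="p1",
                       sample_ids=["a0", "a1", "a2"])
        b = toy_bundle(np.full((2, 3), 3.0), platform="p2",
                       sample_ids=["b0", "b1", "b2"])
        res = gc.bridge_normalize([a, b], [["a0", "a1"], ["b0", "b1"]])
        np.testing.assert_allclose(res.target_median, 2.0)
        np.testing.assert_allclose(res.normalization_factor["p1"], 1.0)
        np.testing.assert_allclose(res.normalization_factor["p2"], -1.0)
        np.testing.assert_allclose(res.combined.values.to_numpy(), 2.0)

    def test_equal_medians_no_change(self):
        a = toy_bundle(np.arange(8.0).reshape(2, 4), platform="p1",
                       sample_ids=list("wxyz"))
        b = toy_bundle(np.arange(8.0).reshape(2, 4), platform="p2",
                       sample_ids=list("WXYZ"))
        res = gc.bridge_normalize([a, b], [list("wxyz"), list("WXYZ")])
        np.testing.assert_allclose(res.normalization_factor.to_numpy(), 0.0)
        np.testing.assert_allclose(
            res.combined.values.to_numpy()[:, :4], a.values.to_numpy())

    def test_bridge_median_equality_exact(self, small_world):
        truth = small_world["truth"]
        bundles = [gc.impute_knn(b, 5) for b in small_world["mouse"]]
        bundles = gc.intersect_platforms(bundles)
        lists = [truth.bridge_ids[str(b.sample_annotations["platform"].iloc[0])]
                 for b in bundles]
        res = gc.bridge_normalize(bundles, lists)
        combined = res.combined
        for b, ids in zip(bundles, lists):
            med = combined.values[ids].median(axis=1)
            np.testing.assert_allclose(med, res.target_median, atol=1e-9)

    def test_commutes_with_platform_constant_after_centering(self):
        a, b = self._two_platforms()
        ids = [["a0", "a1", "a2"], ["b0", "b1", "b2"]]
        base = gc.median_center_rows(gc.bridge_normalize([a, b], ids).combined)
        shifted = toy_bundle(b.values.to_numpy() + 0.7, platform="p2",
                             sample_ids=b.sample_ids)
        out = gc.median_center_rows(gc.bridge_normalize([a, shifted], ids).combined)
        np.testing.assert_allclose(base.values.to_numpy(),
                                   out.values.to_numpy(), atol=1e-10)

    def test_all_missing_bridge_probe_listed(self):
        a, b = self._two_platforms()
        a.values.iloc[0, :3] = np.nan
        with pytest.raises(BundleError, match="f0"):
            gc.bridge_normalize([a, b], [["a0", "a1", "a2"], ["b0", "b1", "b2"]])

    def test_planted_offsets_removed_on_bridge_models(self, small_world):
        """Per-probe platform medians over bridge-model tumors agree across
        platforms after normalization (the quantity the factor equalizes)."""
        truth = small_world["truth"]
        bundles = [gc.impute_knn(b, 5) for b in small_world["mouse"]]
        bundles = gc.intersect_platforms(bundles)
        lists = [truth.bridge_ids[str(b.sample_annotations["platform"].iloc[0])]
                 for b in bundles]
        combined = gc.bridge_normalize(bundles, lists).combined
        meds = [combined.values[ids].median(axis=1) for ids in lists]
        for m in meds[1:]:
            assert float((m - meds[0]).abs().mean()) < 0.05

    def test_same_class_cross_platform_correlation_improves(self, small_world):
        truth = small_world["truth"]
        bundles = [gc.impute_knn(b, 5) for b in small_world["mouse"]]
        bundles = gc.intersect_platforms(bundles)
        lists = [truth.bridge_ids[str(b.sample_annotations["platform"].iloc[0])]
                 for b in bundles]
        pre = gc.ExpressionBundle(
            pd.concat([b.values for b in bundles], axis=1),
            pd.concat([b.sample_annotations for b in bundles]))
        post = gc.bridge_normalize(bundles, lists).combined
        ann = post.sample_annotations

        def corr_sum(bundle):
            total = 0.0
            for cname in set(truth.class_of_sample.values()):
                ids = [s for s in bundle.sample_ids
                       if truth.class_of_sample[s] == cname]
                plats = ann.loc[ids, "platform"]
                C = np.corrcoef(bundle.values[ids].to_numpy().T)
                cross = [(i, j) for i in range(len(ids)) for j in range(i)
                         if plats.iloc[i] != plats.iloc[j]]
                total += np.mean([C[i, j] for i, j in cross])
            return total

        assert corr_sum(post) > corr_sum(pre)


class TestMedianCenter:
    def test_simple_row(self):
        out = gc.median_center_rows(toy_bundle([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[-1, 0, 1]])

    def test_constant_row_becomes_zero(self):
        out = gc.median_center_rows(toy_bundle([[5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.lists(st.floats(-50, 50), min_size=3, max_size=7),
                    min_size=1, max_size=5).filter(
                        lambda rows: len({len(r) for r in rows}) == 1))
    def test_idempotent_and_zero_median(self, rows):
        b = toy_bundle(np.array(rows))
        once = gc.median_center_rows(b)
        twice = gc.median_center_rows(once)
        assert np.abs(np.median(once.values.to_numpy(), axis=1)).max() < 1e-12
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-12)


class TestPCAVerify:
    def test_shuffled_platform_labels_near_zero(self):
        rng = np.random.default_rng(2)
        b = toy_bundle(rng.normal(size=(50, 40)),
                       platform=list(rng.permutation(["p1", "p2"] * 20)))
        rep = gc.pca_verify(b)
        assert rep["platform_r2"] < 0.25 and not rep["flag"]

    def test_planted_offsets_raise_flag(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(60, 30)) * 0.2
        vals[:, 15:] += rng.normal(0, 1.0, size=(60, 1))  # strong per-probe offset
        b = toy_bundle(vals, platform=["p1"] * 15 + ["p2"] * 15)
        rep = gc.pca_verify(b)
        assert rep["flag"]

    def test_single_platform_association_zero(self):
        b = toy_bundle(np.random.default_rng(4).normal(size=(10, 6)),
                       platform="only")
        rep = gc.pca_verify(b)
        assert rep["platform_r2"] == 0.0
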