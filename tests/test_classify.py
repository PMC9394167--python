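"""Heatmap clustering, PCA, component orientation and the sign rule."""

import numpy as np
import pandas as pd
import pytest

from aptashape.classify import (
    ClassifyError,
    MODE_CANCER_VS_CONTROL,
    MODE_COMBINED,
    MODE_TA_VS_T2T4,
    accuracy,
    classify_by_sign,
    hierarchical_cluster_columns,
    orient_components,
    pca_fit,
)
from aptashape.samples import SampleRecord, SampleSheet


def _bc(i: int, length: int = 6) -> str:
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(digits)


def _sheet(groups):
    return SampleSheet(
        [
            SampleRecord(f"s{i}", _bc(i), g, "validation")
            for i, g in enumerate(groups)
        ]
    )


class TestHierarchicalClusterColumns:
    def test_identical_columns_merge_first(self):
        levels = pd.DataFrame(
            {"s0": [1.0, 2.0], "s1": [1.0, 2.0], "s2": [9.0, 9.0]},
            index=["AAAA", "CCCC"],
        )
        out = hierarchical_cluster_columns(levels)
        # the first linkage row joins the two identical leaves at height 0
        assert sorted(out.linkage[0, :2]) == [0, 1]
        assert out.linkage[0, 2] == 0.0

    def test_complete_linkage_heights_on_a_line(self):
        # points 0, 1, 3 on a line: first merge {0,1} at 1, then height 3
        levels = pd.DataFrame({"s0": [0.0], "s1": [1.0], "s2": [3.0]}, index=["AAAA"])
        out = hierarchical_cluster_columns(levels)
        assert out.linkage[0, 2] == pytest.approx(1.0)
        assert out.linkage[1, 2] == pytest.approx(3.0)  # complete, not single (2.0)

    def test_order_invariant_topology(self):
        rng = np.random.default_rng(0)
        levels = pd.DataFrame(
            rng.normal(size=(5, 4)),
            index=[_bc(i, 8) for i in range(5)],
            columns=["s0", "s1", "s2", "s3"],
        )
        cols_b = ["s2", "s0", "s3", "s1"]
        a = hierarchical_cluster_columns(levels)
        b = hierarchical_cluster_columns(levels[cols_b])
        assert set(map(frozenset, _leaf_partitions(a, list(levels.columns)))) == set(
            map(frozenset, _leaf_partitions(b, cols_b))
        )

    def test_single_column_trivial_tree(self):
        levels = pd.DataFrame({"s0": [1.0, 2.0]}, index=["AAAA", "CCCC"])
        out = hierarchical_cluster_columns(levels)
        assert out.order == ["s0"]
        assert out.newick.startswith("s0")


def _leaf_partitions(clustering, columns):
    """Flat cuts of the dendrogram, as sets of sample ids."""
    from scipy.cluster.hierarchy import fcluster

    n = clustering.linkage.shape[0] + 1
    clades = []
    for k in range(2, n):
        labels = fcluster(clustering.linkage, k, criterion="maxclust")
        groups = {}
        for leaf, lab in enumerate(labels):
            groups.setdefault(lab, set()).add(columns[leaf])
        clades.extend(tuple(sorted(g)) for g in groups.values())
    return clades


class TestPCAFit:
    def test_collinear_points_put_all_variance_on_pc1(self):
        m = pd.DataFrame(
            {"apt1": [1.0, -1.0, 2.0, -2.0], "apt2": [0.0, 0.0, 0.0, 0.0]},
            index=["s0", "s1", "s2", "s3"],
        )
        out = pca_fit(m)
        assert out.variance_fraction[0] == pytest.approx(1.0)

    def test_isotropic_data_splits_variance(self):
        # symmetric cross: equal variance per axis, zero covariance
        m = pd.DataFrame(
            {"apt1": [1.0, -1.0, 0.0, 0.0], "apt2": [0.0, 0.0, 1.0, -1.0]},
            index=["s0", "s1", "s2", "s3"],
        )
        out = pca_fit(m)
        assert np.allclose(out.variance_fraction, [0.5, 0.5])

    def test_variance_fractions_sum_to_one_and_scores_centered(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"s{i}" for i in range(10)],
            columns=[_bc(i, 8) for i in range(6)],
        )
        out = pca_fit(m)
        assert out.variance_fraction.sum() == pytest.approx(1.0)
        assert np.allclose(out.scores.mean(axis=0), 0.0, atol=1e-12)

    def test_matches_sklearn_decomposition(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        m = pd.DataFrame(
            rng.normal(size=(12, 5)),
            index=[f"s{i}" for i in range(12)],
            columns=[_bc(i, 8) for i in range(5)],
        )
        ours = pca_fit(m)
        ref = PCA(n_components=5).fit(m.to_numpy())
        assert np.allclose(
            ours.variance_fraction, ref.explained_variance_ratio_, atol=1e-10
        )
        # scores agree up to per-component sign
        ref_scores = ref.transform(m.to_numpy())
        for k in range(5):
            ours_k = ours.scores.iloc[:, k].to_numpy()
            assert np.allclose(ours_k, ref_scores[:, k], atol=1e-8) or np.allclose(
                ours_k, -ref_scores[:, k], atol=1e-8
            )

    def test_covariance_reconstruction(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.normal(size=(15, 4)),
            index=[f"s{i}" for i in range(15)],
            columns=[_bc(i, 8) for i in range(4)],
        )
        out = pca_fit(m)
        lam = out.variance_fraction * np.trace(np.cov(m.to_numpy().T))
        v = out.loadings.to_numpy()
        recon = v @ np.diag(lam) @ v.T
        assert np.allclose(recon, np.cov(m.to_numpy().T), atol=1e-10)

    def test_zero_variance_rejected(self):
        m = pd.DataFrame({"apt1": [1.0, 1.0], "apt2": [2.0, 2.0]}, index=["s0", "s1"])
        with pytest.raises(ClassifyError, match="zero variance"):
            pca_fit(m)


class TestOrientComponents:
    def _pca(self, groups, pc1, pc2=None):
        sheet = _sheet(groups)
        data = {"PC1": pc1}
        if pc2 is not None:
            data["PC2"] = pc2
        scores = pd.DataFrame(data, index=sheet.sample_ids)
        from aptashape.classify import PCAResult

        k = len(data)
        pca = PCAResult(
            scores=scores,
            loadings=pd.DataFrame(
                np.eye(k), index=[_bc(i, 8) for i in range(k)],
                columns=list(data),
            ),
            variance_fraction=np.ones(k) / k,
            signs=np.ones(k, dtype=int),
        )
        return pca, sheet

    def test_negative_cancer_mean_flips_pc1(self):
        pca, sheet = self._pca(["Ta", "T2T4", "C", "C"], [-1.0, -2.0, 1.0, 2.0])
        out = orient_components(pca, sheet)
        assert out.component(1).tolist() == [1.0, 2.0, -1.0, -2.0]
        assert out.signs[0] == -1

    def test_positive_cancer_mean_unchanged(self):
        pca, sheet = self._pca(["Ta", "C"], [1.0, -1.0])
        out = orient_components(pca, sheet)
        assert out.component(1).tolist() == [1.0, -1.0]

    def test_orientation_is_involution(self):
        pca, sheet = self._pca(
            ["Ta", "T2T4", "C"], [-1.0, -2.0, 3.0], pc2=[0.5, -1.5, 1.0]
        )
        once = orient_components(pca, sheet)
        twice = orient_components(once, sheet)
        assert once.scores.equals(twice.scores)


class TestClassifyBySign:
    def test_sign_rule_separates_cancer_from_control(self):
        pca, sheet = TestOrientComponents()._pca(["Ta", "C"], [0.5, -0.3])
        result = classify_by_sign(pca, sheet, mode=MODE_CANCER_VS_CONTROL)
        assert result.accuracies[MODE_CANCER_VS_CONTROL] == 1.0

    def test_all_positive_scores_misclassify_controls(self):
        pca, sheet = TestOrientComponents()._pca(["Ta", "C"], [0.5, 0.3])
        result = classify_by_sign(pca, sheet, mode=MODE_CANCER_VS_CONTROL)
        assert result.accuracies[MODE_CANCER_VS_CONTROL] == 0.5

    def test_zero_score_maps_to_baseline_class(self):
        pca, sheet = TestOrientComponents()._pca(["C", "Ta"], [0.0, 1.0])
        result = classify_by_sign(pca, sheet, mode=MODE_CANCER_VS_CONTROL)
        assert result.accuracies[MODE_CANCER_VS_CONTROL] == 1.0

    def test_stage_task_uses_cancer_samples_only(self):
        pca, sheet = TestOrientComponents()._pca(
            ["C", "Ta", "T2T4"], [-1.0, 1.0, 1.0], pc2=[5.0, -0.5, 0.5]
        )
        result = classify_by_sign(pca, sheet, mode=MODE_COMBINED)
        stage = result.predictions[result.predictions["task"] == MODE_TA_VS_T2T4]
        assert set(stage["sample_id"]) == {"s1", "s2"}  # control excluded
        assert result.accuracies[MODE_TA_VS_T2T4] == 1.0

    def test_stage_task_without_cancer_samples_rejected(self):
        pca, sheet = TestOrientComponents()._pca(["C", "C"], [0.1, -0.1], pc2=[1.0, 2.0])
        with pytest.raises(ClassifyError, match="cancer"):
            classify_by_sign(pca, sheet, mode=MODE_TA_VS_T2T4)

    def test_invariant_to_positive_rescaling(self):
        pca, sheet = TestOrientComponents()._pca(
            ["Ta", "T2T4", "C"], [0.4, 1.0, -0.2], pc2=[-0.5, 1.5, 1.0]
        )
        scaled = pca
        scaled.scores.iloc[:, :] = scaled.scores.to_numpy() * 37.0
        a = classify_by_sign(pca, sheet, mode=MODE_COMBINED)
        b = classify_by_sign(scaled, sheet, mode=MODE_COMBINED)
        assert a.predictions["predicted"].tolist() == b.predictions["predicted"].tolist()


class TestAccuracy:
    def test_fraction_of_matches(self):
        pred = ["cancer"] * 20 + ["control"] * 2
        truth = ["cancer"] * 22
        assert accuracy(pred, truth) == pytest.approx(20 / 22)

    def test_identical_lists(self):
        assert accuracy(["a", "b"], ["a", "b"]) == 1.0

    def test_disjoint_labels(self):
        assert accuracy(["a", "a"], ["b", "b"]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ClassifyError, match="mismatch"):
            accuracy(["a"], ["a", "b"])
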