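"""Validation-cohort analysis: heatmap ordering, PCA, sign-rule labels.

Samples are classified from their coordinates on oriented principal
components of the discriminatory-aptamer relative levels:

* component 1, oriented so cancer samples (Ta and T2-T4) have positive
  mean score, separates cancer from control: positive score -> cancer;
* component 2, oriented so T2-T4 samples have positive mean score,
  separates late from early stage among cancer samples: positive
  score -> T2-T4.

A score of exactly zero maps to the baseline class (control, or Ta).
Because a principal axis is only defined up to sign, the orientation
step is what makes the "positive coordinate means cancer" rule
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .samples import CANCER_GROUPS, GROUP_T2T4, GROUP_TA, SampleSheet

MODE_CANCER_VS_CONTROL = "cancer_vs_control"
MODE_TA_VS_T2T4 = "Ta_vs_T2T4"
MODE_COMBINED = "combined"

LABEL_CANCER = "cancer"
LABEL_CONTROL = "control"


class ClassifyError(ValueError):
    """Invalid input to the classification stage."""


# ---------------------------------------------------------------------------
# Heatmap column ordering
# ---------------------------------------------------------------------------

@dataclass
class ColumnClustering:
    order: list[str]          # sample ids in dendrogram leaf order
    linkage: np.ndarray       # scipy linkage matrix
    newick: str


def hierarchical_cluster_columns(
    levels: pd.DataFrame, metric: str = "euclidean", linkage_method: str = "complete"
) -> ColumnClustering:
    """Order heatmap columns by agglomerative clustering of sample profiles.

    Columns (samples) are clustered on their aptamer-level vectors with
    complete linkage; rows are left in their given (family) order.  A
    single column yields a trivial one-leaf tree.
    """
    samples = list(levels.columns)
    if len(samples) == 0:
        raise ClassifyError("no columns to cluster")
    if len(samples) == 1:
        return ColumnClustering(
            order=samples, linkage=np.empty((0, 4)), newick=f"{samples[0]};"
        )
    x = levels.to_numpy(dtype=float).T  # samples x aptamers
    dist = pdist(x, metric=metric)
    z = hierarchy.linkage(dist, method=linkage_method)
    order = [samples[i] for i in hierarchy.leaves_list(z)]
    return ColumnClustering(order=order, linkage=z, newick=_linkage_to_newick(z, samples))


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, labels)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Scores, loadings, variance fractions and orientation signs.

    ``scores``: samples x components (columns PC1, PC2, ...);
    ``loadings``: aptamers x components; ``variance_fraction``: fraction
    of total variance per component (sums to 1 over all components);
    ``signs``: +-1 orientation applied to each component relative to the
    deterministic fit.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    signs: np.ndarray

    def component(self, k: int) -> pd.Series:
        """Scores on component ``k`` (1-based)."""
        return self.scores[f"PC{k}"]


def pca_fit(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> PCAResult:
    """Principal components of a samples x aptamers matrix via SVD.

    Columns are mean-centered (default) and optionally scaled to unit
    standard deviation, then decomposed; component variances are the
    squared singular values over n - 1, and variance fractions are
    relative to their sum.  Component signs follow a deterministic
    convention (largest-magnitude loading positive), to be re-oriented
    by :func:`orient_components`.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ClassifyError("PCA needs at least 2 samples and 1 aptamer")
    x = matrix.to_numpy(dtype=float)
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ClassifyError("cannot scale zero-variance aptamer columns")
        x = x / sd
    if not np.any(x):
        raise ClassifyError("matrix has zero variance; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    variances = s**2 / (matrix.shape[0] - 1)
    fractions = variances / variances.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comp_names),
        variance_fraction=fractions,
        signs=np.ones(len(s), dtype=int),
    )


def orient_components(pca: PCAResult, sheet: SampleSheet) -> PCAResult:
    """Fix component signs against the labeled groups.

    Component 1 is flipped when the mean score of cancer-labeled samples
    is negative; component 2 when the mean score of T2-T4-labeled
    samples is negative.  Applying the orientation twice is the
    identity.  With no labeled samples present the result is returned
    unchanged.
    """
    labeled = [s for s in pca.scores.index if s in sheet.sample_ids]
    if not labeled:
        return pca
    groups = sheet.groups(labeled)
    scores = pca.scores.copy()
    loadings = pca.loadings.copy()
    signs = pca.signs.copy()
    rules = {
        "PC1": groups.index[groups.isin(CANCER_GROUPS)],
        "PC2": groups.index[groups == GROUP_T2T4],
    }
    for comp, ids in rules.items():
        if comp not in scores.columns or len(ids) == 0:
            continue
        if scores.loc[ids, comp].mean() < 0:
            scores[comp] = -scores[comp]
            loadings[comp] = -loadings[comp]
            signs[int(comp[2:]) - 1] *= -1
    return replace(pca, scores=scores, loadings=loadings, signs=signs)


# ---------------------------------------------------------------------------
# Sign-rule classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    predictions: pd.DataFrame   # sample_id, task, predicted, truth
    accuracies: dict[str, float]

    def to_tsv(self, path) -> None:
        self.predictions.to_csv(path, sep="\t", index=False)


def accuracy(pred: list[str], truth: list[str]) -> float:
    """Fraction of exact label matches."""
    if len(pred) != len(truth):
        raise ClassifyError(
            f"prediction/truth length mismatch: {len(pred)} vs {len(truth)}"
        )
    if not pred:
        raise ClassifyError("cannot compute accuracy of empty label lists")
    return sum(p == t for p, t in zip(pred, truth)) / len(pred)


def classify_by_sign(
    pca: PCAResult, sheet: SampleSheet, mode: str = MODE_COMBINED
) -> ClassificationResult:
    """Assign labels from oriented component signs and score against truth.

    ``cancer_vs_control``: PC1 > 0 -> cancer, else control, for every
    sample.  ``Ta_vs_T2T4``: among true-cancer samples only, PC2 > 0 ->
    T2-T4, else Ta.  ``combined`` runs both tasks on the same PCA.
    """
    groups = sheet.groups([s for s in pca.scores.index if s in sheet.sample_ids])
    if len(groups) == 0:
        raise ClassifyError("no labeled samples to classify")
    rows = []
    accuracies: dict[str, float] = {}
    if mode in (MODE_CANCER_VS_CONTROL, MODE_COMBINED):
        pc1 = pca.component(1).loc[groups.index]
        pred = np.where(pc1 > 0, LABEL_CANCER, LABEL_CONTROL)
        truth = np.where(groups.isin(CANCER_GROUPS), LABEL_CANCER, LABEL_CONTROL)
        accuracies[MODE_CANCER_VS_CONTROL] = accuracy(list(pred), list(truth))
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": groups.index,
                    "task": MODE_CANCER_VS_CONTROL,
                    "score": pc1.to_numpy(),
                    "predicted": pred,
                    "truth": truth,
                }
            )
        )
    if mode in (MODE_TA_VS_T2T4, MODE_COMBINED):
        cancer_ids = groups.index[groups.isin(CANCER_GROUPS)]
        if len(cancer_ids) == 0:
            raise ClassifyError("no cancer samples for the Ta vs T2-T4 task")
        if "PC2" not in pca.scores.columns:
            raise ClassifyError("PCA has fewer than 2 components")
        pc2 = pca.component(2).loc[cancer_ids]
        pred = np.where(pc2 > 0, GROUP_T2T4, GROUP_TA)
        truth = groups.loc[cancer_ids].to_numpy()
        accuracies[MODE_TA_VS_T2T4] = accuracy(list(pred), list(truth))
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": cancer_ids,
                    "task": MODE_TA_VS_T2T4,
                    "score": pc2.to_numpy(),
                    "predicted": pred,
                    "truth": truth,
                }
            )
        )
    if not rows:
        raise ClassifyError(f"unknown classification mode: {mode!r}")
    predictions = pd.concat(rows, ignore_index=True)
    return ClassificationResult(predictions=predictions, accuracies=accuracies)
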