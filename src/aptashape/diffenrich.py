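"""Per-aptamer differential-enrichment testing and selection.

Each aptamer's pool fractions are first rescaled to *relative levels*
(fraction divided by the aptamer's mean fraction across all training
samples), putting abundant and rare aptamers on a common scale.  A
linear model with group indicators is then fit per aptamer: with the
control group as baseline the group coefficients are the differences of
group means in relative-level units, their standard errors come from
the pooled residual variance, and two-sided p-values from a Student's t
distribution.  Re-leveling with the Ta group as baseline yields the
early-vs-late-stage contrast.  P-values are Benjamini-Hochberg adjusted
within each comparison, and aptamers pass when both the coefficient
magnitude and the adjusted p-value clear their thresholds
(|coef| > 0.5 for comparisons against control, > 0.25 for Ta vs T2-T4;
adjusted p < 0.01).

Selected aptamers are grouped into sequence families by single-linkage
clustering under the restricted Damerau-Levenshtein distance.  This is
a documented surrogate for motif-based family assignment: families are
connected components of the "within ``family_max_dist`` edits" graph,
labeled A, B, ... by decreasing size.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .distance import edit_distance
from .samples import GROUP_C, GROUP_TA, GROUP_T2T4, SampleSheet

logger = logging.getLogger(__name__)

COMPARISON_TA_VS_C = "Ta_vs_C"
COMPARISON_T2T4_VS_C = "T2T4_vs_C"
COMPARISON_T2T4_VS_TA = "T2T4_vs_Ta"
COMPARISONS = (COMPARISON_TA_VS_C, COMPARISON_T2T4_VS_C, COMPARISON_T2T4_VS_TA)

# comparison -> (group, baseline)
_CONTRASTS = {
    COMPARISON_TA_VS_C: (GROUP_TA, GROUP_C),
    COMPARISON_T2T4_VS_C: (GROUP_T2T4, GROUP_C),
    COMPARISON_T2T4_VS_TA: (GROUP_T2T4, GROUP_TA),
}

DIRECTION_INCREASED = "increased"
DIRECTION_DEPLETED = "depleted"


class DiffEnrichError(ValueError):
    """Invalid input to differential-enrichment testing."""


def relative_to_mean(freqs: pd.DataFrame) -> pd.DataFrame:
    """Divide each aptamer's frequencies by its mean across samples.

    Rows with zero mean cannot be rescaled and are dropped with a
    warning.  Every returned row has mean 1 by construction.
    """
    means = freqs.mean(axis=1)
    zero = means[means == 0]
    if len(zero):
        logger.warning(
            "dropping %d aptamer(s) with zero mean frequency", len(zero)
        )
    kept = freqs.loc[means > 0]
    return kept.div(means[means > 0], axis=0)


def fit_group_ols(
    levels: pd.DataFrame, sheet: SampleSheet, baseline: str
) -> pd.DataFrame:
    """Indicator-coded least-squares fit per aptamer, vectorized.

    The model is y = b0 + sum_g b_g * 1[sample in g] over all samples
    present in ``sheet``, with coefficients relative to ``baseline``.
    Least squares makes b_g the difference of group means; the standard
    error uses the residual variance pooled across all groups with
    n - n_groups degrees of freedom, and p-values are two-sided
    Student's t.

    Returns a long DataFrame with one row per (aptamer, non-baseline
    group): columns sequence, group, coef, se, t, df, pvalue,
    degenerate.  Rows with zero residual variance carry p = 0 and
    ``degenerate = True``.
    """
    sample_ids = [s for s in sheet.sample_ids if s in levels.columns]
    missing = [s for s in sheet.sample_ids if s not in levels.columns]
    if missing:
        raise DiffEnrichError(f"samples missing from level matrix: {missing}")
    groups = sheet.groups(sample_ids)
    group_names = [g for g in (GROUP_C, GROUP_TA, GROUP_T2T4) if (groups == g).any()]
    if baseline not in group_names:
        raise DiffEnrichError(f"baseline group {baseline!r} has no samples")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise DiffEnrichError(
            f"groups with fewer than 2 samples: {small.index.tolist()}"
        )
    y = levels[sample_ids].to_numpy(dtype=float)  # aptamers x samples
    n = y.shape[1]
    k = len(group_names)
    df_resid = n - k
    if df_resid < 1:
        raise DiffEnrichError("no residual degrees of freedom")

    group_means: dict[str, np.ndarray] = {}
    rss = np.zeros(y.shape[0])
    for g in group_names:
        cols = np.flatnonzero((groups == g).to_numpy())
        mean_g = y[:, cols].mean(axis=1)
        group_means[g] = mean_g
        rss += ((y[:, cols] - mean_g[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    rows = []
    n_base = int(sizes[baseline])
    for g in group_names:
        if g == baseline:
            continue
        n_g = int(sizes[g])
        coef = group_means[g] - group_means[baseline]
        se = np.sqrt(s2 * (1.0 / n_g + 1.0 / n_base))
        degenerate = se == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degenerate, np.inf * np.sign(coef), coef / se)
        pvalue = np.where(
            degenerate,
            np.where(coef == 0, 1.0, 0.0),
            2.0 * stats.t.sf(np.abs(t), df_resid),
        )
        rows.append(
            pd.DataFrame(
                {
                    "sequence": levels.index,
                    "group": g,
                    "coef": coef,
                    "se": se,
                    "t": t,
                    "df": df_resid,
                    "pvalue": pvalue,
                    "degenerate": degenerate,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DiffEnrichError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_differential_tests(
    levels: pd.DataFrame, sheet: SampleSheet, mode: str = "pooled"
) -> pd.DataFrame:
    """OLS results for the three group comparisons, BH-adjusted per comparison.

    ``pooled`` fits one three-group model over all samples (pooled
    residual variance, df = n - 3) and re-levels it for the Ta baseline;
    ``pairwise`` fits each comparison on its two groups only.  The BH
    family is the set of aptamers tested within one comparison.
    """
    frames = []
    for comparison in COMPARISONS:
        group, baseline = _CONTRASTS[comparison]
        if mode == "pooled":
            fit = fit_group_ols(levels, sheet, baseline=baseline)
        elif mode == "pairwise":
            pair_sheet = sheet.subset(groups=(group, baseline))
            fit = fit_group_ols(levels, pair_sheet, baseline=baseline)
        else:
            raise DiffEnrichError(f"unknown OLS mode: {mode!r}")
        fit = fit[fit["group"] == group].copy()
        fit["comparison"] = comparison
        fit["adj_pvalue"] = bh_adjust(fit["pvalue"].to_numpy())
        frames.append(fit.drop(columns="group"))
    result = pd.concat(frames, ignore_index=True)
    cols = ["sequence", "comparison", "coef", "se", "t", "df", "pvalue", "adj_pvalue", "degenerate"]
    return result[cols]


@dataclass
class DiscriminatorySet:
    """Aptamers passing selection, with direction and family labels.

    ``table`` has one row per (aptamer, triggering comparison); the
    ``family`` column is shared across rows of the same aptamer.
    """

    table: pd.DataFrame  # sequence, comparison, coef, adj_pvalue, direction, family

    @property
    def sequences(self) -> list[str]:
        return sorted(self.table["sequence"].unique().tolist())

    def sequences_for(self, comparison: str) -> list[str]:
        mask = self.table["comparison"] == comparison
        return sorted(self.table.loc[mask, "sequence"].unique().tolist())

    @property
    def vs_control_sequences(self) -> list[str]:
        """Aptamers triggering either comparison against the control group."""
        mask = self.table["comparison"].isin(
            [COMPARISON_TA_VS_C, COMPARISON_T2T4_VS_C]
        )
        return sorted(self.table.loc[mask, "sequence"].unique().tolist())

    @property
    def stage_sequences(self) -> list[str]:
        return self.sequences_for(COMPARISON_T2T4_VS_TA)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "DiscriminatorySet":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        df["coef"] = df["coef"].astype(float)
        df["adj_pvalue"] = df["adj_pvalue"].astype(float)
        return cls(df)


def select_discriminatory(
    results: pd.DataFrame, cfg: PipelineConfig
) -> DiscriminatorySet:
    """Apply the coefficient-magnitude and adjusted-p selection gates.

    Against-control comparisons require |coef| > ``coef_threshold_vs_C``
    (default 0.5); the stage comparison requires
    |coef| > ``coef_threshold_Ta_vs_T2T4`` (default 0.25); all require
    adjusted p < ``adj_p_threshold`` (default 0.01).  Direction is
    "increased" for positive and "depleted" for negative coefficients.
    """
    thresholds = {
        COMPARISON_TA_VS_C: cfg.coef_threshold_vs_C,
        COMPARISON_T2T4_VS_C: cfg.coef_threshold_vs_C,
        COMPARISON_T2T4_VS_TA: cfg.coef_threshold_Ta_vs_T2T4,
    }
    selected = []
    for comparison, thr in thresholds.items():
        part = results[results["comparison"] == comparison]
        hits = part[
            (part["coef"].abs() > thr) & (part["adj_pvalue"] < cfg.adj_p_threshold)
        ].copy()
        hits["direction"] = np.where(
            hits["coef"] > 0, DIRECTION_INCREASED, DIRECTION_DEPLETED
        )
        selected.append(hits[["sequence", "comparison", "coef", "adj_pvalue", "direction"]])
    table = pd.concat(selected, ignore_index=True)
    table = table.sort_values(["sequence", "comparison"], kind="mergesort").reset_index(
        drop=True
    )
    table["family"] = ""
    result = DiscriminatorySet(table)
    return group_into_families(result, cfg.family_max_dist, variant=cfg.distance_variant)


def group_into_families(
    selected: DiscriminatorySet, family_max_dist: int = 8, variant: str = "osa"
) -> DiscriminatorySet:
    """Label sequence families by single-linkage edit-distance clustering.

    Two sequences belong to the same family when connected by a chain of
    pairwise distances <= ``family_max_dist``.  Components of size >= 2
    receive letters A, B, ... in order of decreasing size (ties broken
    by smallest member sequence); singletons keep an empty label.
    """
    seqs = selected.sequences
    parent = {s: s for s in seqs}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for a, b in itertools.combinations(seqs, 2):
        if abs(len(a) - len(b)) > family_max_dist:
            continue
        if edit_distance(a, b, variant) <= family_max_dist:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    components: dict[str, list[str]] = {}
    for s in seqs:
        components.setdefault(find(s), []).append(s)
    families = [
        sorted(members) for members in components.values() if len(members) >= 2
    ]
    families.sort(key=lambda m: (-len(m), m[0]))
    labels = _family_labels(len(families))
    label_of: dict[str, str] = {}
    for label, members in zip(labels, families):
        for s in members:
            label_of[s] = label
    table = selected.table.copy()
    table["family"] = table["sequence"].map(lambda s: label_of.get(s, ""))
    return DiscriminatorySet(table)


def _family_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... labels."""
    letters = string.ascii_uppercase
    labels = []
    for i in range(n):
        if i < 26:
            labels.append(letters[i])
        else:
            labels.append(letters[i // 26 - 1] + letters[i % 26])
    return labels


def volcano_coordinates(results: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """(coef, -log10 adjusted p) per aptamer for one comparison's volcano plot."""
    part = results[results["comparison"] == comparison]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(part["adj_pvalue"].to_numpy())
    return pd.DataFrame(
        {
            "sequence": part["sequence"].to_numpy(),
            "coef": part["coef"].to_numpy(),
            "neg_log10_adj_p": neglog,
        }
    )
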