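"""Differential enrichment: relative levels, group OLS, BH, selection, families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aptashape.config import PipelineConfig
from aptashape.diffenrich import (
    COMPARISON_T2T4_VS_C,
    COMPARISON_T2T4_VS_TA,
    COMPARISON_TA_VS_C,
    DiffEnrichError,
    DiscriminatorySet,
    bh_adjust,
    fit_group_ols,
    group_into_families,
    relative_to_mean,
    run_differential_tests,
    select_discriminatory,
)
from aptashape.samples import SampleRecord, SampleSheet


def _bc(i: int, length: int = 6) -> str:
    """Deterministic unique DNA barcode: base-4 encoding of ``i``."""
    digits = []
    for _ in range(length):
        digits.append("ACGT"[i % 4])
        i //= 4
    return "".join(digits)


def _two_group_sheet(n1=2, n2=2, groups=("C", "Ta")):
    recs = [
        SampleRecord(f"a{i}", _bc(i), groups[0], "training") for i in range(n1)
    ] + [
        SampleRecord(f"b{i}", _bc(100 + i), groups[1], "training") for i in range(n2)
    ]
    return SampleSheet(recs)


class TestRelativeToMean:
    def test_row_rescaling(self):
        freqs = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["AAAA"])
        out = relative_to_mean(freqs)
        assert out.loc["AAAA"].tolist() == [0.5, 1.0, 1.5]

    def test_constant_row_becomes_ones(self):
        freqs = pd.DataFrame({"s1": [4.0], "s2": [4.0]}, index=["AAAA"])
        assert relative_to_mean(freqs).loc["AAAA"].tolist() == [1.0, 1.0]

    def test_zero_row_dropped(self):
        freqs = pd.DataFrame(
            {"s1": [0.0, 1.0], "s2": [0.0, 3.0]}, index=["AAAA", "CCCC"]
        )
        out = relative_to_mean(freqs)
        assert out.index.tolist() == ["CCCC"]

    def test_every_row_mean_is_one(self):
        rng = np.random.default_rng(0)
        freqs = pd.DataFrame(
            rng.lognormal(size=(20, 6)),
            index=[_bc(i, length=8) for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        out = relative_to_mean(freqs)
        assert np.allclose(out.mean(axis=1), 1.0)


class TestFitGroupOLS:
    def test_worked_two_group_example(self):
        """Baseline [1,2] vs other [2,3]: coef 1.0, SE 0.7071, t 1.4142, p 0.293."""
        sheet = _two_group_sheet()
        levels = pd.DataFrame(
            [[1.0, 2.0, 2.0, 3.0]], index=["AAAA"], columns=sheet.sample_ids
        )
        fit = fit_group_ols(levels, sheet, baseline="C")
        row = fit.iloc[0]
        assert row["coef"] == pytest.approx(1.0)
        assert row["se"] == pytest.approx(0.7071, abs=1e-4)
        assert row["t"] == pytest.approx(1.4142, abs=1e-4)
        assert row["df"] == 2
        assert row["pvalue"] == pytest.approx(0.2929, abs=1e-3)

    def test_identical_group_means_give_zero_coef(self):
        sheet = _two_group_sheet()
        levels = pd.DataFrame(
            [[1.0, 3.0, 2.0, 2.0]], index=["AAAA"], columns=sheet.sample_ids
        )
        fit = fit_group_ols(levels, sheet, baseline="C")
        assert fit.iloc[0]["coef"] == pytest.approx(0.0)

    def test_matches_pooled_t_test_on_random_instances(self):
        """Agreement with scipy's equal-variance two-sample t-test to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(2, 12, size=2)
            sheet = _two_group_sheet(n1, n2)
            y1, y2 = rng.normal(size=n1), rng.normal(2.0 * rng.random(), size=n2)
            levels = pd.DataFrame(
                [np.concatenate([y1, y2])], index=["AAAA"], columns=sheet.sample_ids
            )
            fit = fit_group_ols(levels, sheet, baseline="C").iloc[0]
            t_ref, p_ref = sps.ttest_ind(y2, y1, equal_var=True)
            assert fit["coef"] == pytest.approx(y2.mean() - y1.mean(), abs=1e-12)
            assert fit["t"] == pytest.approx(t_ref, abs=1e-10)
            assert fit["pvalue"] == pytest.approx(p_ref, abs=1e-10)

    def test_matches_statsmodels_three_group_ols(self):
        """Pooled three-group model equals statsmodels OLS with dummy coding."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        recs = []
        for g, n in (("C", 4), ("Ta", 5), ("T2T4", 3)):
            for i in range(n):
                recs.append(SampleRecord(f"{g}_{i}", _bc(len(recs)), g, "training"))
        sheet = SampleSheet(recs)
        y = rng.normal(size=12)
        levels = pd.DataFrame([y], index=["AAAA"], columns=sheet.sample_ids)
        fit = fit_group_ols(levels, sheet, baseline="C")
        groups = sheet.groups(sheet.sample_ids)
        x = pd.get_dummies(groups, drop_first=False)[["Ta", "T2T4"]].astype(float)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        for g in ("Ta", "T2T4"):
            row = fit[fit["group"] == g].iloc[0]
            assert row["coef"] == pytest.approx(model.params[g], abs=1e-10)
            assert row["se"] == pytest.approx(model.bse[g], abs=1e-10)
            assert row["pvalue"] == pytest.approx(model.pvalues[g], abs=1e-10)

    def test_single_sample_group_rejected(self):
        sheet = _two_group_sheet(n1=1, n2=3)
        levels = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["AAAA"], columns=sheet.sample_ids
        )
        with pytest.raises(DiffEnrichError, match="fewer than 2"):
            fit_group_ols(levels, sheet, baseline="C")

    def test_degenerate_zero_variance_flagged(self):
        sheet = _two_group_sheet()
        levels = pd.DataFrame(
            [[1.0, 1.0, 2.0, 2.0]], index=["AAAA"], columns=sheet.sample_ids
        )
        fit = fit_group_ols(levels, sheet, baseline="C").iloc[0]
        assert fit["degenerate"]
        assert fit["pvalue"] == 0.0


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_step_up_hand_values(self, pvals, expected):
        assert np.allclose(bh_adjust(pvals), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffEnrichError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone: sorting p sorts the adjusted values the same way
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _result_row(seq, comparison, coef, adj_p):
    return {
        "sequence": seq,
        "comparison": comparison,
        "coef": coef,
        "se": 0.1,
        "t": coef / 0.1,
        "df": 93,
        "pvalue": adj_p / 2,
        "adj_pvalue": adj_p,
        "degenerate": False,
    }


class TestSelectDiscriminatory:
    def test_threshold_gates(self):
        results = pd.DataFrame(
            [
                _result_row("AAAA", COMPARISON_T2T4_VS_C, -0.6, 0.005),   # in, depleted
                _result_row("CCCC", COMPARISON_T2T4_VS_C, -0.4, 0.001),   # out: |coef|
                _result_row("GGGG", COMPARISON_T2T4_VS_TA, 0.3, 0.005),   # in, increased
                _result_row("TTTT", COMPARISON_TA_VS_C, 0.6, 0.02),       # out: adj p
            ]
        )
        selected = select_discriminatory(results, PipelineConfig())
        t = selected.table.set_index("sequence")
        assert sorted(selected.sequences) == ["AAAA", "GGGG"]
        assert t.loc["AAAA", "direction"] == "depleted"
        assert t.loc["GGGG", "direction"] == "increased"

    def test_selection_invariant_to_row_order(self):
        rows = [
            _result_row("AAAA", COMPARISON_T2T4_VS_C, -0.6, 0.005),
            _result_row("GGGG", COMPARISON_T2T4_VS_TA, 0.3, 0.005),
            _result_row("CCCC", COMPARISON_TA_VS_C, 0.9, 0.0001),
        ]
        cfg = PipelineConfig()
        a = select_discriminatory(pd.DataFrame(rows), cfg)
        b = select_discriminatory(pd.DataFrame(rows[::-1]), cfg)
        assert a.table.equals(b.table)


class TestGroupIntoFamilies:
    def _dset(self, seqs):
        return DiscriminatorySet(
            pd.DataFrame(
                {
                    "sequence": seqs,
                    "comparison": COMPARISON_TA_VS_C,
                    "coef": -0.6,
                    "adj_pvalue": 0.001,
                    "direction": "depleted",
                    "family": "",
                }
            )
        )

    def test_identical_sequences_share_family(self):
        # duplicate rows (same aptamer selected in two comparisons) always
        # carry the same family label
        out = group_into_families(self._dset(["AAAAAAAA", "AAAAAAAA"]))
        assert out.table["family"].nunique() == 1
        # and sequences within the distance cutoff are co-labeled
        out = group_into_families(self._dset(["AAAAAAAA", "AAAAAAAC"]))
        assert set(out.table["family"]) == {"A"}

    def test_distant_sequences_stay_singletons(self):
        out = group_into_families(self._dset(["A" * 16, "C" * 16, "G" * 16]))
        assert set(out.table["family"]) == {""}

    def test_single_linkage_chains(self):
        # A-B and B-C within 8, A-C at 16: one family through the chain
        a, b, c = "A" * 16, "A" * 8 + "C" * 8, "C" * 16
        out = group_into_families(self._dset([a, b, c]), family_max_dist=8)
        assert set(out.table["family"]) == {"A"}


def test_run_differential_tests_covers_three_comparisons(small_simulation):
    from aptashape.seqproc import normalize_frequencies

    _, _, sheet, counts, _ = small_simulation
    levels = relative_to_mean(normalize_frequencies(counts))
    results = run_differential_tests(levels, sheet)
    assert set(results["comparison"]) == {
        COMPARISON_TA_VS_C,
        COMPARISON_T2T4_VS_C,
        COMPARISON_T2T4_VS_TA,
    }
    assert (results["adj_pvalue"] >= results["pvalue"] - 1e-12).all()
    assert results["adj_pvalue"].between(0, 1).all()
    # pairwise mode agrees on the coefficient (means difference) though
    # not necessarily on the standard error
    pairwise = run_differential_tests(levels, sheet, mode="pairwise")
    merged = results.merge(pairwise, on=["sequence", "comparison"], suffixes=("_p", "_w"))
    assert np.allclose(merged["coef_p"], merged["coef_w"])
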