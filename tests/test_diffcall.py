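"""Normalisation, dispersion, NB Wald test, BH correction, site calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import tiercall as tc
from tiercall.diffcall import DISPERSION_FLOOR, estimate_dispersion
from tiercall.errors import InputError, NormalizationError


def _matrix(rows, columns):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i, "+") for i in range(len(rows))], names=["chrom", "pos0", "strand"]
    )
    return pd.DataFrame(rows, index=idx, columns=columns)


def _design44():
    return [
        tc.SampleDesign("wt1", "WT", 44, 1),
        tc.SampleDesign("wt2", "WT", 44, 2),
        tc.SampleDesign("wt3", "WT", 44, 3),
        tc.SampleDesign("ts1", "TS", 44, 1),
        tc.SampleDesign("ts2", "TS", 44, 2),
        tc.SampleDesign("ts3", "TS", 44, 3),
    ]


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = _matrix([[5, 5], [9, 9], [2, 2]], ["a", "b"])
        sf = tc.size_factors(m)
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_rank_one_matrix_closed_form(self):
        # every row ratio to the geometric mean is 1/sqrt(2) and sqrt(2)
        m = _matrix([[10, 20], [30, 60], [50, 100]], ["a", "b"])
        sf = tc.size_factors(m)
        np.testing.assert_allclose(sf, [2**-0.5, 2**0.5], rtol=1e-12)

    def test_scale_equivariance_and_row_permutation_invariance(self):
        # scaling one library by k multiplies its size factor *relative to
        # every other library* by k (the geometric-mean reference absorbs
        # a factor k^(1/m), so raw factors shift by k^(-1/m) across the board)
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(1, 100, size=(50, 4)), list("abcd"))
        sf = tc.size_factors(m)
        scaled = m.copy()
        scaled["c"] = scaled["c"] * 7
        sf2 = tc.size_factors(scaled)
        for other in "abd":
            np.testing.assert_allclose(
                sf2["c"] / sf2[other], 7 * sf["c"] / sf[other], rtol=1e-12
            )
        np.testing.assert_allclose(sf2[["a", "b", "d"]] / sf[["a", "b", "d"]], 7**-0.25)
        perm = m.sample(frac=1, random_state=1)
        np.testing.assert_allclose(tc.size_factors(perm), sf, rtol=1e-12)

    def test_no_all_positive_row_raises(self):
        m = _matrix([[0, 5], [3, 0]], ["a", "b"])
        with pytest.raises(NormalizationError):
            tc.size_factors(m)


class TestDispersion:
    def test_equal_counts_floor(self):
        m = _matrix([[100, 100, 100, 10, 10, 10]], [d.sample_id for d in _design44()])
        sf = pd.Series(1.0, index=m.columns)
        alpha = estimate_dispersion(m, sf, [m.columns[:3], m.columns[3:]])
        np.testing.assert_allclose(alpha, DISPERSION_FLOOR)

    def test_method_of_moments_recovers_simulated_dispersion(self):
        rng = np.random.default_rng(3)
        n, alpha_true, mu = 10_000, 0.2, 50.0
        counts = rng.poisson(rng.gamma(1 / alpha_true, mu * alpha_true, (n, 3)))
        m = _matrix(counts, ["a", "b", "c"])
        sf = pd.Series(1.0, index=m.columns)
        alpha = estimate_dispersion(m, sf, [["a", "b", "c"]])
        assert 0.05 <= np.median(alpha) <= 0.5


class TestPositionFilter:
    def test_threshold_is_any_contrast_library(self):
        m = _matrix([[25, 0, 0, 0], [19, 19, 19, 19]], ["a", "b", "c", "d"])
        mask = tc.position_filter(m, ["a", "b", "c", "d"], min_coverage=20)
        assert mask.tolist() == [True, False]

    def test_zero_threshold_keeps_everything(self):
        m = _matrix([[0, 0], [1, 0]], ["a", "b"])
        assert tc.position_filter(m, ["a", "b"], min_coverage=0).all()


class TestNBTest:
    def test_threefold_depletion_fixture(self):
        design = _design44()
        m = _matrix([[200, 180, 220, 24, 26, 25]], [d.sample_id for d in design])
        sf = pd.Series(1.0, index=m.columns)
        alpha = estimate_dispersion(m, sf, [m.columns[:3], m.columns[3:]])
        res = tc.nb_test(m, sf, alpha, design)
        assert res["log2fc"].iloc[0] == pytest.approx(-3.0, abs=0.05)
        assert res["p"].iloc[0] < 1e-4

    def test_null_fixture(self):
        design = _design44()
        m = _matrix([[50, 60, 55, 55, 60, 50]], [d.sample_id for d in design])
        sf = pd.Series(1.0, index=m.columns)
        alpha = estimate_dispersion(m, sf, [m.columns[:3], m.columns[3:]])
        res = tc.nb_test(m, sf, alpha, design)
        assert abs(res["log2fc"].iloc[0]) < 0.2
        assert res["p"].iloc[0] > 0.5

    def test_poisson_limit_matches_two_sample_poisson_wald(self):
        design = _design44()
        m = _matrix([[1000, 1020, 980, 880, 900, 890]], [d.sample_id for d in design])
        sf = pd.Series(1.0, index=m.columns)
        res = tc.nb_test(m, sf, np.array([1e-8]), design)
        mw, mt = 1000.0, 890.0
        z = np.log(mt / mw) / np.sqrt(1 / (3 * mt) + 1 / (3 * mw))
        p_oracle = 2 * sps.norm.sf(abs(z))
        assert res["p"].iloc[0] == pytest.approx(p_oracle, rel=0.10)


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            tc.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_and_tied_pvalues(self):
        np.testing.assert_allclose(tc.bh_adjust([0.37]), [0.37])
        np.testing.assert_allclose(tc.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            tc.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_agrees_with_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = tc.bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-10, atol=1e-12)
        assert (ours >= 0).all() and (ours <= 1).all()
        # monotone in p-rank
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(ours[order]) >= -1e-15).all()


class TestCalling:
    def _tests(self, rows):
        idx = pd.MultiIndex.from_tuples(
            [("chr1", i, "+") for i in range(len(rows))],
            names=["chrom", "pos0", "strand"],
        )
        return pd.DataFrame(rows, index=idx, columns=["log2fc", "padj"]).assign(
            base_mean=50.0, se=0.3, p=lambda d: d["padj"]
        )

    def test_threshold_logic(self):
        t = self._tests(
            [
                [-2.2, 0.01],  # |FC| ~ 4.6, significant -> called
                [-1.2, 0.001],  # FC below 3 -> not called
                [-3.5, 0.06],  # padj above 0.05 -> not called
                [2.5, 0.01],  # enriched, depleted direction -> not called
            ]
        )
        called = tc.call_cleavage_sites(t)
        assert list(called.table.index.get_level_values("pos0")) == [0]
        both = tc.call_cleavage_sites(t, direction="both")
        assert list(both.table.index.get_level_values("pos0")) == [0, 3]

    def test_requires_padj_column(self):
        t = self._tests([[-2.2, 0.01]]).drop(columns="padj")
        with pytest.raises(InputError):
            tc.call_cleavage_sites(t)

    def test_thirty_degree_control_filter(self):
        t = self._tests([[-2.2, 0.01], [-2.5, 0.01]])
        t["log2fc_30"] = [0.1, -2.0]  # second site also differs at 30 degC
        called = tc.call_cleavage_sites(t, require_null_at_30=True)
        assert list(called.table.index.get_level_values("pos0")) == [0]
        t2 = t.drop(columns="log2fc_30")
        with pytest.raises(InputError):
            tc.call_cleavage_sites(t2, require_null_at_30=True)

    def test_control_ratio_is_null_at_planted_sites(self, default_scenario):
        """At 30 degC both strains cleave, so the strain ratio there should
        not reach the calling threshold at genuine sites: the control
        filter must retain nearly all true calls."""
        results = default_scenario["results"]
        assert "log2fc_30" in results.columns
        truth = default_scenario["dataset"].truth.site_keys()
        plain = tc.call_cleavage_sites(results)
        strict = tc.call_cleavage_sites(results, require_null_at_30=True)
        tp_plain = len(plain.keys() & truth)
        tp_strict = len(strict.keys() & truth)
        assert tp_strict >= 0.95 * tp_plain
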