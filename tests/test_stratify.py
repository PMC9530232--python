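"""Reference normalization, strata assignment, rate tables, rank statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, norm, rankdata

from episig import (
    StrataConfig,
    assign_strata,
    kruskal_dunn,
    normalize_to_reference,
    outcome_rates,
    spearman_ci,
)

from _oracles import fisher_two_sided, spearman_d2


class TestNormalizeToReference:
    def test_control_mean_zero_and_worked_value(self):
        e = pd.DataFrame(
            {"c1": [2.0], "c2": [4.0], "p1": [5.0]}, index=["g"]
        )
        out = normalize_to_reference(e, ["c1", "c2"])
        assert out.loc["g", ["c1", "c2"]].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.loc["g", "p1"] == pytest.approx(2.0)

    def test_shift_invariance_for_patients(self):
        rng = np.random.default_rng(0)
        e = pd.DataFrame(rng.normal(size=(5, 6)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"s{j}" for j in range(6)])
        out1 = normalize_to_reference(e, ["s0", "s1"])
        out2 = normalize_to_reference(e + 13.7, ["s0", "s1"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_controls(self):
        e = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="2 control"):
            normalize_to_reference(e, ["a"])


class TestAssignStrata:
    def test_printed_cutpoints(self):
        """ES just below 0 is low; ES exactly 0.25 is high; 0 is mid."""
        es = pd.Series([-0.01, 0.25, 0.0, 0.24, 5.0], index=list("abcde"))
        lab = assign_strata(es)
        assert list(lab) == ["low", "high", "mid", "mid", "high"]

    def test_idempotent_and_total(self):
        rng = np.random.default_rng(1)
        es = pd.Series(rng.normal(size=100))
        lab1 = assign_strata(es)
        lab2 = assign_strata(es)
        assert lab1.notna().all()
        pd.testing.assert_series_equal(lab1, lab2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    def test_every_finite_score_gets_a_label(self, v):
        lab = assign_strata(pd.Series([v]))
        assert lab.iloc[0] in ("low", "mid", "high")

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            assign_strata(pd.Series([np.nan]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            StrataConfig(thresholds=(0.25, 0.0))
        with pytest.raises(ValueError):
            StrataConfig(thresholds=(0.0,), labels=("a", "b", "c"))


def _cohort(resp_by_stratum):
    """Build a one-arm patient cohort with given (n_resp, n_total) per stratum."""
    rows, es = [], []
    for stratum, (k, n) in resp_by_stratum.items():
        base = {"low": -0.5, "mid": 0.1, "high": 0.5}[stratum]
        for i in range(n):
            rows.append({"group": "patient", "arm": "active",
                         "clinical_remission": 1.0 if i < k else 0.0})
            es.append(base)
    idx = pd.Index([f"p{i}" for i in range(len(rows))], name="sample")
    return pd.DataFrame(rows, index=idx), pd.Series(es, index=idx)


class TestOutcomeRates:
    def test_all_responders_rate_one(self):
        cohort, es = _cohort({"low": (10, 10), "high": (10, 10)})
        rates, _ = outcome_rates(cohort, assign_strata(es), "clinical_remission")
        filled = rates[rates["denominator"] > 0]
        assert (filled["rate"] == 1.0).all()

    def test_exact_tail_worked_value(self):
        """5/10 vs 1/10: one-sided exact upper tail is 13013/184756."""
        from scipy.stats import fisher_exact

        table = [[5, 5], [1, 9]]
        _, p_one = fisher_exact(table, alternative="greater")
        assert p_one == pytest.approx(13013 / 184756)
        # the pipeline reports the classical two-sided version of the same table
        cohort, es = _cohort({"low": (5, 10), "high": (1, 10)})
        _, pw = outcome_rates(cohort, assign_strata(es), "clinical_remission")
        assert pw["p_fisher"].iloc[0] == pytest.approx(
            fisher_two_sided(5, 5, 1, 9)
        )

    def test_two_sided_fisher_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            k1, n1 = rng.integers(0, 10), 10
            k2, n2 = rng.integers(0, 10), 10
            cohort, es = _cohort({"low": (int(k1), n1), "high": (int(k2), n2)})
            _, pw = outcome_rates(cohort, assign_strata(es), "clinical_remission")
            assert pw["p_fisher"].iloc[0] == pytest.approx(
                fisher_two_sided(int(k1), n1 - int(k1), int(k2), n2 - int(k2))
            )

    def test_sample_order_invariance(self):
        cohort, es = _cohort({"low": (3, 8), "mid": (2, 6), "high": (1, 9)})
        r1, _ = outcome_rates(cohort, assign_strata(es), "clinical_remission")
        perm = np.random.default_rng(3).permutation(len(cohort))
        r2, _ = outcome_rates(cohort.iloc[perm], assign_strata(es), "clinical_remission")
        pd.testing.assert_frame_equal(r1, r2)

    def test_unknown_outcome(self):
        cohort, es = _cohort({"low": (1, 2)})
        with pytest.raises(ValueError, match="unknown outcome"):
            outcome_rates(cohort, assign_strata(es), "nope")


class TestSpearmanCI:
    def test_cohort_scale_ci_rounds_to_printed_interval(self):
        """r = 0.54 at n = 550 gives a 95% CI of (0.48, 0.60) at 2 decimals."""
        z = np.arctanh(0.54)
        se = 1 / np.sqrt(550 - 3)
        lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
        assert (round(lo, 2), round(hi, 2)) == (0.48, 0.60)
        # and the function reproduces the same arithmetic on data with r=0.54
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(size=550)
            y = 0.6 * x + rng.normal(size=550)
            res = spearman_ci(x, y)
            z2 = np.arctanh(res["r"])
            assert res["ci_low"] == pytest.approx(np.tanh(z2 - 1.959964 * se), abs=1e-9)

    def test_monotone_pair_r_one(self):
        x = np.arange(10.0)
        res = spearman_ci(x, np.exp(x))
        assert res["r"] == pytest.approx(1.0)

    def test_d2_formula_on_triplet_plus_one(self):
        """x=(1,2,3,4), y=(3,1,2,4): agrees with the 1-6*sum(d^2) formula."""
        x, y = [1, 2, 3, 4], [3, 1, 2, 4]
        res = spearman_ci(x, y)
        assert res["r"] == pytest.approx(spearman_d2(x, y))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="4 pairs"):
            spearman_ci([1, 2, 3], [1, 2, 3])


class TestKruskalDunn:
    def test_worked_small_example(self):
        """A=(1,2), B=(3,4): H = 2.4, p = Pr(chi2_1 >= 2.4) ~ 0.121."""
        res = kruskal_dunn([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert res["H"] == pytest.approx(2.4)
        assert res["p_global"] == pytest.approx(chi2.sf(2.4, 1))

    def test_identical_groups_null(self):
        res = kruskal_dunn([5, 5, 5, 5], ["A", "A", "B", "B"])
        assert res["H"] == pytest.approx(0.0)
        assert res["p_global"] == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        vals = [3, 1, 4, 1, 5, 9, 2, 6]
        g1 = ["A", "A", "B", "B", "C", "C", "C", "A"]
        g2 = ["X", "X", "Y", "Y", "Z", "Z", "Z", "X"]
        assert kruskal_dunn(vals, g1)["H"] == pytest.approx(kruskal_dunn(vals, g2)["H"])

    def test_dunn_z_by_hand(self):
        """Dunn z from pooled rank sums, no ties."""
        vals = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        groups = ["A", "A", "A", "B", "B", "B"]
        res = kruskal_dunn(vals, groups)
        ranks = rankdata(vals)
        mr_a, mr_b = ranks[:3].mean(), ranks[3:].mean()
        n = 6
        se = np.sqrt((n * (n + 1) / 12) * (1 / 3 + 1 / 3))
        z_hand = (mr_a - mr_b) / se
        assert res["pairwise"]["z"].iloc[0] == pytest.approx(z_hand)
        assert res["pairwise"]["p_adj"].iloc[0] == pytest.approx(
            min(1.0, 2 * norm.sf(abs(z_hand)))
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_dunn([1, 2], ["A", "A"])
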