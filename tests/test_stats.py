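"""Variance partitioning, Tukey-Kramer and correlation, cross-checked
against independent oracles (scipy.stats.f_oneway, statsmodels Tukey HSD)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from psychrosap.stats import (
    GroupSummary,
    anova_from_summaries,
    anova_raw,
    correlate_capacities,
    isolate_anova,
    tukey_hsd,
)


def summaries_of(groups):
    return [
        GroupSummary(label, len(v), float(np.mean(v)), float(np.std(v, ddof=1)))
        for label, v in groups
    ]


class TestGroupSummary:
    def test_sd_derived_from_sem(self):
        g = GroupSummary("a", 4, 0.5, sem=0.1)
        assert g.sd == pytest.approx(0.2)

    def test_inconsistent_sd_and_sem_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GroupSummary("a", 4, 0.5, sd=0.5, sem=0.1)

    @pytest.mark.parametrize("kwargs", [{"n": 1, "sd": 1.0}, {"n": 3},
                                        {"n": 3, "sd": -0.1}])
    def test_invalid_summaries_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GroupSummary("a", mean=0.0, **kwargs)


class TestAnova:
    def test_hand_worked_two_group_example(self):
        """{1,2,3} vs {2,3,4}: SS_among 1.5, SS_within 4, F 1.5."""
        res = anova_from_summaries([
            GroupSummary("g1", 3, 2.0, sd=1.0),
            GroupSummary("g2", 3, 3.0, sd=1.0),
        ])
        assert res["among"].ss == pytest.approx(1.5)
        assert res["within"].ss == pytest.approx(4.0)
        assert res["among"].f == pytest.approx(1.5)
        raw = anova_raw([("g1", [1, 2, 3]), ("g2", [2, 3, 4])])
        assert raw["among"].ss == pytest.approx(res["among"].ss)
        assert raw["among"].p == pytest.approx(res["among"].p)

    def test_identical_means_give_zero_among(self):
        res = anova_from_summaries([
            GroupSummary("g1", 3, 2.0, sd=1.0),
            GroupSummary("g2", 5, 2.0, sd=0.5),
        ])
        assert res["among"].ss == pytest.approx(0.0)
        assert res["among"].f == pytest.approx(0.0)
        assert res.percent_among == pytest.approx(0.0)

    def test_zero_within_variance_flagged_infinite_f(self):
        res = anova_from_summaries([
            GroupSummary("g1", 3, 1.0, sd=0.0),
            GroupSummary("g2", 3, 2.0, sd=0.0),
        ])
        assert math.isinf(res["among"].f) and res["among"].p == 0.0
        assert res.degenerate

    def test_all_values_equal_is_degenerate(self):
        res = anova_raw([("g1", [2.0, 2.0]), ("g2", [2.0, 2.0])])
        assert res["total"].ss == 0.0
        assert res.degenerate

    def test_summary_and_raw_routes_agree_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k = rng.integers(2, 6)
            groups = [
                (f"g{i}", rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 2),
                                     size=rng.integers(2, 9)))
                for i in range(k)
            ]
            raw = anova_raw(groups)
            summ = anova_from_summaries(summaries_of(groups))
            for src in ("among", "within", "total"):
                assert summ[src].ss == pytest.approx(raw[src].ss, rel=1e-10)
                assert summ[src].df == raw[src].df
            assert summ["among"].f == pytest.approx(raw["among"].f, rel=1e-10)
            assert summ["among"].p == pytest.approx(raw["among"].p, rel=1e-8)

    def test_f_and_p_match_scipy_oneway(self):
        rng = np.random.default_rng(7)
        groups = [("a", rng.normal(0, 1, 5)), ("b", rng.normal(1, 1, 8)),
                  ("c", rng.normal(0.5, 2, 4))]
        res = anova_raw(groups)
        f, p = sps.f_oneway(*(v for _, v in groups))
        assert res["among"].f == pytest.approx(f, rel=1e-12)
        assert res["among"].p == pytest.approx(p, rel=1e-12)

    def test_additivity_and_percent_invariants(self):
        rng = np.random.default_rng(11)
        groups = [(f"g{i}", rng.normal(i, 1, 6)) for i in range(4)]
        res = anova_raw(groups)
        assert res["among"].df + res["within"].df == res["total"].df
        assert res["among"].ss + res["within"].ss == pytest.approx(res["total"].ss)
        assert res.percent_among + res.percent_within == pytest.approx(100.0)
        assert res["among"].f == pytest.approx(res["among"].ms / res["within"].ms)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summaries([GroupSummary("g", 3, 1.0, sd=1.0)])
        with pytest.raises(ValueError):
            anova_raw([("g1", [1.0, 2.0]), ("g2", [3.0])])


class TestIsolateAnova:
    def make_estimates(self, means, sds):
        return pd.DataFrame({
            "isolate_id": [f"i{j}" for j in range(len(means))],
            "boot_mean": means,
            "boot_sd": sds,
        })

    def test_df_rows_for_forty_isolates_four_replicates(self):
        rng = np.random.default_rng(0)
        est = self.make_estimates(rng.normal(0.2, 0.2, 40), rng.uniform(0.01, 0.1, 40))
        res = isolate_anova(est, n_per_isolate=4)
        assert (res["among"].df, res["within"].df, res["total"].df) == (39, 120, 159)

    def test_identical_isolates_have_zero_among_share(self):
        est = self.make_estimates([0.3] * 10, [0.05] * 10)
        res = isolate_anova(est, n_per_isolate=4)
        assert res.percent_among == pytest.approx(0.0)

    def test_large_spread_small_noise_dominates_partition(self):
        rng = np.random.default_rng(1)
        est = self.make_estimates(rng.normal(0.2, 0.5, 40), [0.01] * 40)
        res = isolate_anova(est, n_per_isolate=4)
        assert res.percent_among > 90

    def test_duplicate_isolates_rejected(self):
        est = self.make_estimates([0.1, 0.2], [0.05, 0.05])
        est.loc[1, "isolate_id"] = "i0"
        with pytest.raises(ValueError, match="duplicate"):
            isolate_anova(est)


class TestTukey:
    def test_all_means_equal_share_one_letter(self):
        groups = [GroupSummary(f"g{i}", 5, 1.0, sd=0.5) for i in range(4)]
        res = tukey_hsd(groups, ms_within=0.25, df_within=16)
        assert set(res.letters.values()) == {"a"}

    def test_extreme_separation_gets_distinct_letters(self):
        """q far beyond the critical value -> different letters; the critical
        value itself checked against the studentized-range CDF."""
        groups = [GroupSummary("hi", 5, 100.0, sd=0.1),
                  GroupSummary("lo", 5, 0.0, sd=0.1)]
        res = tukey_hsd(groups, ms_within=0.01, df_within=8)
        assert res.letters["hi"] != res.letters["lo"]
        assert sps.studentized_range.cdf(res.q_critical, 2, 8) == pytest.approx(0.95)

    def test_letters_shift_invariant(self):
        rng = np.random.default_rng(3)
        means = rng.normal(0, 1, 5)
        groups = [GroupSummary(f"g{i}", 6, float(m), sd=0.8)
                  for i, m in enumerate(means)]
        shifted = [GroupSummary(g.label, g.n, g.mean + 17.3, sd=g.sd)
                   for g in groups]
        a = tukey_hsd(groups, ms_within=0.64, df_within=25)
        b = tukey_hsd(shifted, ms_within=0.64, df_within=25)
        assert a.letters == b.letters
        pd.testing.assert_series_equal(a.comparisons["q"], b.comparisons["q"])

    def test_significance_flags_match_statsmodels_oracle(self):
        """Balanced raw-data comparison against statsmodels pairwise_tukeyhsd."""
        rng = np.random.default_rng(5)
        raw = {f"g{i}": rng.normal(mu, 1.0, 6)
               for i, mu in enumerate([0.0, 0.5, 2.5, 3.0])}
        values = np.concatenate(list(raw.values()))
        labels = np.repeat(list(raw.keys()), [len(v) for v in raw.values()])
        sm = pairwise_tukeyhsd(values, labels, alpha=0.05)
        # result-table rows are [group1, group2, meandiff, ...]
        sm_flags = {
            frozenset((row[0], row[1])): bool(rej)
            for row, rej in zip(sm._results_table.data[1:], sm.reject)
        }
        anova = anova_raw(list(raw.items()))
        res = tukey_hsd(summaries_of(list(raw.items())),
                        ms_within=anova["within"].ms,
                        df_within=anova["within"].df)
        ours = {
            frozenset((row.group_1, row.group_2)): bool(row.significant)
            for row in res.comparisons.itertuples()
        }
        assert ours == sm_flags

    def test_letters_are_clique_cover_of_nonsignificance_graph(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            k = int(rng.integers(3, 7))
            groups = [
                GroupSummary(f"g{i}", int(rng.integers(3, 10)),
                             float(rng.normal(0, 1)), sd=float(rng.uniform(0.2, 1)))
                for i in range(k)
            ]
            res = tukey_hsd(groups, ms_within=float(rng.uniform(0.05, 1.0)),
                            df_within=int(rng.integers(5, 40)))
            sig = {
                frozenset((r.group_1, r.group_2)): r.significant
                for r in res.comparisons.itertuples()
            }
            for pair, significant in sig.items():
                g1, g2 = sorted(pair)
                shared = set(res.letters[g1]) & set(res.letters[g2])
                if significant:
                    assert not shared, (trial, g1, g2, res.letters)
                else:
                    assert shared, (trial, g1, g2, res.letters)

    @pytest.mark.parametrize("kwargs", [
        {"ms_within": 0.0, "df_within": 10},
        {"ms_within": 0.1, "df_within": 0},
        {"ms_within": 0.1, "df_within": 10, "alpha": 1.5},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        groups = [GroupSummary("a", 3, 0.0, sd=1.0), GroupSummary("b", 3, 1.0, sd=1.0)]
        with pytest.raises(ValueError):
            tukey_hsd(groups, **kwargs)


class TestCorrelation:
    def frame(self, ids, values):
        return pd.DataFrame({"isolate_id": ids, "boot_mean": values})

    def test_perfect_linearity(self):
        ids = list("abcd")
        x = [0.1, 0.2, 0.3, 0.5]
        res = correlate_capacities(self.frame(ids, x),
                                   self.frame(ids, [2 * v for v in x]))
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_hand_computed_r(self):
        """x = 1..4 against y = {2,1,4,3}: r = 0.6."""
        ids = list("abcd")
        res = correlate_capacities(self.frame(ids, [1, 2, 3, 4]),
                                   self.frame(ids, [2, 1, 4, 3]))
        assert res.r == pytest.approx(0.6)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(t, res.n - 2), rel=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        ids = [f"i{j}" for j in range(12)]
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = correlate_capacities(self.frame(ids, x), self.frame(ids, y))
        scaled = correlate_capacities(self.frame(ids, 3.0 * x + 1.0),
                                      self.frame(ids, 0.5 * y - 2.0))
        assert scaled.r == pytest.approx(base.r, rel=1e-12)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_pairing_ignores_row_order(self):
        ids = list("abcd")
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        shuffled = self.frame(ids[::-1], y[::-1])
        res = correlate_capacities(self.frame(ids, x), shuffled)
        assert res.r == pytest.approx(0.6)

    def test_mismatched_isolate_sets_rejected_with_difference(self):
        with pytest.raises(ValueError, match=r"\['c', 'd'\]"):
            correlate_capacities(self.frame(["a", "b", "c"], [1, 2, 3]),
                                 self.frame(["a", "b", "d"], [1, 2, 3]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate_capacities(self.frame(["a", "b"], [1, 2]),
                                 self.frame(["a", "b"], [1, 2]))
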