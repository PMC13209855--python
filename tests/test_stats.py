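"""ANOVA, Tukey-Kramer, and compact-letter-display behavior, including the
published nine-formulation groupings and a cross-check against statsmodels."""

import numpy as np
import pytest
from scipy import stats as sps

from capmetrics import reference
from capmetrics.errors import DegenerateVarianceError
from capmetrics.stats import (
    GroupData,
    anova_oneway,
    check_assumptions,
    compact_letter_display,
    tukey_family_error_rate,
    tukey_hsd,
)


def _letters_for(summary_dict, n=3):
    g = GroupData.from_summary_dict(summary_dict, n=n)
    comps = tukey_hsd(g)
    return compact_letter_display(comps, dict(zip(g.labels, g.means))), comps


class TestGroupData:
    def test_raw_and_summary_agree_by_construction(self):
        raw = {
            "A": [1.0, 2.0, 3.0],
            "B": [2.0, 3.0, 4.0],
            "C": [10.0, 11.0, 12.0],
        }
        g_raw = GroupData.from_raw(raw)
        g_sum = GroupData.from_summary(
            g_raw.labels, g_raw.means, g_raw.sds, g_raw.ns
        )
        a_raw, a_sum = anova_oneway(g_raw), anova_oneway(g_sum)
        assert a_raw.f_statistic == pytest.approx(a_sum.f_statistic, rel=1e-12)
        assert a_raw.p_value == pytest.approx(a_sum.p_value, rel=1e-12)
        for c1, c2 in zip(tukey_hsd(g_raw), tukey_hsd(g_sum)):
            assert c1.p_adjusted == pytest.approx(c2.p_adjusted, rel=1e-12)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            GroupData.from_raw({"A": [1.0], "B": [1.0, 2.0]})

    def test_two_groups_minimum(self):
        with pytest.raises(ValueError):
            GroupData.from_raw({"A": [1.0, 2.0]})


class TestAssumptions:
    def test_normal_groups_pass_levene(self):
        rng = np.random.default_rng(0)
        g = GroupData.from_raw(
            {"A": rng.normal(0, 1, 30), "B": rng.normal(0, 1, 30)}
        )
        norm_p, lev_p = check_assumptions(g)
        assert lev_p > 0.05
        assert all(p > 0.01 for p in norm_p.values())

    def test_constant_group_reports_nan_normality(self):
        g = GroupData.from_raw({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        norm_p, _ = check_assumptions(g)
        assert np.isnan(norm_p["A"])

    def test_summary_only_input_returns_markers(self):
        g = GroupData.from_summary_dict({"A": (1.0, 0.1), "B": (2.0, 0.1)})
        norm_p, lev_p = check_assumptions(g)
        assert np.isnan(lev_p)


class TestAnova:
    def test_identical_groups_give_f_near_zero(self):
        g = GroupData.from_summary_dict({"A": (5.0, 1.0), "B": (5.0, 1.0)})
        assert anova_oneway(g).f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_identical_rejected(self):
        g = GroupData.from_summary_dict({"A": (5.0, 0.0), "B": (5.0, 0.0)})
        with pytest.raises(DegenerateVarianceError):
            anova_oneway(g)

    def test_published_moisture_summaries_significant(self):
        g = GroupData.from_summary_dict(reference.MOISTURE_PCT)
        res = anova_oneway(g)
        assert res.p_value < 0.05
        assert res.df_within == 18 and res.df_between == 8

    def test_matches_scipy_f_oneway_on_raw_data(self):
        rng = np.random.default_rng(3)
        raw = {k: rng.normal(i, 1, 5) for i, k in enumerate("ABCD")}
        res = anova_oneway(GroupData.from_raw(raw))
        f_ref, p_ref = sps.f_oneway(*raw.values())
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, rel=1e-10)


class TestTukey:
    def test_huge_separation_significant(self):
        g = GroupData.from_summary_dict({"A": (0.0, 1.0), "B": (100.0, 1.0)})
        comps = tukey_hsd(g)
        assert comps[0].significant

    def test_identical_groups_not_significant(self):
        g = GroupData.from_summary_dict({"A": (5.0, 1.0), "B": (5.0, 1.0)})
        assert not tukey_hsd(g)[0].significant

    def test_two_groups_reduce_to_t_test(self):
        """For k = 2 the studentized-range p equals the pooled t-test p."""
        raw = {"A": [1.0, 2.0, 3.0, 2.5], "B": [4.0, 5.0, 4.5, 6.0]}
        g = GroupData.from_raw(raw)
        comp = tukey_hsd(g)[0]
        t_p = sps.ttest_ind(raw["A"], raw["B"]).pvalue
        assert comp.p_adjusted == pytest.approx(t_p, rel=1e-6)

    def test_zero_variance_rejected(self):
        g = GroupData.from_summary_dict({"A": (1.0, 0.0), "B": (2.0, 0.0)})
        with pytest.raises(DegenerateVarianceError):
            tukey_hsd(g)

    def test_published_ee_summaries_single_significant_pair(self):
        g = GroupData.from_summary_dict(reference.ENCAPSULATION_EFFICIENCY_PCT)
        sig = [c for c in tukey_hsd(g) if c.significant]
        assert len(sig) == 1
        assert {sig[0].label_a, sig[0].label_b} == {"SHS", "ETA"}

    def test_matches_statsmodels_on_raw_data(self):
        """Independent oracle: statsmodels' Tukey HSD on raw unbalanced data."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(11)
        raw = {
            "A": rng.normal(0.0, 1.0, 4),
            "B": rng.normal(1.0, 1.0, 6),
            "C": rng.normal(2.5, 1.0, 5),
        }
        g = GroupData.from_raw(raw)
        ours = {
            frozenset((c.label_a, c.label_b)): c.p_adjusted for c in tukey_hsd(g)
        }
        values = np.concatenate(list(raw.values()))
        labels = sum(([k] * len(v) for k, v in raw.items()), [])
        ref = pairwise_tukeyhsd(values, labels)
        pairs = [(row[0], row[1]) for row in ref.summary().data[1:]]
        for (a, b), p in zip(pairs, ref.pvalues):
            assert ours[frozenset((a, b))] == pytest.approx(p, abs=1e-6)


class TestLetterDisplay:
    def test_no_significant_pairs_all_share_a(self):
        g = GroupData.from_summary_dict(
            {"A": (5.0, 1.0), "B": (5.1, 1.0), "C": (4.9, 1.0)}
        )
        letters = compact_letter_display(
            tukey_hsd(g), dict(zip(g.labels, g.means))
        )
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters_by_descending_mean(self):
        g = GroupData.from_summary_dict(
            {"low": (0.0, 0.1), "mid": (10.0, 0.1), "high": (20.0, 0.1)}
        )
        letters = compact_letter_display(
            tukey_hsd(g), dict(zip(g.labels, g.means))
        )
        assert letters == {"high": "a", "mid": "b", "low": "c"}

    def test_published_moisture_grouping(self):
        """Five homogeneous groups; the highest-moisture formulation is alone
        in 'a' and the three driest share the bottom letter 'e'."""
        letters, _ = _letters_for(reference.MOISTURE_PCT)
        distinct = set("".join(letters.values()))
        assert len(distinct) == 5
        assert letters["CON"] == "a"
        assert sum(1 for v in letters.values() if "a" in v) == 1
        assert letters["STA"] == letters["CTA"] == letters["CHS"] == "e"

    @pytest.mark.parametrize("seed", range(20))
    def test_contract_share_letter_iff_not_significant(self, seed):
        """For random significance patterns (k <= 10), two groups share at
        least one letter iff their pair is not significant."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 11))
        labels = [f"g{i}" for i in range(k)]
        means = {lb: float(rng.normal()) for lb in labels}
        from capmetrics.stats import PairwiseComparison

        comps = []
        for i in range(k):
            for j in range(i + 1, k):
                sig = bool(rng.random() < 0.4)
                comps.append(
                    PairwiseComparison(
                        label_a=labels[i], label_b=labels[j],
                        mean_difference=means[labels[i]] - means[labels[j]],
                        q_statistic=0.0, p_adjusted=0.0 if sig else 1.0,
                        significant=sig,
                    )
                )
        letters = compact_letter_display(comps, means)
        sig_map = {
            frozenset((c.label_a, c.label_b)): c.significant for c in comps
        }
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
                assert share != sig_map[frozenset((labels[i], labels[j]))]

    def test_letters_start_at_a_for_largest_mean(self):
        g = GroupData.from_summary_dict(
            {"small": (1.0, 0.05), "big": (9.0, 0.05)}
        )
        letters = compact_letter_display(
            tukey_hsd(g), dict(zip(g.labels, g.means))
        )
        assert "a" in letters["big"]


class TestFamilyWiseError:
    def test_shortcut_agrees_with_full_tukey_on_replicates(self):
        """The max-studentized-range shortcut declares a family significant
        exactly when tukey_hsd flags any pair."""
        rng = np.random.default_rng(2)
        k, n = 5, 3
        df_w = k * (n - 1)
        q_crit = sps.studentized_range.ppf(0.95, k, df_w)
        for _ in range(20):
            data = rng.normal(size=(k, n))
            g = GroupData.from_raw({f"g{i}": data[i] for i in range(k)})
            any_sig = any(c.significant for c in tukey_hsd(g))
            means = data.mean(axis=1)
            ms_w = data.var(axis=1, ddof=1).mean()
            q_max = (means.max() - means.min()) / np.sqrt(ms_w / n)
            assert any_sig == (q_max > q_crit)
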