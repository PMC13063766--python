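"""Truncation classification, plaque profiles, sampling, correlation and
group statistics."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abmsi.masslist import make_variant
from abmsi.plaques import (
    CATEGORIES,
    TruncationCategory,
    category_fractions,
    classify_truncation,
    compare_groups,
    log_pearson_matrix,
    sample_plaques,
    subject_profiles,
    truncation_profiles,
)


class TestClassification:
    @pytest.mark.parametrize(
        "start,end,pyroglu,expected",
        [
            (1, 42, False, TruncationCategory.full_length),
            (1, 40, False, TruncationCategory.full_length),
            (1, 38, False, TruncationCategory.C_truncated),
            (1, 36, False, TruncationCategory.C_truncated),
            (4, 42, False, TruncationCategory.N_truncated),
            (3, 42, True, TruncationCategory.N_truncated),
            (11, 40, True, TruncationCategory.N_truncated),
            (9, 38, False, TruncationCategory.bi_truncated),
            (2, 37, False, TruncationCategory.bi_truncated),
            (2, 39, False, TruncationCategory.bi_truncated),
            (2, 43, False, TruncationCategory.bi_truncated),
        ],
    )
    def test_reported_species_categories(self, start, end, pyroglu, expected):
        assert classify_truncation(make_variant(start, end, pyroglu)) is expected

    def test_partition_is_total_over_enumeration(self, masslist):
        for v in masslist:
            assert classify_truncation(v) in TruncationCategory


class TestFractions:
    def test_single_variant_plaque(self, masslist):
        frac = category_fractions({"Abeta1-42": 5.0}, masslist)
        assert frac["full_length"] == 1.0
        assert frac["C_truncated"] == frac["N_truncated"] == frac["bi_truncated"] == 0.0
        assert np.isnan(frac["split_40"])

    def test_equal_split_full_and_c(self, masslist):
        frac = category_fractions({"Abeta1-42": 2.0, "Abeta1-38": 2.0}, masslist)
        assert frac["full_length"] == pytest.approx(0.5)
        assert frac["C_truncated"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, masslist):
        rng = np.random.default_rng(0)
        abundances = {v.name: float(rng.gamma(1.0)) for v in masslist[::5]}
        frac = category_fractions(abundances, masslist)
        assert sum(frac[c] for c in CATEGORIES) == pytest.approx(1.0, abs=1e-9)

    def test_terminal_split_sums_to_one(self, masslist):
        frac = category_fractions(
            {"Abeta4-40": 1.0, "AbetapE3-42": 3.0, "Abeta1-42": 1.0}, masslist
        )
        assert frac["split_40"] + frac["split_42"] == pytest.approx(1.0)
        assert frac["split_42"] == pytest.approx(0.75)

    def test_zero_total_rejected(self, masslist):
        with pytest.raises(ValueError, match="undefined"):
            category_fractions({"Abeta1-42": 0.0}, masslist)

    def test_zero_plaques_excluded_with_warning(self, masslist):
        table = pd.DataFrame(
            {
                "plaque_id": [1, 2],
                "subject": ["s1", "s1"],
                "group": ["sAD", "sAD"],
                "area_um2": [400.0, 400.0],
                "Abeta1-42": [1.0, 0.0],
            }
        )
        with pytest.warns(UserWarning, match="zero total"):
            prof = truncation_profiles(table, masslist)
        assert len(prof) == 1


class TestSampling:
    def _table(self, counts):
        rows = []
        pid = 0
        for subject, n in counts.items():
            for _ in range(n):
                rows.append(
                    {"plaque_id": pid, "subject": subject, "group": "sAD",
                     "area_um2": 400.0, "Abeta1-42": 1.0}
                )
                pid += 1
        return pd.DataFrame(rows)

    def test_caps_rich_subjects(self):
        out = sample_plaques(self._table({"a": 500}), n_per_subject=300, seed=0)
        assert len(out) == 300
        assert out["plaque_id"].is_unique

    def test_clamps_poor_subjects_with_warning(self):
        with pytest.warns(UserWarning, match="only 120"):
            out = sample_plaques(self._table({"a": 120}), n_per_subject=300, seed=0)
        assert len(out) == 120

    def test_deterministic_under_seed(self):
        table = self._table({"a": 400, "b": 350})
        a = sample_plaques(table, n_per_subject=300, seed=7)
        b = sample_plaques(table, n_per_subject=300, seed=7)
        assert a["plaque_id"].tolist() == b["plaque_id"].tolist()
        c = sample_plaques(table, n_per_subject=300, seed=8)
        assert a["plaque_id"].tolist() != c["plaque_id"].tolist()

    def test_empty_table(self):
        out = sample_plaques(self._table({}), n_per_subject=300, seed=0)
        assert out.empty


class TestLogPearson:
    def _table(self, columns):
        df = pd.DataFrame(columns)
        df.insert(0, "plaque_id", range(len(df)))
        df.insert(1, "subject", "s1")
        df.insert(2, "group", "sAD")
        df.insert(3, "area_um2", 400.0)
        return df

    def test_proportional_variants_correlate_perfectly(self):
        base = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        table = self._table({"Abeta1-42": base, "Abeta1-40": 3.0 * base})
        R = log_pearson_matrix(table)
        assert R.loc["Abeta1-42", "Abeta1-40"] == pytest.approx(1.0)
        assert np.allclose(R.values, R.values.T)

    def test_constant_column_flagged_nan(self):
        table = self._table(
            {"Abeta1-42": [1.0, 2.0, 4.0], "Abeta1-40": [3.0, 3.0, 3.0]}
        )
        with pytest.warns(UserWarning, match="constant columns"):
            R = log_pearson_matrix(table)
        assert np.isnan(R.loc["Abeta1-40", "Abeta1-42"])
        assert R.loc["Abeta1-42", "Abeta1-42"] == pytest.approx(1.0)

    def test_lognormal_bivariate_recovery(self):
        """Estimated r falls in the 95% Fisher-z interval of the generating
        correlation in >= 90 % of replicates."""
        rho = 0.7
        n = 300
        rng = np.random.default_rng(123)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        half_width = 1.959964 / np.sqrt(n - 3)
        z_true = np.arctanh(rho)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            L = rng.multivariate_normal([0, 0], cov, size=n)
            table = self._table(
                {"Abeta1-42": np.exp(L[:, 0]), "Abeta1-40": np.exp(L[:, 1])}
            )
            r = log_pearson_matrix(table).loc["Abeta1-42", "Abeta1-40"]
            hits += abs(np.arctanh(r) - z_true) <= half_width
        assert hits / n_rep >= 0.90

    def test_too_few_plaques_rejected(self):
        table = self._table({"Abeta1-42": [1.0, 2.0]})
        with pytest.raises(ValueError):
            log_pearson_matrix(table)


class TestCompareGroups:
    def test_identical_groups_mann_whitney(self):
        # force the rank test with clearly non-normal duplicated values
        vals = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 10.0, 10.0])
        res = compare_groups({"a": vals, "b": vals})
        assert res.test == "mann_whitney"
        assert res.statistic == pytest.approx(len(vals) ** 2 / 2)
        assert res.p_value > 0.99

    def test_complete_separation_u_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        res = compare_groups({"a": a, "b": b})
        assert res.test == "mann_whitney" or res.test == "welch_t"
        u_a = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert u_a == 0.0
        # exact two-sided p for complete separation of 5 vs 5
        res_rank = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res_rank.pvalue == pytest.approx(2 / 252)

    def test_normal_data_uses_welch(self):
        rng = np.random.default_rng(5)
        res = compare_groups(
            {"a": rng.normal(0, 1, 40), "b": rng.normal(1, 2, 35)}
        )
        assert res.test == "welch_t"
        assert res.normality_p is not None and all(
            p > 0.05 for p in res.normality_p.values()
        )

    def test_small_group_skips_gate_with_warning(self):
        with pytest.warns(UserWarning, match="normality gate skipped"):
            res = compare_groups({"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0, 5.0])})
        assert res.test == "mann_whitney"

    def test_kruskal_wallis_hand_computed(self):
        # ranks 1..6 in three groups of two: H = 12/(6*7) * (8 + 0 + 8)
        res = compare_groups(
            {"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0]), "c": np.array([5.0, 6.0])},
        )
        assert res.test == "kruskal_wallis"
        assert res.statistic == pytest.approx(32.0 / 7.0)

    def test_dunn_posthoc_hand_computed(self):
        res = compare_groups(
            {
                "a": np.array([1.0, 2.0, 3.0]),
                "b": np.array([4.0, 5.0, 6.0]),
                "c": np.array([7.0, 8.0, 9.0]),
            },
        )
        assert res.posthoc is not None
        row = res.posthoc.set_index(["group_a", "group_b"]).loc[("a", "b")]
        # mean ranks 2 and 5; SE = sqrt((9*10/12)*(2/3)) = sqrt(5)
        assert row["z"] == pytest.approx(-3.0 / np.sqrt(5.0))
        assert row["p_raw"] == pytest.approx(
            2 * stats.norm.sf(3.0 / np.sqrt(5.0)), rel=1e-12
        )

    def test_power_on_shifted_gaussians(self):
        """Two n=300 samples shifted by one sd reject at alpha=0.05 in
        >= 99 % of simulations."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0, 1, 300)
            b = rng.normal(1, 1, 300)
            res = compare_groups({"a": a, "b": b})
            rejections += res.p_value <= 0.05
        assert rejections / n_rep >= 0.99

    def test_dunn_adjustments_monotone(self):
        groups = {
            "a": np.arange(10.0),
            "b": np.arange(10.0) + 3,
            "c": np.arange(10.0) + 8,
        }
        none = compare_groups(groups, posthoc_adjust="none").posthoc
        bonf = compare_groups(groups, posthoc_adjust="bonferroni").posthoc
        holm = compare_groups(groups, posthoc_adjust="holm").posthoc
        assert (bonf["p_adj"] >= none["p_adj"] - 1e-15).all()
        assert (holm["p_adj"] <= bonf["p_adj"] + 1e-15).all()


class TestSubjectProfiles:
    def test_pooled_and_mean_methods(self, masslist):
        table = pd.DataFrame(
            {
                "plaque_id": [0, 1],
                "subject": ["s1", "s1"],
                "group": ["sAD", "sAD"],
                "area_um2": [400.0, 800.0],
                "Abeta1-42": [3.0, 1.0],
                "Abeta1-38": [1.0, 3.0],
            }
        )
        pooled = subject_profiles(table, masslist, method="pooled")
        assert pooled.loc[0, "full_length"] == pytest.approx(0.5)
        mean = subject_profiles(table, masslist, method="mean_of_plaques")
        assert mean.loc[0, "full_length"] == pytest.approx(0.5)
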