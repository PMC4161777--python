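"""Phenotype taxonomy, patient/cohort aggregation and comparison statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import ctcpheno as cp
from ctcpheno import cohort as ch

# ---------------------------------------------------------------------------
# independent oracles


def yates_chi2_oracle(table):
    """Direct evaluation of the continuity-corrected chi-square formula."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    stat = np.sum(np.maximum(np.abs(t - expected) - 0.5, 0.0) ** 2 / expected)
    return stat, sps.chi2.sf(stat, df=1)


def mann_whitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group labelings."""
    combined = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        xs = [combined[i] for i in idx_a]
        ys = [combined[i] for i in range(len(combined)) if i not in idx_a]
        return sum(1 for x in xs for y in ys if x > y) + 0.5 * sum(
            1 for x in xs for y in ys if x == y
        )

    u_obs = u_stat(tuple(range(n_a)))
    us = [u_stat(idx) for idx in itertools.combinations(range(len(combined)), n_a)]
    n_ab = n_a * (len(combined) - n_a)
    lo = min(u_obs, n_ab - u_obs)
    return sum(1 for u in us if u <= lo or u >= n_ab - lo) / len(us)


# ---------------------------------------------------------------------------


class TestAssignPhenotype:
    @pytest.mark.parametrize(
        "aldh1,twist,expected",
        [
            ("high", "nuc", "high_nuc"),
            ("neg", "nuc", "lowneg_nuc"),
            ("low", "neg", "lowneg_cytneg"),
            ("high", "cyt", "high_cytneg"),
            ("low", "cyt", "lowneg_cytneg"),
            ("neg", "neg", "lowneg_cytneg"),
        ],
    )
    def test_collapse_rules(self, aldh1, twist, expected):
        assert ch.assign_phenotype(aldh1, twist) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ch.assign_phenotype("medium", "nuc")
        with pytest.raises(ValueError):
            ch.assign_phenotype("high", "membrane")


class TestSummarizePatient:
    def test_counts_and_percentages_from_calls(self):
        calls = [("high", "nuc")] * 5 + [("high", "cyt")] * 14 + [("low", "neg")] * 2
        out = cp.summarize_patient(calls)
        assert list(out["counts"]) == [5, 14, 0, 2]
        assert out["percentages"] == (23.8, 66.7, 0.0, 9.5)

    def test_zero_ctcs_is_error(self):
        with pytest.raises(ValueError):
            cp.summarize_patient([])

    def test_percentages_sum_to_100_up_to_rounding(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.multinomial(rng.integers(1, 30), [0.4, 0.3, 0.2, 0.1])
            assert abs(sum(cp.phenotype_percentages(counts)) - 100.0) <= 0.2


def profiles(setting, detected_counts, n_negative=0):
    out = [
        ch.PatientProfile(f"{setting}-{i}", setting, np.array(c))
        for i, c in enumerate(detected_counts)
    ]
    out += [
        ch.PatientProfile(f"{setting}-neg{i}", setting, np.zeros(4, int))
        for i in range(n_negative)
    ]
    return out


class TestSummarizeCohort:
    def test_detection_rate_over_all_patients(self):
        profs = profiles("early", [(1, 0, 0, 0)] * 13, n_negative=67)
        summary = ch.summarize_cohort(profs)
        assert summary.detection_rate_pct == pytest.approx(16.25, abs=0.01)
        assert summary.n_detected == 13 and summary.n_patients == 80

    def test_homogeneous_cohort_is_fully_exclusive(self):
        profs = profiles("early", [(3, 0, 0, 0), (1, 0, 0, 0)])
        row = ch.summarize_cohort(profs).row("high_nuc")
        assert row["patients_with_any_pct"] == 100.0
        assert row["patients_exclusive_pct"] == 100.0
        assert row["ctc_level_pct"] == 100.0

    def test_exclusive_never_exceeds_with_any(self):
        rng = np.random.default_rng(1)
        counts = [rng.multinomial(rng.integers(1, 10), [0.4, 0.3, 0.2, 0.1]) for _ in range(20)]
        summary = ch.summarize_cohort(profiles("x", counts))
        for cat in ch.CATEGORIES:
            row = summary.row(cat)
            assert row["patients_exclusive_pct"] <= row["patients_with_any_pct"] + 1e-9

    def test_phenotype_ctc_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        counts = [rng.multinomial(rng.integers(1, 10), [0.4, 0.3, 0.2, 0.1]) for _ in range(15)]
        summary = ch.summarize_cohort(profiles("x", counts))
        total = sum(summary.row(ph)["ctc_level_pct"] for ph in ch.PHENOTYPES)
        assert total == pytest.approx(100.0, abs=0.2)

    def test_counts_conserved_to_pooled_level(self):
        rng = np.random.default_rng(3)
        counts = [rng.multinomial(rng.integers(1, 12), [0.3, 0.3, 0.2, 0.2]) for _ in range(12)]
        summary = ch.summarize_cohort(profiles("x", counts))
        assert summary.total_ctcs == int(np.sum(counts))


class TestChiSquareYates:
    def test_null_table_gives_zero_statistic(self):
        stat, p = cp.chi_square_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_agrees_with_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            t = rng.integers(0, 30, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            stat, p = cp.chi_square_yates(t)
            stat_o, p_o = yates_chi2_oracle(t)
            assert stat == pytest.approx(stat_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)
            checked += 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cp.chi_square_yates([[0, 0], [5, 10]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            cp.chi_square_yates([[1.5, 2], [3, 4]])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = cp.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.pvalue == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_small_samples_exact(self):
        res = cp.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_a, n_b = rng.integers(3, 7, size=2)
            a = rng.permutation(100)[:n_a].astype(float)  # tie-free
            b = rng.permutation(100)[50 : 50 + n_b].astype(float) + 0.5
            res = cp.mann_whitney(a, b)
            assert res.pvalue == pytest.approx(mann_whitney_exact_oracle(a, b), abs=1e-9)

    def test_asymptotic_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 8).round(3)
        b = rng.normal(0.5, 1, 8).round(3)
        exact = mann_whitney_exact_oracle(a, b)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.pvalue == pytest.approx(exact, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cp.mann_whitney([], [1, 2])


class TestSpearman:
    def test_concordant_binary_vectors(self):
        x = [1, 1, 0, 0, 1, 0]
        assert cp.spearman_rho(x, x).rho == pytest.approx(1.0)

    def test_anticoncordant_vectors(self):
        x = np.array([1, 1, 0, 0, 1, 0])
        assert cp.spearman_rho(x, 1 - x).rho == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(17)
        x = rng.integers(0, 2, 2000)
        y = rng.integers(0, 2, 2000)
        res = cp.spearman_rho(x, y)
        assert abs(res.rho) < 0.05 and res.pvalue > 0.01

    def test_constant_vector_flagged_undefined(self):
        res = cp.spearman_rho([1, 1, 1, 1], [0, 1, 0, 1])
        assert not res.defined and math.isnan(res.rho)


class TestCompareCohorts:
    def test_identical_cohorts_give_null_pvalues(self):
        counts = [(2, 1, 0, 0), (0, 0, 1, 2), (1, 1, 1, 1), (3, 0, 0, 0)]
        report = ch.compare_cohorts(
            profiles("early", counts), profiles("metastatic", counts)
        )
        assert (report["p_chi2_any"].dropna() > 0.99).all()
        assert (report["p_mannwhitney"] > 0.9).all()

    def test_distinct_phenotype_mixes_detected_in_majority_of_seeds(self):
        # power check: the generating mixes of the two clinical settings differ
        # strongly in the high/nuc phenotype at n = 13 vs 25 detected patients
        rejections = 0
        for seed in range(11):
            e = cp.generate_cohort_counts(
                "early", 13, 1.0, cp.simdata.EARLY_COHORT["phenotype_probs"],
                mean_ctc=31 / 13, seed=seed,
            )
            m = cp.generate_cohort_counts(
                "metastatic", 25, 1.0, cp.simdata.METASTATIC_COHORT["phenotype_probs"],
                mean_ctc=91 / 25, seed=1000 + seed,
            )
            report = ch.compare_cohorts(
                ch.profiles_from_counts_table(e), ch.profiles_from_counts_table(m)
            )
            rejections += report.loc["high_nuc", "p_chi2_any"] < 0.05
        assert rejections > 5

    def test_bh_correction_adds_adjusted_columns(self):
        counts = [(2, 1, 0, 0), (0, 0, 1, 2), (1, 1, 1, 1)]
        report = ch.compare_cohorts(
            profiles("early", counts), profiles("metastatic", counts), bh_correction=True
        )
        assert "p_chi2_any_bh" in report.columns
        ok = report["p_chi2_any_bh"].dropna()
        assert ((ok >= report["p_chi2_any"].dropna() - 1e-12) & (ok <= 1.0)).all()


class TestPerCtcIndicators:
    def test_joint_distribution_reconstructed_from_counts(self):
        profs = profiles("m", [(2, 1, 3, 4)])
        high, nuc = ch.per_ctc_indicators(profs)
        assert high.sum() == 3 and nuc.sum() == 5 and len(high) == 10
        assert int(np.sum(high & nuc)) == 2
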