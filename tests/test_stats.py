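"""Statistical battery: oracle agreement and association-report behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from atriamorph.stats import (
    AssociationConfig,
    benjamini_hochberg,
    chi_square,
    ks_normality,
    lva_association_analysis,
    pearson,
    spearman,
    t_test,
    validate_cohort_table,
    wilcoxon,
)
from atriamorph.synthetic import CohortDistribution, generate_cohort, truth_metrics_table


def brute_force_spearman(x, y):
    """Independent oracle: rank correlation + exact permutation p by full
    enumeration (direct formulas, no shared code path)."""

    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rx, ry = ranks(x), ranks(y)
    r_obs = corr(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(corr(rx, np.array(perm))) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, count / total


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_matches_brute_force_enumeration_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 6.0, 5.0, 4.0])
        r, p = spearman(x, y)
        r_bf, p_bf = brute_force_spearman(x, y)
        assert r == pytest.approx(r_bf, abs=1e-12)
        assert p == pytest.approx(p_bf, abs=1e-12)

    def test_large_sample_p_matches_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, p = spearman(x, y)
        ref_r, _ = sps.spearmanr(x, y)
        assert r == pytest.approx(float(ref_r), abs=1e-12)
        t = r * np.sqrt(28 / (1 - r * r))
        assert p == pytest.approx(float(2 * sps.t.sf(abs(t), 28)), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, _ = pearson(x, y)
        cx, cy = x - x.mean(), y - y.mean()
        manual = cx @ cy / np.sqrt((cx @ cx) * (cy @ cy))
        assert r == pytest.approx(manual, abs=1e-12)


class TestTTest:
    def test_identical_paired_samples(self):
        t, df, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert t == 0.0 and p == 1.0 and df == 2.0

    def test_pooled_variance_hand_computation(self):
        t, df, p = t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4.0
        assert p == pytest.approx(float(2 * sps.t.sf(3.674, 4)), abs=1e-4)

    def test_constant_nonzero_paired_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], paired=True)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])

    def test_welch_differs_from_pooled_under_variance_imbalance(self, rng):
        a = rng.normal(0, 5, 8)
        b = rng.normal(0, 0.5, 20)
        t_p, df_p, _ = t_test(a, b, equal_variance=True)
        t_w, df_w, _ = t_test(a, b, equal_variance=False)
        assert df_w < df_p


class TestWilcoxon:
    def test_identical_paired_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="signed_rank")

    def test_rank_sum_exact_enumeration(self):
        # fully separated groups of 3: two extreme assignments out of C(6,3)=20
        _, p = wilcoxon([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], mode="rank_sum")
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_signed_rank_matches_sign_pattern_enumeration(self):
        d = np.array([1.2, -0.7, 2.5, -3.1, 0.9, 1.7])
        stat, p = wilcoxon(d, mode="signed_rank")
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        dist = []
        for signs in itertools.product([0, 1], repeat=len(d)):
            dist.append(ranks[np.array(signs, bool)].sum())
        dist = np.array(dist)
        w_min = min(w_obs, ranks.sum() - w_obs)
        assert stat == pytest.approx(w_min, abs=1e-12)
        p_exact = min(1.0, 2.0 * np.mean(dist <= w_min))
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon([1.0, 2.0], [3.0, 4.0], mode="median")


class TestChiSquare:
    def test_perfect_independence(self):
        chi2, df, p = chi_square([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_perfect_association(self):
        chi2, df, p = chi_square([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0, abs=1e-12)
        assert df == 1.0

    def test_matches_observed_expected_loop(self, rng):
        table = rng.integers(1, 30, (2, 3)).astype(float)
        chi2, df, _ = chi_square(table)
        total = table.sum()
        manual = 0.0
        for i in range(2):
            for j in range(3):
                e = table[i].sum() * table[:, j].sum() / total
                manual += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(manual, abs=1e-12)
        assert df == 2.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 3]])


class TestHelpers:
    def test_ks_normality_flags_uniform_tail(self, rng):
        stat_n, p_n = ks_normality(rng.normal(size=500))
        stat_u, p_u = ks_normality(rng.uniform(size=500))
        assert p_n > p_u

    def test_benjamini_hochberg_small_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.20])
        adj = benjamini_hochberg(p)
        # ordered p: .01 .03 .04 .20 -> raw m*p/i: .04 .06 .0533 .20 ->
        # monotone from the back: .04 .0533 .0533 .20
        assert adj == pytest.approx([0.04, 0.0533333333, 0.0533333333, 0.2])


@pytest.fixture(scope="module")
def cohort_table():
    return truth_metrics_table(
        generate_cohort(40, CohortDistribution(), seed=21, meshes=False)
    )


class TestAssociationReport:
    def test_schema_validation_errors(self, cohort_table):
        bad = cohort_table.drop(columns=["LAS"])
        with pytest.raises(ValueError, match="missing columns"):
            validate_cohort_table(bad)
        dup = pd.concat([cohort_table, cohort_table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            validate_cohort_table(dup)
        wrong = cohort_table.copy()
        wrong.loc[0, "lva_segment_count"] = 99
        with pytest.raises(ValueError, match="label sum"):
            validate_cohort_table(wrong)

    def test_report_families_and_flags(self, cohort_table):
        report = lva_association_analysis(cohort_table)
        assert len(report.count_correlations) == 9  # 6 D + LAV, ASI, LAS
        assert len(report.pairwise_correlations) == 15 + 18  # C(6,2) + 6*3
        assert len(report.group_contrasts) == 6
        assert report.count_correlations["significant"].dtype == bool

    def test_row_permutation_invariance(self, cohort_table, rng):
        report0 = lva_association_analysis(cohort_table)
        shuffled = cohort_table.sample(frac=1.0, random_state=7)
        report1 = lva_association_analysis(shuffled)
        pd.testing.assert_frame_equal(
            report0.count_correlations, report1.count_correlations
        )
        pd.testing.assert_frame_equal(
            report0.group_contrasts, report1.group_contrasts
        )

    def test_constant_count_reported_not_computable(self, cohort_table):
        frozen = cohort_table.copy()
        for s in ("roof", "posterior", "septum", "inferior_septum",
                  "inferior_posterior", "lateral"):
            frozen[f"lva_{s}"] = 1
        frozen["lva_segment_count"] = 6
        report = lva_association_analysis(frozen)
        assert not report.count_correlations["computable"].any()

    def test_small_group_contrast_not_an_exception(self, cohort_table):
        # nobody with extended (all-six) low voltage
        table = cohort_table[cohort_table["lva_segment_count"] < 6].copy()
        report = lva_association_analysis(table)
        assert (~report.group_contrasts["computable"]).all() or (
            report.group_contrasts["n_extended"] == 0
        ).all()

    def test_bh_flag_adds_adjusted_column(self, cohort_table):
        report = lva_association_analysis(
            cohort_table, AssociationConfig(bh_correction=True)
        )
        assert "p_adjusted" in report.count_correlations.columns
        ok = report.count_correlations.dropna(subset=["p", "p_adjusted"])
        assert (ok["p_adjusted"] >= ok["p"] - 1e-15).all()

    def test_serialisation_and_plot(self, cohort_table, tmp_path):
        report = lva_association_analysis(cohort_table)
        report.to_json(tmp_path / "report.json")
        report.to_csv(tmp_path / "report.csv")
        assert (tmp_path / "report.json").stat().st_size > 0
        flat = pd.read_csv(tmp_path / "report.csv")
        assert set(flat["family"]) == {
            "count_correlation", "pairwise_correlation", "group_contrast"
        }
        fig = report.plot_deviation_by_count(tmp_path / "fig.png")
        assert (tmp_path / "fig.png").exists()
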