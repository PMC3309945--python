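import math
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pubmed_expand import evaluation as ev
from pubmed_expand.fixtures import FixtureConfig, expected_kappa, gen_judgments
from pubmed_expand.terminology import DescriptorFeatures

CATS = ev.CATEGORIES


def matrix_from_rows(rows, raters=None):
    raters = raters or [f"r{i + 1}" for i in range(len(rows[0]))]
    return ev.JudgmentMatrix(pd.DataFrame(rows, columns=raters))


def random_matrix(rng, n=10, m=4):
    return matrix_from_rows([[CATS[rng.integers(0, 3)] for _ in range(m)] for _ in range(n)])


def brute_force_fleiss(rows):
    """Direct transcription of the published multi-rater kappa formula."""
    n = len(rows)
    m = len(rows[0])
    nij = [[row.count(cat) for cat in CATS] for row in rows]
    p_bar = sum(
        sum(c * (c - 1) for c in row_counts) / (m * (m - 1)) for row_counts in nij
    ) / n
    p_j = [sum(row_counts[j] for row_counts in nij) / (n * m) for j in range(len(CATS))]
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


class TestJudgmentMatrix:
    def test_requires_two_raters(self):
        with pytest.raises(ValueError, match="2 raters"):
            ev.JudgmentMatrix(pd.DataFrame({"r1": ["bad", "full"]}))

    def test_rejects_unknown_category(self):
        with pytest.raises(ValueError, match="outside"):
            matrix_from_rows([["bad", "excellent"]])

    def test_rejects_empty_row(self):
        frame = pd.DataFrame({"r1": ["bad", np.nan], "r2": ["full", np.nan]})
        with pytest.raises(ValueError, match="at least one rating"):
            ev.JudgmentMatrix(frame)

    def test_from_judgments_csv(self):
        csv = (
            "term,rank,pmid,rater,rating\n"
            "asthma,1,10,r1,full\n"
            "asthma,1,10,r2,partial\n"
            "asthma,2,11,r1,bad\n"
            "asthma,2,11,r2,bad\n"
        )
        matrix = ev.JudgmentMatrix.from_judgments(StringIO(csv))
        assert matrix.n_rows == 2
        assert matrix.raters == ["r1", "r2"]
        assert matrix.ratings("r1") == ["full", "bad"]

    def test_missing_flagged(self):
        frame = pd.DataFrame({"r1": ["bad", "full"], "r2": ["full", np.nan]})
        matrix = ev.JudgmentMatrix(frame)
        assert matrix.has_missing
        assert len(matrix.complete_rows()) == 1


class TestPrecision:
    def test_all_full_degenerate_wald(self):
        matrix = matrix_from_rows([["full", "full"]] * 20)
        est = ev.precision(matrix, "r1", "full")
        assert (est.p, est.ci_low, est.ci_high) == (1.0, 1.0, 1.0)

    def test_hand_computed_wald(self):
        rows = [["full", "bad"]] * 12 + [["partial", "bad"]] * 3 + [["bad", "bad"]] * 5
        matrix = matrix_from_rows(rows)
        est = ev.precision(matrix, "r1", "partial_or_full")
        assert est.p == 0.75
        assert est.ci_low == pytest.approx(0.560, abs=5e-4)
        assert est.ci_high == pytest.approx(0.940, abs=5e-4)

    def test_zero_hits(self):
        matrix = matrix_from_rows([["bad", "bad"]] * 20)
        est = ev.precision(matrix, "r1", "full")
        assert (est.p, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_pooled_over_all_raters(self):
        matrix = matrix_from_rows([["full", "bad"]] * 10)
        est = ev.precision(matrix, None, "full")
        assert est.n == 20
        assert est.p == 0.5

    def test_missing_kept_per_rater(self):
        frame = pd.DataFrame({"r1": ["full", "full", np.nan], "r2": ["bad", "bad", "bad"]})
        est = ev.precision(ev.JudgmentMatrix(frame), "r1", "full")
        assert est.n == 2 and est.p == 1.0

    def test_monotone_in_level(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            matrix = random_matrix(rng)
            for rater in matrix.raters:
                full = ev.precision(matrix, rater, "full")
                both = ev.precision(matrix, rater, "partial_or_full")
                assert both.p >= full.p

    def test_wilson_option_brackets_p(self):
        matrix = matrix_from_rows([["full", "bad"]] * 10 + [["bad", "bad"]] * 10)
        est = ev.precision(matrix, "r1", "full", ci="wilson")
        assert est.ci_low < est.p < est.ci_high

    def test_ci_width_shrinks_like_inverse_sqrt_n(self):
        rows_small = [["full", "bad"]] * 5 + [["bad", "bad"]] * 5
        rows_big = rows_small * 100
        w_small = ev.precision(matrix_from_rows(rows_small), "r1", "full")
        w_big = ev.precision(matrix_from_rows(rows_big), "r1", "full")
        ratio = (w_small.ci_high - w_small.ci_low) / (w_big.ci_high - w_big.ci_low)
        assert ratio == pytest.approx(10.0, rel=1e-9)

    def test_bad_level(self):
        matrix = matrix_from_rows([["full", "bad"]])
        with pytest.raises(ValueError, match="level"):
            ev.precision(matrix, "r1", "bad")


class TestFleissKappa:
    def test_unanimity_gives_one(self):
        matrix = matrix_from_rows([["full"] * 4, ["bad"] * 4, ["partial"] * 4] * 3)
        assert ev.fleiss_kappa(matrix).kappa == pytest.approx(1.0)

    def test_single_category_defined_as_one_with_warning(self):
        matrix = matrix_from_rows([["full"] * 4] * 5)
        with pytest.warns(UserWarning, match="single category"):
            assert ev.fleiss_kappa(matrix).kappa == 1.0

    def test_chance_agreement_gives_zero(self):
        rows = [["bad", "bad"], ["bad", "full"], ["full", "bad"], ["full", "full"]]
        assert ev.fleiss_kappa(matrix_from_rows(rows)).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            matrix = random_matrix(rng)
            rows = matrix.frame.to_numpy().tolist()
            assert ev.fleiss_kappa(matrix).kappa == pytest.approx(
                brute_force_fleiss(rows), abs=1e-12
            )

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(6)
        matrix = random_matrix(rng, n=30)
        coded = matrix.frame.apply(lambda col: col.map({c: i for i, c in enumerate(CATS)}))
        table, _ = aggregate_raters(coded)
        assert ev.fleiss_kappa(matrix).kappa == pytest.approx(float(sm_fleiss(table)), abs=1e-12)

    def test_invariant_under_relabeling_and_rater_permutation(self):
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng)
        base = ev.fleiss_kappa(matrix).kappa
        relabeled = ev.JudgmentMatrix(
            matrix.frame.replace({"bad": "full", "full": "bad"})
        )
        permuted = ev.JudgmentMatrix(matrix.frame[["r3", "r1", "r4", "r2"]])
        assert ev.fleiss_kappa(relabeled).kappa == pytest.approx(base, abs=1e-12)
        assert ev.fleiss_kappa(permuted).kappa == pytest.approx(base, abs=1e-12)

    def test_incomplete_rows_dropped_and_counted(self):
        frame = pd.DataFrame(
            {"r1": ["bad", "full", "bad"], "r2": ["bad", np.nan, "full"], "r3": ["bad", "full", "full"]}
        )
        result = ev.fleiss_kappa(ev.JudgmentMatrix(frame))
        assert result.n_dropped_rows == 1
        assert result.n_subjects == 2

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="2 complete rows"):
            ev.fleiss_kappa(matrix_from_rows([["bad", "full"]]))

    def test_recovers_generative_agreement(self):
        config = FixtureConfig(seed=42, rater_agreement=0.8, n_judgment_rows=500)
        matrix = ev.JudgmentMatrix.from_judgments(StringIO(gen_judgments(config)))
        estimated = ev.fleiss_kappa(matrix).kappa
        assert estimated == pytest.approx(expected_kappa(0.8, config.latent_dist), abs=0.05)


class TestSpearman:
    def make_features(self, xs):
        return [DescriptorFeatures(f"D{i}", int(x), int(x), int(x)) for i, x in enumerate(xs)]

    def test_strictly_increasing_gives_one(self):
        features = self.make_features(range(10))
        out = ev.spearman_assoc(features, [float(i * i) for i in range(10)])
        assert out["n_sons"].statistic == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        xs = rng.integers(0, 15, size=20)
        ys = rng.permutation(20).astype(float)
        features = self.make_features(xs)
        rho = ev.spearman_assoc(features, list(ys))["n_sons"].statistic
        oracle = stats.pearsonr(stats.rankdata(xs), stats.rankdata(ys)).statistic
        assert rho == pytest.approx(float(oracle), abs=1e-12)
        assert abs(rho) < 0.6  # independent permutation: weak association

    def test_constant_factor_flagged(self):
        features = self.make_features([3] * 5)
        result = ev.spearman_assoc(features, [1.0, 2.0, 3.0, 4.0, 5.0])["n_sons"]
        assert math.isnan(result.statistic)
        assert result.warning is not None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.spearman_assoc(self.make_features([1, 2, 3]), [1.0, 2.0])


class TestCompareRaters:
    def test_identical_columns_statistic_zero(self):
        matrix = matrix_from_rows([["bad"] * 4, ["full"] * 4, ["partial"] * 4])
        result = ev.compare_raters(matrix)
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_hand_computed_three_by_three(self):
        rows = [
            ["bad", "partial", "full"],
            ["partial", "full", "bad"],
            ["bad", "full", "partial"],
        ]
        result = ev.compare_raters(matrix_from_rows(rows))
        # rank sums (4, 8, 6): chi2 = 12/(3*3*4) * (16+64+36) - 3*3*4 = 8/3
        assert result.statistic == pytest.approx(8.0 / 3.0, abs=1e-12)
        assert result.df == 2
        assert result.p_value == pytest.approx(float(stats.chi2.sf(8.0 / 3.0, 2)), abs=1e-12)

    def test_tie_free_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        scores = np.array([rng.permutation(3) for _ in range(12)])
        rows = [[CATS[v] for v in row] for row in scores]
        ours = ev.compare_raters(matrix_from_rows(rows))
        reference = stats.friedmanchisquare(*scores.T)
        assert ours.statistic == pytest.approx(float(reference.statistic), abs=1e-10)
        assert ours.p_value == pytest.approx(float(reference.pvalue), abs=1e-10)

    def test_biased_rater_detected(self):
        rng = np.random.default_rng(10)
        rows = []
        for _ in range(20):
            base = int(rng.integers(0, 2))  # bad or partial
            rows.append([CATS[base], CATS[base], CATS[base], CATS[base + 1]])
        result = ev.compare_raters(matrix_from_rows(rows))
        assert result.p_value < 0.05

    def test_biased_rater_matches_permutation_oracle(self):
        def fast_statistic(scores):
            ranks = stats.rankdata(scores, axis=1)
            n, k = scores.shape
            col = ranks.sum(axis=0)
            a = float((ranks**2).sum())
            c = n * k * (k + 1) ** 2 / 4.0
            if a - c < 1e-12:
                return 0.0
            return (k - 1) * float(((col - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)

        rng = np.random.default_rng(12)
        rows = []
        for _ in range(20):
            base = int(rng.integers(0, 2))
            rows.append([CATS[base], CATS[base], CATS[base], CATS[base + 1]])
        matrix = matrix_from_rows(rows)
        observed = ev.compare_raters(matrix)
        scores = np.array([[{"bad": 0, "partial": 1, "full": 2}[c] for c in r] for r in rows])
        assert fast_statistic(scores) == pytest.approx(observed.statistic, abs=1e-10)

        hits = 0
        n_shuffles = 10_000
        for _ in range(n_shuffles):
            if fast_statistic(rng.permuted(scores, axis=1)) >= observed.statistic - 1e-12:
                hits += 1
        perm_p = hits / n_shuffles
        # permutation p and the chi-square approximation agree on significance
        assert perm_p < 0.05
        assert observed.p_value < 0.05


class TestCompareTerms:
    def test_identical_columns(self):
        result = ev.compare_terms([[10, 10], [90, 90]])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_random_table_matches_formula_oracle(self):
        rng = np.random.default_rng(13)
        obs = rng.integers(5, 60, size=(2, 20)).astype(float)
        result = ev.compare_terms(obs)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        oracle = float(((obs - expected) ** 2 / expected).sum())
        assert result.statistic == pytest.approx(oracle, abs=1e-10)
        assert result.df == 19

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            ev.compare_terms([[0, 5], [0, 5]])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ev.compare_terms([[1, -1], [2, 3]])

    def test_small_expected_warns(self):
        result = ev.compare_terms([[1, 2], [3, 4]])
        assert result.warning is not None
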