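import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, mannwhitneyu
from scipy.stats import multivariate_hypergeom

from commflux import stats


def bh_bruteforce(p):
    """Step-up definition: q_i = min over j>=i of min(1, m*p_(j)/j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBenjaminiHochberg:
    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(
                stats.benjamini_hochberg(p), bh_bruteforce(p), atol=1e-12
            )

    def test_hand_computed_example(self):
        q = stats.benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_properties_hold_for_arbitrary_p_vectors(self, p):
        q = stats.benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-12)  # q never below p
        assert np.all((0 <= q) & (q <= 1))
        # monotone: ordering of q follows ordering of p
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.allclose(q, bh_bruteforce(p), atol=1e-12)


class TestWilcoxonScreen:
    @staticmethod
    def _data(x, y):
        features = pd.DataFrame({"f": list(x) + list(y)})
        groups = pd.Series(["a"] * len(x) + ["b"] * len(y))
        return features, groups

    def test_completely_separated_exact_p(self):
        # 5 vs 5 with full separation: 2 / C(10,5) = 2/252
        features, groups = self._data([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        out = stats.wilcoxon_fdr_screen(features, groups, ("a", "b"))
        assert out["p_value"].iloc[0] == pytest.approx(2 / 252)

    def test_all_tied_feature_emitted_with_p_one(self):
        features, groups = self._data([2, 2, 2, 2], [2, 2, 2, 2])
        out = stats.wilcoxon_fdr_screen(features, groups, ("a", "b"))
        assert len(out) == 1
        assert out["p_value"].iloc[0] == 1.0

    def test_needs_three_per_group(self):
        features, groups = self._data([1, 2], [3, 4, 5])
        with pytest.raises(ValueError):
            stats.wilcoxon_fdr_screen(features, groups, ("a", "b"))

    def test_null_false_discovery_proportion(self):
        """All-null screen keeps the realised FDP near or below alpha."""
        rng = np.random.default_rng(123)
        fdp = []
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(16, 200)))
            groups = pd.Series(["a"] * 8 + ["b"] * 8)
            out = stats.wilcoxon_fdr_screen(X, groups, ("a", "b"))
            fdp.append(out["significant"].mean())
        assert np.mean(fdp) <= 0.05 + 2.33 * np.sqrt(0.05 * 0.95 / 10)


class TestFisherScreen:
    def test_extreme_table_exact_p(self):
        # [[10,0],[0,10]] -> 2 / C(20,10)
        binary = pd.DataFrame({"f": [True] * 10 + [False] * 10})
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        out, _ = stats.fisher_secretion_screen(binary, groups)
        assert out["p_value"].iloc[0] == pytest.approx(2 / 184756)

    def test_balanced_table_p_one(self):
        binary = pd.DataFrame({"f": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5})
        groups = pd.Series(["a"] * 10 + ["b"] * 10)
        out, _ = stats.fisher_secretion_screen(binary, groups)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_coupled_duplicates_tested_once(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 2, 12).astype(bool)
        binary = pd.DataFrame({"f1": col, "f2": col, "f3": ~col})
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        out, _ = stats.fisher_secretion_screen(binary, groups)
        assert len(out) == 2  # f1/f2 coupled; f3 is its complement pattern

    def test_constant_features_skipped(self):
        binary = pd.DataFrame(
            {"always": [True] * 8, "varies": [True] * 4 + [False] * 4}
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        out, skipped = stats.fisher_secretion_screen(binary, groups)
        assert skipped == ["always"]
        assert list(out["feature_id"]) == ["varies"]

    def test_freeman_halton_reduces_to_fisher_for_2x2(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(2)
        for _ in range(20):
            table = rng.integers(0, 8, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum() == 0:
                continue
            assert stats.freeman_halton(table) == pytest.approx(
                fisher_exact(table)[1], abs=1e-10
            )

    def test_freeman_halton_2x3_matches_enumeration(self):
        """Independent oracle: enumerate all 2x3 tables with the observed
        margins and sum multivariate-hypergeometric masses."""
        tables = [
            np.array([[3, 0, 1], [0, 4, 2]]),
            np.array([[2, 2, 2], [2, 2, 2]]),
            np.array([[5, 1, 0], [1, 3, 4]]),
        ]
        for table in tables:
            col = table.sum(axis=0)
            r1 = table[0].sum()
            p_obs = multivariate_hypergeom.pmf(table[0], col, r1)
            total = 0.0
            for a in range(min(col[0], r1) + 1):
                for b in range(min(col[1], r1 - a) + 1):
                    c = r1 - a - b
                    if c < 0 or c > col[2]:
                        continue
                    p = multivariate_hypergeom.pmf([a, b, c], col, r1)
                    if p <= p_obs * (1 + 1e-9):
                        total += p
            assert stats.freeman_halton(table) == pytest.approx(total, abs=1e-10)


class TestRegression:
    @staticmethod
    def _simulate(seed, b_group=0.0, n=100):
        rng = np.random.default_rng(seed)
        n_strains = rng.integers(3, 60, size=n).astype(float)
        group = rng.integers(0, 2, size=n)
        count = 10 + 8 * np.log(n_strains) + b_group * group + rng.normal(size=n)
        return (
            pd.Series(count),
            pd.Series(n_strains),
            pd.Series(np.where(group == 1, "g1", "g0")),
        )

    def test_log_form_recovered(self):
        hits = 0
        for seed in range(10):
            counts, ns, groups = self._simulate(seed)
            res = stats.secreted_count_regression(counts, ns, groups, "g1", "g0")
            hits += res.chosen_power == 0.0
        assert hits >= 9

    def test_group_effect_coverage(self):
        covered = 0
        for seed in range(20):
            counts, ns, groups = self._simulate(seed, b_group=-5.0)
            res = stats.secreted_count_regression(counts, ns, groups, "g1", "g0")
            covered += res.ci[0] <= -5.0 <= res.ci[1]
        assert covered >= 18

    def test_null_group_effect_p_uniform(self):
        ps = []
        for seed in range(50):
            counts, ns, groups = self._simulate(seed + 100, b_group=0.0)
            res = stats.secreted_count_regression(counts, ns, groups, "g1", "g0")
            ps.append(res.p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_ci_contains_point_and_deviance_ordering(self):
        counts, ns, groups = self._simulate(3)
        res = stats.secreted_count_regression(counts, ns, groups, "g1", "g0")
        assert res.ci[0] <= res.b <= res.ci[1]
        assert res.deviances[res.chosen_power] <= res.deviances[1.0]

    def test_singular_design_names_column(self):
        counts = pd.Series(np.arange(12.0))
        ns = pd.Series(np.full(12, 4.0))  # constant regressor -> collinear
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        with pytest.raises(ValueError, match="collinear"):
            stats.secreted_count_regression(counts, ns, groups)


class TestAUC:
    def test_perfect_separation(self):
        score = pd.Series([1, 2, 3, 10, 11, 12], dtype=float)
        labels = pd.Series(["neg"] * 3 + ["pos"] * 3)
        assert stats.classify_auc(score, labels).auc == 1.0

    def test_equals_mann_whitney_u(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n1, n2 = rng.integers(5, 15, 2)
            score = pd.Series(rng.normal(size=n1 + n2))
            labels = pd.Series(["a"] * n1 + ["b"] * n2)
            res = stats.classify_auc(score, labels)
            u = mannwhitneyu(
                score[labels == "b"], score[labels == "a"],
                alternative="two-sided",
            ).statistic
            assert res.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(5)
        aucs = [
            stats.classify_auc(
                pd.Series(rng.normal(size=40)),
                pd.Series(rng.permutation(["a"] * 20 + ["b"] * 20)),
            ).auc
            for _ in range(30)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            stats.classify_auc(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


class TestMediation:
    @staticmethod
    def _simulate(seed, kind, n=200):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        flip = rng.random(n) < 0.2
        if kind == "null":
            m = rng.integers(0, 2, n).astype(float)
            y = 2.0 * x + rng.normal(size=n)
        else:
            m = np.where(flip, 1 - x, x)
            if kind == "full":
                y = 3.0 * m + rng.normal(size=n)
            else:  # half: direct effect chosen equal to indirect (0.6*1.5)
                y = 1.5 * m + 0.9 * x + rng.normal(size=n)
        return pd.Series(y), pd.Series(x), pd.Series(m)

    def test_total_is_direct_plus_indirect(self):
        y, x, m = self._simulate(0, "half")
        res = stats.mediation_analysis(y, x, m, n_boot=50, seed=1)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-10)

    def test_full_mediation_recovered(self):
        y, x, m = self._simulate(1, "full")
        res = stats.mediation_analysis(y, x, m, n_boot=500, seed=2)
        assert res.proportion_mediated == pytest.approx(1.0, abs=0.15)
        assert res.ci[0] > 0  # indirect CI excludes zero

    def test_null_mediation(self):
        y, x, m = self._simulate(2, "null")
        res = stats.mediation_analysis(y, x, m, n_boot=500, seed=3)
        assert abs(res.proportion_mediated) < 0.2
        assert res.ci[0] <= 0 <= res.ci[1]

    def test_deterministic_given_seed(self):
        y, x, m = self._simulate(3, "half")
        a = stats.mediation_analysis(y, x, m, n_boot=100, seed=9)
        b = stats.mediation_analysis(y, x, m, n_boot=100, seed=9)
        assert a.ci == b.ci and a.proportion_ci == b.proportion_ci

    def test_constant_mediator_raises(self):
        y, x, _ = self._simulate(4, "full")
        with pytest.raises(ValueError, match="mediator"):
            stats.mediation_analysis(y, x, pd.Series(np.ones(len(y))))


class TestRandomForest:
    @staticmethod
    def _data(seed, signal=True, n=60):
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.permutation(["a"] * (n // 2) + ["b"] * (n // 2)))
        X = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=[f"noise{i}" for i in range(6)]
        )
        if signal:
            X["marker"] = np.where(y == "a", 0.0, 5.0) + rng.normal(
                scale=0.1, size=n
            )
        return X, y

    def test_discriminative_feature_ranks_first(self):
        X, y = self._data(0)
        res = stats.rf_stratify(X, y, n_trees=400, seed=1)
        assert res.feature_ranking.index[0] == "marker"
        assert res.oob_error < 0.1

    def test_permuted_labels_oob_near_chance(self):
        X, y = self._data(1, signal=False)
        res = stats.rf_stratify(X, y, n_trees=400, seed=2)
        assert res.oob_error > 0.25

    def test_deterministic_given_seed(self):
        X, y = self._data(2)
        a = stats.rf_stratify(X, y, n_trees=300, seed=5)
        b = stats.rf_stratify(X, y, n_trees=300, seed=5)
        assert a.oob_error == b.oob_error
        assert (a.feature_ranking == b.feature_ranking).all()

    def test_low_tree_count_warns(self):
        X, y = self._data(3)
        with pytest.warns(UserWarning, match="low"):
            stats.rf_stratify(X, y, n_trees=50, seed=1)


class TestDirectionAgreement:
    def test_identical_tables_full_agreement(self):
        d = pd.Series(["up"] * 5 + ["down"] * 5, index=[f"m{i}" for i in range(10)])
        res = stats.direction_agreement(d, d)
        assert res.percent_agreement == 100.0
        assert res.n_agree == 10

    def test_reversed_tables_zero_agreement(self):
        idx = [f"m{i}" for i in range(8)]
        d = pd.Series(["up"] * 4 + ["down"] * 4, index=idx)
        r = pd.Series(["down"] * 4 + ["up"] * 4, index=idx)
        res = stats.direction_agreement(d, r)
        assert res.percent_agreement == 0.0

    def test_nonsignificant_excluded_from_overlap(self):
        idx = list("abcd")
        d = pd.Series(["up", "down", "nonsignificant", "up"], index=idx)
        r = pd.Series(["up", "up", "down", "nonsignificant"], index=idx)
        res = stats.direction_agreement(d, r)
        assert res.n_agree + res.n_disagree == 2

    def test_noisy_reference_agreement_expectation(self):
        from commflux.synthetic_data import generate_metabolomic_reference

        idx = [f"m{i}" for i in range(23)]
        truth = pd.Series(["up", "down"] * 11 + ["up"], index=idx)
        pcts = []
        for seed in range(200):
            ref = generate_metabolomic_reference(
                idx, list(truth.values), noise_rate=0.3, seed=seed
            )
            pcts.append(stats.direction_agreement(truth, ref).percent_agreement)
        assert np.mean(pcts) == pytest.approx(70.0, abs=2.0)

    def test_empty_overlap_raises(self):
        d = pd.Series(["nonsignificant"], index=["m"])
        with pytest.raises(ValueError):
            stats.direction_agreement(d, d)
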