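"""Selection chain and ROC metrics against exact/enumeration oracles."""

import itertools

import numpy as np
import pytest

import perifuse as pf
from perifuse.errors import ParameterError
from perifuse.metrics import delong_variance, evaluate_at_threshold
from perifuse.selection import ChainParams, FeatureMatrix


def fm(values, labels, tags=None, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureMatrix(
        values=values,
        case_ids=[f"c{i}" for i in range(n)],
        labels=np.asarray(labels, dtype=int),
        feature_names=names or [f"f{j}" for j in range(p)],
        region_tags=tags or ["all"] * p,
    )


class TestPca:
    def test_reduces_to_32_components(self):
        rng = np.random.default_rng(0)
        train = fm(rng.random((200, 500)), rng.integers(0, 2, 200))
        out, _, _ = pf.pca_reduce(train, None, n_components=32)
        assert out.n_features == 32

    def test_training_mean_projects_to_zero(self):
        rng = np.random.default_rng(1)
        train = fm(rng.random((30, 10)), rng.integers(0, 2, 30))
        _, _, transform = pf.pca_reduce(train, None, n_components=5)
        projected = transform.transform(train.values.mean(axis=0, keepdims=True))
        assert np.allclose(projected, 0.0, atol=1e-10)

    def test_rank_two_matrix_explains_everything_in_two_components(self):
        rng = np.random.default_rng(2)
        basis = rng.random((2, 40))
        coeffs = rng.random((25, 2))
        train = fm(coeffs @ basis, rng.integers(0, 2, 25))
        _, _, transform = pf.pca_reduce(train, None, n_components=10)
        assert transform.explained_variance_ratio_[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_are_orthonormal(self):
        rng = np.random.default_rng(3)
        train = fm(rng.random((40, 20)), rng.integers(0, 2, 40))
        _, _, transform = pf.pca_reduce(train, None, n_components=8)
        gram = transform.components_ @ transform.components_.T
        assert np.allclose(gram, np.eye(8), atol=1e-10)

    def test_feature_count_mismatch_raises(self):
        rng = np.random.default_rng(4)
        train = fm(rng.random((20, 10)), rng.integers(0, 2, 20))
        other = fm(rng.random((5, 7)), rng.integers(0, 2, 5))
        with pytest.raises(ParameterError, match="features"):
            pf.pca_reduce(train, other)


def exact_mwu_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    observed = u_stat(range(n))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n)]
    mean_u = len(x) * len(y) / 2.0
    extreme = sum(abs(u - mean_u) >= abs(observed - mean_u) - 1e-12 for u in us)
    return extreme / len(us)


class TestMwuFilter:
    def test_exact_p_for_disjoint_triples_is_0_1(self):
        """{1,2,3} vs {4,5,6}: 2/20 assignments are as extreme -> p = 0.1,
        which the filter must reproduce and drop at alpha 0.05."""
        assert exact_mwu_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        matrix = fm(np.array([[1, 2, 3, 4, 5, 6]]).T, [0, 0, 0, 1, 1, 1])
        filtered, p_values = pf.mwu_filter(matrix, alpha=0.05)
        assert p_values[0] == pytest.approx(0.1)
        assert filtered.n_features == 0

    def test_constant_feature_dropped_with_p_one(self):
        matrix = fm(np.ones((10, 1)), [0] * 5 + [1] * 5)
        filtered, p_values = pf.mwu_filter(matrix)
        assert p_values[0] == 1.0 and filtered.n_features == 0

    def test_perfectly_separated_feature_retained(self):
        values = np.concatenate([np.arange(20), np.arange(100, 120)])[:, None]
        filtered, p_values = pf.mwu_filter(fm(values, [0] * 20 + [1] * 20))
        assert p_values[0] < 1e-6 and filtered.n_features == 1

    def test_single_class_raises(self):
        with pytest.raises(ParameterError, match="both classes"):
            pf.mwu_filter(fm(np.random.default_rng(0).random((6, 2)), [1] * 6))


class TestPearsonPrune:
    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        col = rng.random(20)
        matrix = fm(np.column_stack([col, 2 * col]), rng.integers(0, 2, 20))
        pruned = pf.pearson_prune(matrix, p_values=[0.04, 0.01])
        assert pruned.feature_names == ["f1"]

    def test_independent_columns_all_survive(self):
        rng = np.random.default_rng(1)
        matrix = fm(rng.random((200, 6)), rng.integers(0, 2, 200))
        pruned = pf.pearson_prune(matrix, p_values=np.arange(6) / 10)
        assert pruned.n_features == 6

    def test_correlation_chain_matches_greedy_oracle(self):
        """5-feature chain with engineered correlations: replay the greedy
        visit order by hand and compare the surviving sets."""
        rng = np.random.default_rng(2)
        z = rng.standard_normal(400)
        cols = np.column_stack([
            z,
            z + 0.1 * rng.standard_normal(400),     # r ~ 0.995 with col0
            z + 2.0 * rng.standard_normal(400),     # moderate r
            rng.standard_normal(400),
            -z + 0.1 * rng.standard_normal(400),    # strong negative r with col0
        ])
        p_values = np.array([0.01, 0.02, 0.03, 0.04, 0.005])
        matrix = fm(cols, rng.integers(0, 2, 400))
        pruned = pf.pearson_prune(matrix, p_values, r_threshold=0.9)

        corr = np.corrcoef(cols.T)
        kept = []
        for j in np.argsort(p_values, kind="stable"):
            if all(abs(corr[j, k]) < 0.9 for k in kept):
                kept.append(j)
        assert pruned.feature_names == [f"f{j}" for j in sorted(kept)]
        surv = [matrix.feature_names.index(n) for n in pruned.feature_names]
        for a in surv:
            for b in surv:
                if a != b:
                    assert abs(corr[a, b]) < 0.9


class TestLassoSelect:
    def test_sparsity_and_subset_contract(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100, 10))
        y = (x[:, 0] + 0.2 * rng.standard_normal(100) > 0).astype(int)
        selected, report = pf.lasso_select(fm(x, y), folds=10, seed=0)
        assert set(selected.feature_names) <= {f"f{j}" for j in range(10)}
        assert report.n_after_lasso == selected.n_features <= 10
        assert report.chosen_penalty in report.penalty_path

    def test_informative_feature_recovered_across_seeds(self):
        """One feature shifted by 2 SD among 19 noise features, n=200:
        LASSO keeps it in at least 9 of 10 seeded runs."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            y = np.repeat([0, 1], 100)
            x = rng.standard_normal((200, 20))
            x[:, 7] += 2.0 * y
            selected, _ = pf.lasso_select(fm(x, y), folds=10, seed=seed)
            hits += "f7" in selected.feature_names
        assert hits >= 9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((60, 8))
        y = rng.integers(0, 2, 60)
        a = pf.lasso_select(fm(x, y), folds=5, seed=11)
        b = pf.lasso_select(fm(x, y), folds=5, seed=11)
        assert a[1] == b[1]
        assert np.array_equal(a[0].values, b[0].values)

    def test_too_few_cases_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ParameterError, match="fold"):
            pf.lasso_select(fm(rng.random((8, 3)), [0, 1] * 4), folds=10)


def brute_force_auc(labels, scores):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return total / (len(pos) * len(neg))


class TestAucAndEvaluation:
    def test_auc_enumerated_example(self):
        # 4 positive-negative pairs, 3 concordant, 0 tied -> 0.75
        assert pf.auc_score([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_perfect_separation_gives_auc_one(self):
        assert pf.auc_score([0, 0, 1, 1], [0.1, 0.2, 0.7, 0.9]) == 1.0

    def test_label_flip_maps_auc_to_complement(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        assert pf.auc_score(labels, scores) == pytest.approx(
            1.0 - pf.auc_score(1 - labels, scores)
        )

    @pytest.mark.parametrize("n,ties", [(10, False), (57, True), (200, True), (200, False)])
    def test_auc_equals_pairwise_concordance(self, n, ties):
        rng = np.random.default_rng(n + ties)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.integers(0, 8, n) / 8.0 if ties else rng.random(n)
        assert pf.auc_score(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )

    def test_youden_threshold_maximizes_index(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        scores = np.array([0.1, 0.3, 0.6, 0.4, 0.7, 0.8, 0.9])
        thr = pf.youden_threshold(labels, scores)
        from perifuse.metrics import confusion_metrics

        best = confusion_metrics(labels, scores, thr)
        for t in np.unique(scores):
            other = confusion_metrics(labels, scores, t)
            assert (
                best["sensitivity"] + best["specificity"]
                >= other["sensitivity"] + other["specificity"] - 1e-12
            )

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 40)
        scores = rng.random(80) + 0.5 * labels
        rep = evaluate_at_threshold(labels, scores, threshold=0.75, n_boot=200, seed=0)
        for metric in ("auc", "accuracy", "sensitivity", "specificity"):
            lo, hi = rep.ci95[metric]
            assert lo <= getattr(rep, metric) <= hi

    def test_fit_and_evaluate_freezes_train_threshold(self):
        rng = np.random.default_rng(6)
        y_tr = np.repeat([0, 1], 40)
        x_tr = rng.standard_normal((80, 3)) + 1.2 * y_tr[:, None]
        y_te = np.repeat([0, 1], 15)
        x_te = rng.standard_normal((30, 3)) + 1.2 * y_te[:, None]
        train_rep, test_rep, model = pf.fit_and_evaluate(
            fm(x_tr, y_tr), fm(x_te, y_te), n_boot=50, seed=0
        )
        assert train_rep.threshold == test_rep.threshold == model.threshold
        assert 0.5 < train_rep.auc <= 1.0
        assert train_rep.cv_auc == pytest.approx(train_rep.auc, abs=0.2)
        assert test_rep.n_cases == 30

    def test_single_class_test_cohort_warns_and_suppresses_ci(self):
        rng = np.random.default_rng(7)
        y_tr = np.repeat([0, 1], 20)
        x_tr = rng.standard_normal((40, 2)) + y_tr[:, None]
        x_te = rng.standard_normal((6, 2))
        with pytest.warns(UserWarning, match="single-class"):
            _, test_rep, _ = pf.fit_and_evaluate(
                fm(x_tr, y_tr), fm(x_te, [1] * 6), n_boot=100, seed=0
            )
        assert test_rep.ci95 == {}


class TestCompareAucPaired:
    def test_identical_scores_give_zero_delta_p_one(self):
        labels = np.repeat([0, 1], 10)
        scores = np.linspace(0, 1, 20)
        delta, p = pf.compare_auc_paired(scores, scores, labels)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 30)
        a = rng.random(60) + 0.4 * labels
        b = rng.random(60) + 0.1 * labels
        d_ab, p_ab = pf.compare_auc_paired(a, b, labels)
        d_ba, p_ba = pf.compare_auc_paired(b, a, labels)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ParameterError, match="identical case sets"):
            pf.compare_auc_paired([0.1, 0.2], [0.1], [0, 1])

    def test_delong_variance_close_to_bootstrap(self):
        """Analytic DeLong variance of the paired AUC difference within 20%
        of a 2000-replicate bootstrap on n=200 correlated scores."""
        rng = np.random.default_rng(12)
        n = 200
        labels = np.repeat([0, 1], n // 2)
        latent = rng.standard_normal(n) + 0.8 * labels
        a = latent + 0.6 * rng.standard_normal(n)
        b = latent + 0.6 * rng.standard_normal(n)

        pos, neg = labels == 1, labels == 0
        v10a = ((a[pos][:, None] > a[neg]) + 0.5 * (a[pos][:, None] == a[neg])).mean(1)
        v10b = ((b[pos][:, None] > b[neg]) + 0.5 * (b[pos][:, None] == b[neg])).mean(1)
        delong_var = _paired_delong_var(a, b, labels)

        boot = []
        for _ in range(2000):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(pos), pos.sum()),
                rng.choice(np.flatnonzero(neg), neg.sum()),
            ])
            boot.append(pf.auc_score(labels[idx], a[idx]) - pf.auc_score(labels[idx], b[idx]))
        boot_var = np.var(boot, ddof=1)
        assert abs(delong_var - boot_var) <= 0.2 * boot_var


def _paired_delong_var(a, b, labels):
    """Recover the variance the paired test used, from its z statistic."""
    from scipy import stats

    delta, p = pf.compare_auc_paired(a, b, labels)
    z = stats.norm.isf(p / 2.0)
    return (delta / z) ** 2


class TestChainIntegration:
    def _features(self, seed, n=80, p=60, shift=1.5):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        x = rng.standard_normal((n, p))
        x[:, :3] += shift * y[:, None]
        perm = rng.permutation(n)
        return fm(x[perm], y[perm])

    def test_counts_never_increase_along_the_chain(self):
        train = self._features(0)
        test = self._features(1)
        _, _, report = pf.run_selection_chain(train, test, ChainParams(), seed=0)
        counts = [report.n_input, report.n_after_pca, report.n_after_mwu,
                  report.n_after_pearson, report.n_after_lasso]
        assert counts == sorted(counts, reverse=True)
        assert report.n_after_lasso >= 1

    def test_no_leakage_from_test_rows(self):
        """Transforms are fitted on train only: permuting test rows permutes
        scores correspondingly, and editing one test row leaves the other
        test scores untouched."""
        train = self._features(2)
        test = self._features(3)
        tr_sel, te_sel, _ = pf.run_selection_chain(train, test, seed=0)
        _, _, model = pf.fit_and_evaluate(tr_sel, te_sel, n_boot=0, seed=0)
        scores = model.scores(te_sel)

        perm = np.random.default_rng(0).permutation(test.n_cases)
        test_perm = FeatureMatrix(
            test.values[perm], [test.case_ids[i] for i in perm], test.labels[perm],
            list(test.feature_names), list(test.region_tags),
        )
        tr2, te2, _ = pf.run_selection_chain(train, test_perm, seed=0)
        _, _, model2 = pf.fit_and_evaluate(tr2, te2, n_boot=0, seed=0)
        assert np.allclose(model2.scores(te2), scores[perm])

        tampered = test.values.copy()
        tampered[4] += 100.0
        test_mod = FeatureMatrix(
            tampered, list(test.case_ids), test.labels.copy(),
            list(test.feature_names), list(test.region_tags),
        )
        tr3, te3, _ = pf.run_selection_chain(train, test_mod, seed=0)
        _, _, model3 = pf.fit_and_evaluate(tr3, te3, n_boot=0, seed=0)
        scores3 = model3.scores(te3)
        keep = np.arange(test.n_cases) != 4
        assert np.allclose(scores3[keep], scores[keep])

    def test_flf_regions_get_symmetric_pca_blocks(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 30)
        x = rng.standard_normal((60, 200))
        x[:, :5] += y[:, None]
        tags = ["intra"] * 100 + ["peri"] * 100
        train = fm(x, y, tags=tags)
        reduced, _ = pf.selection.pca_reduce_by_region(train, None, n_components=32)
        assert reduced.n_features == 64
        assert reduced.region_tags.count("intra") == 32
        assert reduced.region_tags.count("peri") == 32
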