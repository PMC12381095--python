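"""LDA, balanced folds, super-trials, within/cross-phase decoding, cluster null."""

import itertools

import numpy as np
import pytest
from scipy import stats

from retromem import decoding, erp, synth


class TestLda:
    def test_separable_toy_perfect_and_bisector(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.1, size=(30, 2))
        b = rng.normal([10, 0], 0.1, size=(30, 2))
        X = np.vstack([a, b])
        y = np.array([0] * 30 + [1] * 30)
        model = decoding.lda_fit(X, y, shrinkage=0.0)
        assert np.all(decoding.lda_predict(model, X) == y)
        # decision boundary at the perpendicular bisector of the class means
        mid = (model.class_means[0] + model.class_means[1]) / 2.0
        s = decoding.lda_scores(model, mid[None, :])[0]
        assert abs(s[0] - s[1]) < 1e-6
        probe = mid + np.array([0.5, 0.0])
        assert decoding.lda_predict(model, probe[None, :])[0] == 1

    def test_tie_breaks_to_lowest_class_index(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([0, 1])
        model = decoding.lda_fit(X, y, shrinkage=1.0)
        # exactly equidistant from both means
        assert decoding.lda_predict(model, np.array([[1.0]]))[0] == 0

    def test_full_shrinkage_equals_diagonal_discriminant(self, rng):
        X = rng.normal(size=(60, 3)) + np.repeat([[0, 0, 0], [2, 1, 0]], 30, axis=0)
        y = np.repeat([0, 1], 30)
        model = decoding.lda_fit(X, y, shrinkage=1.0)
        assert np.allclose(
            model.pooled_covariance, np.diag(np.diag(model.pooled_covariance))
        )
        # scores must equal the explicit shared-diagonal-covariance Gaussian
        # log-likelihood up to a per-sample constant
        Xt = rng.normal(size=(10, 3))
        var = np.diag(model.pooled_covariance)
        ll = np.stack(
            [
                -0.5 * np.sum((Xt - m) ** 2 / var, axis=1) + np.log(pi)
                for m, pi in zip(model.class_means, model.class_priors)
            ],
            axis=1,
        )
        s = decoding.lda_scores(model, Xt)
        diff = s - ll
        assert np.allclose(diff - diff[:, :1], 0.0, atol=1e-9)

    def test_one_trial_per_class_is_nearest_mean(self):
        X = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        y = np.array([0, 1, 2])
        model = decoding.lda_fit(X, y, shrinkage=1.0)
        probes = np.array([[0.5, 0.5], [3.5, 0.2], [0.1, 3.9]])
        assert list(decoding.lda_predict(model, probes)) == [0, 1, 2]

    def test_score_equivalence_with_gaussian_likelihood_oracle(self, rng):
        X = rng.normal(size=(90, 3)) + np.repeat([[0, 0, 0], [1, 2, 0], [0, 1, 2]], 30, axis=0)
        y = np.repeat([0, 1, 2], 30)
        lam = 0.3
        model = decoding.lda_fit(X, y, shrinkage=lam)
        Xt = rng.normal(size=(12, 3))
        cov = model.pooled_covariance
        icov = np.linalg.inv(cov)
        ll = np.stack(
            [
                -0.5 * np.einsum("ij,jk,ik->i", Xt - m, icov, Xt - m) + np.log(pi)
                for m, pi in zip(model.class_means, model.class_priors)
            ],
            axis=1,
        )
        s = decoding.lda_scores(model, Xt)
        diff = s - ll
        assert np.allclose(diff - diff[:, :1], 0.0, atol=1e-8)
        assert np.all(np.argmax(s, axis=1) == np.argmax(ll, axis=1))

    def test_agrees_with_sklearn_on_well_separated_data(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 4, size=200)
        X[:, :4] += 3.0 * np.eye(4)[y, :]
        ours = decoding.lda_fit(X, y, shrinkage=0.0)
        ref = LinearDiscriminantAnalysis().fit(X, y)
        Xt = rng.normal(size=(100, 5))
        Xt[:, :4] += 3.0 * np.eye(4)[rng.integers(0, 4, 100), :]
        agree = np.mean(decoding.lda_predict(ours, Xt) == ref.predict(Xt))
        assert agree == 1.0

    def test_dimension_mismatch_raises(self, rng):
        model = decoding.lda_fit(rng.normal(size=(20, 3)), rng.integers(0, 2, 20), 0.5)
        with pytest.raises(ValueError, match="dimension"):
            decoding.lda_predict(model, rng.normal(size=(5, 4)))


class TestBalancedFolds:
    def test_four_classes_ten_each_ten_folds(self):
        y = np.repeat([0, 1, 2, 3], 10)
        folds = decoding.build_balanced_folds(y, 10, seed=0)
        assert np.all(folds >= 0)
        for f in range(10):
            labels = y[folds == f]
            assert sorted(labels) == [0, 1, 2, 3]

    def test_unbalanced_classes_are_subsampled(self):
        y = np.array([0] * 12 + [1] * 10 + [2] * 10 + [3] * 10)
        folds = decoding.build_balanced_folds(y, 10, seed=1)
        assert np.sum((y == 0) & (folds == -1)) == 2
        assert np.sum(folds >= 0) == 40

    def test_deterministic(self):
        y = np.repeat([0, 1, 2, 3], 20)
        a = decoding.build_balanced_folds(y, 5, seed=7)
        b = decoding.build_balanced_folds(y, 5, seed=7)
        assert np.array_equal(a, b)

    def test_too_few_trials_per_class_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            decoding.build_balanced_folds(np.repeat([0, 1], 4), 10, seed=0)


class TestSuperTrials:
    def test_k1_is_identity(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.integers(0, 2, 20)
        Xs, ys = decoding.make_super_trials(X, y, 1, seed=0)
        assert np.array_equal(Xs, X)
        assert np.array_equal(ys, y)

    def test_k_equals_class_size_gives_class_mean(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.repeat([0, 1], 6)
        Xs, ys = decoding.make_super_trials(X, y, 6, seed=0)
        assert Xs.shape == (2, 4)
        for c in (0, 1):
            assert np.allclose(Xs[ys == c][0], X[y == c].mean(axis=0))

    def test_variance_reduced_k_fold(self):
        k, reps = 4, 100
        ratios = []
        for s in range(reps):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(80, 1))
            y = np.zeros(80, dtype=int)
            Xs, _ = decoding.make_super_trials(X, y, k, seed=s)
            ratios.append(Xs.var() / X.var())
        assert abs(np.mean(ratios) - 1.0 / k) < 0.2 / k

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer"):
            decoding.make_super_trials(rng.normal(size=(6, 2)), np.repeat([0, 1], 3), 4, 0)


def _quick_config(**kw):
    base = dict(n_folds=4, super_trial_size=2, n_repeats=1, seed=0)
    base.update(kw)
    return decoding.DecoderConfig(**base)


class TestWithinPhase:
    def test_shuffled_labels_decode_at_chance(self):
        params = synth.GeneratorParams(
            experiment=1, n_participants=1, n_objects=48, seed=13,
            noise_sd=2.0, location_signal_amplitude=3.0,
        )
        exp = synth.SyntheticExperiment(params)
        ep = exp.epochs(0, "encoding")
        rng = np.random.default_rng(99)
        ep.metadata["location"] = rng.permutation(ep.metadata["location"].to_numpy())
        idx = np.arange(50, 350, 25)
        tc = decoding.decode_within_phase(ep, _quick_config(n_repeats=2), time_indices=idx)
        accs = tc.accuracy[0]
        se = np.sqrt(0.25 * 0.75 / (len(accs) * 16))  # rough scale
        assert abs(accs.mean() - 0.25) < max(3 * accs.std() / np.sqrt(len(accs)), 0.06)

    def test_noiseless_distinct_patterns_decode_perfectly(self):
        params = synth.GeneratorParams(
            experiment=1, n_participants=1, n_objects=48, seed=14,
            noise_sd=0.0, location_signal_amplitude=2.0, participant_amplitude_sd=0.0,
        )
        exp = synth.SyntheticExperiment(params)
        ep = exp.epochs(0, "encoding")
        peak = int(np.argmin(np.abs(ep.times - 500.0)))
        tc = decoding.decode_within_phase(ep, _quick_config(), time_indices=np.array([peak]))
        assert tc.accuracy[0, 0] == 1.0
        assert tc.chance_level == 0.25

    def test_output_time_axis_matches_input(self, small_experiment):
        ep = small_experiment.epochs(0, "encoding")
        idx = np.arange(0, len(ep.times), 30)
        tc = decoding.decode_within_phase(ep, _quick_config(), time_indices=idx)
        assert np.array_equal(tc.times, ep.times[idx])


class TestCrossPhase:
    @pytest.mark.parametrize("rho,above", [(0.0, False), (1.0, True)])
    def test_cross_phase_tracks_pattern_similarity(self, rho, above):
        params = synth.GeneratorParams(
            experiment=1, n_participants=3, n_objects=48, seed=15,
            noise_sd=2.0, location_signal_amplitude=3.0, cross_phase_similarity=rho,
        )
        exp = synth.SyntheticExperiment(params)
        tcs = [
            decoding.decode_cross_phase(
                exp.epochs(p, "encoding"), (0.0, 500.0),
                exp.epochs(p, "retrieval"), (500.0, 1000.0),
                _quick_config(), train_mode="window_mean",
            )
            for p in range(3)
        ]
        group = decoding.stack_timecourses(tcs)
        mean_acc = group.accuracy.mean()
        if above:
            assert mean_acc > 0.4
        else:
            assert abs(mean_acc - 0.25) < 0.05

    def test_argument_order_symmetry(self):
        params = synth.GeneratorParams(
            experiment=1, n_participants=1, n_objects=48, seed=16,
            noise_sd=2.0, location_signal_amplitude=3.0, cross_phase_similarity=0.5,
        )
        exp = synth.SyntheticExperiment(params)
        enc, ret = exp.epochs(0, "encoding"), exp.epochs(0, "retrieval")
        a = decoding.decode_cross_phase(
            enc, (0, 500), ret, (500, 1000), _quick_config(), train_mode="window_mean"
        )
        b = decoding.decode_cross_phase(
            ret, (500, 1000), enc, (0, 500), _quick_config(), train_mode="window_mean"
        )
        assert np.allclose(a.accuracy, b.accuracy)


def _exact_max_run_distribution(diffs, alpha, min_len):
    """Sufficiency-collapsed oracle for the cell-wise swap null.

    Columns are independent under cell-wise sign flips, so per column the
    probability of a sub-alpha one-sided t is exact over its 2^n sign
    patterns; the max-run distribution follows by enumerating indicator
    patterns.
    """
    n, T = diffs.shape
    q = []
    for j in range(T):
        hits = 0
        for signs in itertools.product([1.0, -1.0], repeat=n):
            d = diffs[:, j] * np.array(signs)
            sd = d.std(ddof=1)
            if sd == 0:
                continue
            t = d.mean() / (sd / np.sqrt(n))
            if stats.t.sf(t, n - 1) < alpha:
                hits += 1
        q.append(hits / 2**n)
    probs = {}
    for pattern in itertools.product([0, 1], repeat=T):
        pr = np.prod([q[j] if b else 1 - q[j] for j, b in enumerate(pattern)])
        best = run = 0
        for b in pattern:
            run = run + 1 if b else 0
            best = max(best, run)
        key = best if best >= min_len else 0
        probs[key] = probs.get(key, 0.0) + pr
    return probs


class TestDecodingClusterTest:
    def _timecourse(self, acc, chance=0.25):
        acc = np.asarray(acc, dtype=float)
        return decoding.DecodingTimecourse(
            accuracy=acc,
            times=np.arange(acc.shape[1]) * 4.0,
            chance_level=chance,
            kind="within",
        )

    def test_accuracy_at_chance_never_significant(self):
        tc = self._timecourse(np.full((10, 30), 0.25))
        res = decoding.decoding_cluster_test(
            tc, erp.ClusterTestConfig(n_permutations=300, seed=0)
        )
        assert res.significant_clusters == []
        assert res.clusters == []

    def test_perfect_accuracy_yields_full_window_cluster(self):
        tc = self._timecourse(np.ones((20, 50)))
        res = decoding.decoding_cluster_test(
            tc, erp.ClusterTestConfig(n_permutations=500, seed=1)
        )
        assert len(res.significant_clusters) == 1
        start, end, length = res.significant_clusters[0]
        assert (start, end, length) == (0.0, 49 * 4.0, 50)

    def test_null_matches_sufficiency_collapsed_oracle(self):
        rng = np.random.default_rng(17)
        n, T = 5, 4
        acc = 0.25 + rng.normal(0.05, 0.1, size=(n, T))
        tc = self._timecourse(acc)
        n_perm = 6000
        res = decoding.decoding_cluster_test(
            tc, erp.ClusterTestConfig(n_permutations=n_perm, seed=2)
        )
        exact = _exact_max_run_distribution(acc - 0.25, 0.05, 2)
        for size, pr in exact.items():
            emp = np.mean(res.null_max_cluster_sizes == size)
            tol = 4 * np.sqrt(max(pr * (1 - pr), 1e-4) / n_perm)
            assert abs(emp - pr) < tol, (size, emp, pr)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(18)
        tc = self._timecourse(0.25 + rng.normal(0, 0.05, size=(8, 20)))
        cfg = erp.ClusterTestConfig(n_permutations=400, seed=3)
        r1 = decoding.decoding_cluster_test(tc, cfg)
        r2 = decoding.decoding_cluster_test(tc, cfg)
        assert np.array_equal(r1.null_max_cluster_sizes, r2.null_max_cluster_sizes)
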