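"""Linear-discriminant location decoding within and across task phases.

Pipeline per participant and time point: subsample trials so every location
class is equally frequent, split into class-balanced cross-validation folds,
average same-class trials into super-trials separately on the train and test
sides, fit a shrinkage-regularized LDA on all channels, and score accuracy
on the held-out fold. Balanced folds make the empirical chance level exactly
1/n_classes (0.25 for the four locations).

Cross-phase decoding trains on one phase's designated window and tests on
the other's, in both directions; the reported accuracy is the average of the
two directions as a function of time *within* the designated windows (the
windows have equal length, so test times align on a common relative axis).

Significance against chance uses the swap-with-chance permutation null: for
each participant and time point, the observed accuracy and the chance
constant are randomly exchanged between the two comparison vectors, and a
one-sided paired t / maximum-cluster-size statistic is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erp import ClusterResult, ClusterTestConfig
from .synth import EEGEpochs


@dataclass(frozen=True)
class DecoderConfig:
    n_folds: int = 10
    super_trial_size: int = 4
    shrinkage: float | None = None  # None = analytic (toward diagonal)
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.super_trial_size < 1:
            raise ValueError("super_trial_size must be >= 1")
        if self.shrinkage is not None and not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")


@dataclass
class LdaModel:
    classes: np.ndarray
    class_means: np.ndarray  # (classes, features)
    pooled_covariance: np.ndarray  # regularized
    class_priors: np.ndarray
    _weights: np.ndarray = None  # Sigma^-1 mu_k, cached
    _bias: np.ndarray = None


@dataclass
class DecodingTimecourse:
    """Per-participant, per-timepoint classification accuracy."""

    accuracy: np.ndarray  # (participant, time)
    times: np.ndarray  # ms (within-phase: epoch times; cross: relative ms)
    chance_level: float
    kind: str  # "within" | "cross"
    train_window: tuple | None = None
    test_window: tuple | None = None
    extras: dict = field(default_factory=dict)


def _diag_shrinkage_intensity(X: np.ndarray, means: np.ndarray, labels, classes) -> float:
    """Analytic shrinkage intensity toward the diagonal target.

    Schafer–Strimmer style: lambda* = sum of estimated variances of the
    off-diagonal sample covariances over the sum of their squares, clipped
    to [0, 1]. Computed on within-class centered data.
    """
    centered = X - means[np.searchsorted(classes, labels)]
    n = centered.shape[0]
    if n < 2:
        return 1.0
    w = centered[:, :, None] * centered[:, None, :]  # (n, f, f)
    s = w.mean(axis=0)
    var_s = w.var(axis=0) * n / (n - 1) ** 2
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = np.sum(s[off] ** 2)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))


def lda_fit(features: np.ndarray, labels, shrinkage: float | None = None) -> LdaModel:
    """Fit LDA with pooled covariance shrunk toward its own diagonal.

    Sigma_reg = (1 - lambda) Sigma + lambda diag(Sigma). With lambda = 1 the
    classifier reduces to a diagonal-covariance (naive Gaussian)
    discriminant; with one trial per class it is the nearest-class-mean
    classifier.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    n, f = X.shape
    centered = X - means[np.searchsorted(classes, y)]
    dof = max(n - len(classes), 1)
    cov = centered.T @ centered / dof
    lam = shrinkage
    if lam is None:
        lam = _diag_shrinkage_intensity(X, means, y, classes) if n > len(classes) else 1.0
    cov_reg = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))
    if not np.all(np.isfinite(cov_reg)):
        raise np.linalg.LinAlgError("non-finite covariance; increase shrinkage")
    # zero-variance features (noiseless or single-trial classes): fall back
    # to unit variance there, which makes the lam = 1 limit the
    # nearest-class-mean classifier
    diag = np.diag(cov_reg).copy()
    if np.any(diag <= 0):
        fill = diag[diag > 0].mean() if np.any(diag > 0) else 1.0
        idx = np.flatnonzero(diag <= 0)
        cov_reg = cov_reg.copy()
        cov_reg[idx, idx] = fill
    priors = counts / counts.sum()
    try:
        weights = np.linalg.solve(cov_reg, means.T)  # (features, classes)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular regularized covariance; increase shrinkage"
        ) from err
    bias = -0.5 * np.sum(means.T * weights, axis=0) + np.log(priors)
    return LdaModel(
        classes=classes,
        class_means=means,
        pooled_covariance=cov_reg,
        class_priors=priors,
        _weights=weights,
        _bias=bias,
    )


def lda_scores(model: LdaModel, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError("feature dimension mismatch")
    return X @ model._weights + model._bias


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Argmax of the linear discriminant scores; ties -> lowest class index."""
    scores = lda_scores(model, features)
    return model.classes[np.argmax(scores, axis=1)]  # argmax takes first max


def build_balanced_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Class-balanced fold assignment; -1 marks subsampled-out trials.

    Every class is randomly subsampled to the same count (the largest
    multiple of ``n_folds`` not exceeding the minimum class count) and
    spread evenly over folds, so each fold holds exactly the same number of
    trials of every class.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    per_fold = m // n_folds
    if per_fold < 1:
        raise ValueError(
            f"minimum class count {m} is smaller than n_folds={n_folds}"
        )
    keep_per_class = per_fold * n_folds
    assignment = np.full(len(y), -1, dtype=int)
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)[:keep_per_class]
        folds = np.repeat(np.arange(n_folds), per_fold)
        assignment[idx] = rng.permutation(folds)
    return assignment


def make_super_trials(features: np.ndarray, labels, k: int, seed: int):
    """Average k distinct same-class trials into pseudo-trials.

    Leftover trials (fewer than k in a class after chunking) are dropped.
    Averaging reduces noise variance about k-fold. Works for 2-D
    (trial, feature) and 3-D (trial, feature, time) arrays.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if k == 1:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    out_X, out_y = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            raise ValueError(f"class {c!r} has fewer than k={k} trials")
        idx = rng.permutation(idx)
        n_groups = len(idx) // k
        for g in range(n_groups):
            out_X.append(X[idx[g * k : (g + 1) * k]].mean(axis=0))
            out_y.append(c)
    return np.stack(out_X), np.asarray(out_y)


def _super_trial_groups(indices: np.ndarray, labels, k: int, rng) -> list:
    """Index groups of k same-class trials (for reuse across time points)."""
    y = np.asarray(labels)
    groups = []
    for c in np.unique(y[indices]):
        idx = indices[y[indices] == c]
        idx = rng.permutation(idx)
        for g in range(len(idx) // k):
            groups.append((c, idx[g * k : (g + 1) * k]))
    return groups


def decode_within_phase(
    epochs: EEGEpochs,
    config: DecoderConfig = DecoderConfig(),
    label_column: str = "location",
    time_indices: np.ndarray | None = None,
) -> DecodingTimecourse:
    """Per-timepoint location decoding for a single participant.

    Returns a (1, time) accuracy array; stack several participants'
    timecourses for group statistics. ``time_indices`` restricts computation
    to a subset of time points (accuracy reported only there).
    """
    y = epochs.metadata[label_column].to_numpy()
    classes = np.unique(y)
    times_idx = (
        np.arange(len(epochs.times)) if time_indices is None else np.asarray(time_indices)
    )
    acc = np.zeros(len(times_idx))
    rng = np.random.default_rng(config.seed)
    n_total = 0
    for rep in range(config.n_repeats):
        folds = build_balanced_folds(y, config.n_folds, int(rng.integers(2**31)))
        for f in range(config.n_folds):
            train_idx = np.flatnonzero((folds >= 0) & (folds != f))
            test_idx = np.flatnonzero(folds == f)
            g_train = _super_trial_groups(train_idx, y, config.super_trial_size, rng)
            g_test = _super_trial_groups(test_idx, y, config.super_trial_size, rng)
            if not g_train or not g_test:
                continue
            ytr = np.array([c for c, _ in g_train])
            yte = np.array([c for c, _ in g_test])
            Xtr_all = np.stack([epochs.data[g].mean(axis=0) for _, g in g_train])
            Xte_all = np.stack([epochs.data[g].mean(axis=0) for _, g in g_test])
            for j, t in enumerate(times_idx):
                model = lda_fit(Xtr_all[:, :, t], ytr, config.shrinkage)
                pred = lda_predict(model, Xte_all[:, :, t])
                acc[j] += np.mean(pred == yte)
            n_total += 1
    if n_total == 0:
        raise ValueError("no usable folds; check trial counts vs super_trial_size")
    return DecodingTimecourse(
        accuracy=(acc / n_total)[None, :],
        times=epochs.times[times_idx],
        chance_level=1.0 / len(classes),
        kind="within",
        extras={"super_trial_size": config.super_trial_size, "n_folds": config.n_folds},
    )


def _balanced_subsample(labels, rng) -> np.ndarray:
    """Indices with every class subsampled to the minimum class count."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = [rng.permutation(np.flatnonzero(y == c))[:m] for c in classes]
    return np.sort(np.concatenate(keep))


def _window_indices(times: np.ndarray, window: tuple) -> np.ndarray:
    idx = np.flatnonzero((times >= window[0]) & (times <= window[1]))
    if len(idx) == 0:
        raise ValueError(f"window {window} outside epoch times")
    return idx


def _cross_direction(
    train_ep: EEGEpochs,
    train_idx: np.ndarray,
    test_ep: EEGEpochs,
    test_idx: np.ndarray,
    config: DecoderConfig,
    label_column: str,
    rng,
    train_mode: str,
) -> np.ndarray:
    """Accuracy per test time point, averaged over training time points."""
    ytr_all = train_ep.metadata[label_column].to_numpy()
    yte_all = test_ep.metadata[label_column].to_numpy()
    acc = np.zeros(len(test_idx))
    n_total = 0
    for rep in range(config.n_repeats):
        tr_keep = _balanced_subsample(ytr_all, rng)
        te_keep = _balanced_subsample(yte_all, rng)
        g_train = _super_trial_groups(tr_keep, ytr_all, config.super_trial_size, rng)
        g_test = _super_trial_groups(te_keep, yte_all, config.super_trial_size, rng)
        ytr = np.array([c for c, _ in g_train])
        yte = np.array([c for c, _ in g_test])
        Xtr = np.stack([train_ep.data[g].mean(axis=0) for _, g in g_train])
        Xte = np.stack([test_ep.data[g].mean(axis=0) for _, g in g_test])
        if train_mode == "window_mean":
            model = lda_fit(Xtr[:, :, train_idx].mean(axis=2), ytr, config.shrinkage)
            for j, tt in enumerate(test_idx):
                acc[j] += np.mean(lda_predict(model, Xte[:, :, tt]) == yte)
            n_total += 1
        else:  # per training time point, averaged
            for t in train_idx:
                model = lda_fit(Xtr[:, :, t], ytr, config.shrinkage)
                for j, tt in enumerate(test_idx):
                    acc[j] += np.mean(lda_predict(model, Xte[:, :, tt]) == yte)
            n_total += len(train_idx)
    return acc / max(n_total, 1)


def decode_cross_phase(
    epochs_a: EEGEpochs,
    window_a: tuple,
    epochs_b: EEGEpochs,
    window_b: tuple,
    config: DecoderConfig = DecoderConfig(),
    label_column: str = "location",
    train_mode: str = "per_timepoint",
) -> DecodingTimecourse:
    """Reciprocal cross-phase decoding for one participant.

    Direction 1 trains on phase A inside ``window_a`` and tests across
    ``window_b``; direction 2 swaps the roles. Both windows must have equal
    duration; accuracies are averaged on the common relative time axis, so
    the result is symmetric in the argument order. ``train_mode`` is
    ``per_timepoint`` (train at every training time point and average) or
    ``window_mean`` (train once on window-averaged features).
    """
    idx_a = _window_indices(epochs_a.times, window_a)
    idx_b = _window_indices(epochs_b.times, window_b)
    m = min(len(idx_a), len(idx_b))
    idx_a, idx_b = idx_a[:m], idx_b[:m]
    # both directions draw from identically seeded streams, which makes the
    # averaged result invariant to swapping the (A, B) argument order
    acc_ab = _cross_direction(
        epochs_a, idx_a, epochs_b, idx_b, config, label_column,
        np.random.default_rng(config.seed + 1), train_mode,
    )
    acc_ba = _cross_direction(
        epochs_b, idx_b, epochs_a, idx_a, config, label_column,
        np.random.default_rng(config.seed + 1), train_mode,
    )
    rel_times = epochs_a.times[idx_a] - epochs_a.times[idx_a][0]
    classes = np.unique(epochs_a.metadata[label_column].to_numpy())
    return DecodingTimecourse(
        accuracy=((acc_ab + acc_ba) / 2.0)[None, :],
        times=rel_times,
        chance_level=1.0 / len(classes),
        kind="cross",
        train_window=tuple(window_a),
        test_window=tuple(window_b),
        extras={"train_mode": train_mode},
    )


def stack_timecourses(timecourses: list) -> DecodingTimecourse:
    """Stack single-participant timecourses into one group object."""
    first = timecourses[0]
    return DecodingTimecourse(
        accuracy=np.vstack([tc.accuracy for tc in timecourses]),
        times=first.times,
        chance_level=first.chance_level,
        kind=first.kind,
        train_window=first.train_window,
        test_window=first.test_window,
        extras=dict(first.extras),
    )


def decoding_cluster_test(
    timecourse: DecodingTimecourse, config: ClusterTestConfig
) -> ClusterResult:
    """Swap-with-chance cluster permutation test (one-sided, above chance).

    The observed comparison is accuracy vs the chance constant; under the
    null each participant/time cell's accuracy and the chance value are
    exchangeable, which is exactly a sign flip of (accuracy - chance).
    """
    acc = timecourse.accuracy
    if acc.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    diffs = acc - timecourse.chance_level
    n, T = diffs.shape

    from scipy import stats as sstats

    from .erp import (
        _max_run_lengths,
        _paired_t_from_diffs,
        find_clusters,
        nearest_rank_percentile,
    )

    _, p_obs = _paired_t_from_diffs(diffs, "one")
    observed = find_clusters(p_obs, config.alpha_pointwise, config.min_cluster_length)

    # cell-wise sign flips: swapping a cell's accuracy with the chance
    # constant between the two comparison vectors negates that cell's
    # difference, independently per participant AND time point
    rng = np.random.default_rng(config.seed)
    msq = np.mean(diffs**2, axis=0)
    null = np.empty(config.n_permutations, dtype=int)
    chunk = max(1, int(5e6 // (n * T)))
    done = 0
    while done < config.n_permutations:
        m = min(chunk, config.n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n, T))
        mean = (signs * diffs).mean(axis=1)
        var = np.maximum((msq - mean**2) * n / (n - 1), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
        p = sstats.t.sf(t, df=n - 1)
        null[done : done + m] = _max_run_lengths(
            p < config.alpha_pointwise, config.min_cluster_length
        )
        done += m
    threshold = int(nearest_rank_percentile(null, config.null_percentile))
    clusters_ms = [
        (float(timecourse.times[s]), float(timecourse.times[e]), int(l))
        for s, e, l in observed
    ]
    significant = [c for c in clusters_ms if c[2] > threshold]
    return ClusterResult(
        clusters=clusters_ms,
        null_max_cluster_sizes=null,
        size_threshold=threshold,
        significant_clusters=significant,
    )
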