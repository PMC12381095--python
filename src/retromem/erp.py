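"""Condition ERPs over an electrode cluster and cluster-based permutation tests.

The contrast machinery follows the classic maximum-cluster-size permutation
scheme for paired designs: pointwise paired t-tests threshold the time
series at ``alpha``; runs of at least ``min_cluster_length`` contiguous
significant points form clusters; the null distribution of the *largest*
cluster length is built by randomly flipping, per participant, the sign of
the condition difference (equivalent to shuffling the two condition labels
within participant); observed clusters longer than the 95th percentile
(nearest rank) of that null are significant. Strictly longer — ties at the
threshold are not significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synth import EEGEpochs, PARIETAL_CLUSTER


@dataclass
class ErpMatrix:
    """Cluster-averaged ERPs: values (participant, condition, time) in μV."""

    values: np.ndarray
    times: np.ndarray  # ms
    conditions: list
    electrode_cluster: tuple = PARIETAL_CLUSTER
    analysis_window: tuple = (0.0, 1200.0)

    def condition_index(self, cond: str) -> int:
        return list(self.conditions).index(cond)


@dataclass(frozen=True)
class ClusterTestConfig:
    alpha_pointwise: float = 0.05
    n_permutations: int = 10_000
    min_cluster_length: int = 2
    null_percentile: float = 95.0
    seed: int = 0
    sidedness: str = "two"  # "two" or "one" (one-sided: A > B)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_pointwise < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.min_cluster_length < 2:
            raise ValueError("min_cluster_length must be >= 2")


@dataclass
class ClusterResult:
    """Observed clusters, the permutation null, and the significance cut."""

    clusters: list  # (start_ms, end_ms, length_in_points)
    null_max_cluster_sizes: np.ndarray
    size_threshold: int
    significant_clusters: list = field(default_factory=list)
    exhaustive: bool = False

    def to_json(self, path=None) -> str:
        payload = {
            "clusters": [list(c) for c in self.clusters],
            "significant_clusters": [list(c) for c in self.significant_clusters],
            "size_threshold": int(self.size_threshold),
            "n_permutations": int(len(self.null_max_cluster_sizes)),
            "exhaustive": bool(self.exhaustive),
            "null_size_mean": float(np.mean(self.null_max_cluster_sizes)),
            "null_size_p95": int(self.size_threshold),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def condition_erp(
    participant_epochs: list,
    cluster=PARIETAL_CLUSTER,
    window=(0.0, 1200.0),
    conditions=None,
    by: str = "condition",
) -> ErpMatrix:
    """Average trials then cluster channels, per participant and condition.

    ``participant_epochs`` is one :class:`EEGEpochs` per participant. ``by``
    selects the metadata column defining the conditions (e.g. ``condition``
    or ``probing_count``).
    """
    first = participant_epochs[0]
    ch_idx = []
    for ch in cluster:
        if ch not in first.channel_labels:
            raise ValueError(f"channel {ch!r} not present")
        ch_idx.append(first.channel_labels.index(ch))
    tmask = (first.times >= window[0]) & (first.times <= window[1])
    times = first.times[tmask]
    if conditions is None:
        conditions = sorted(first.metadata[by].unique().tolist())
    values = np.empty((len(participant_epochs), len(conditions), tmask.sum()))
    for p, ep in enumerate(participant_epochs):
        for c, cond in enumerate(conditions):
            sel = (ep.metadata[by] == cond).to_numpy()
            if not sel.any():
                raise ValueError(f"participant {p} has no trials for {by}={cond!r}")
            # mean over trials, then over the electrode cluster
            values[p, c] = ep.data[sel][:, ch_idx][:, :, tmask].mean(axis=0).mean(axis=0)
    return ErpMatrix(values=values, times=times, conditions=list(conditions),
                     electrode_cluster=tuple(cluster), analysis_window=tuple(window))


def _paired_t_from_diffs(diffs: np.ndarray, sidedness: str = "two"):
    """t and p per time point from (participant, time) difference waveforms.

    Zero-variance convention: if all differences at a time point are equal,
    p = 1 when the mean difference is 0, else p = 0.
    """
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    if sidedness == "two":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    else:
        p = stats.t.sf(t, df=n - 1)
    degenerate = sd == 0
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            signed_inf = np.where(mean == 0, 0.0, np.sign(mean) * np.inf)
        t = np.where(degenerate, signed_inf, t)
        p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)
    return t, p


def paired_t_series(erp: ErpMatrix, cond_a, cond_b, sidedness: str = "two"):
    """Pointwise paired t-test between two conditions of an ErpMatrix."""
    if erp.values.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    diffs = erp.values[:, erp.condition_index(cond_a)] - erp.values[:, erp.condition_index(cond_b)]
    return _paired_t_from_diffs(diffs, sidedness)


def find_clusters(p: np.ndarray, alpha: float = 0.05, min_len: int = 2) -> list:
    """Maximal runs of strictly sub-alpha p-values with length >= min_len.

    Returns (start_index, end_index_inclusive, length) triples in order.
    """
    p = np.asarray(p)
    sig = p < alpha
    clusters = []
    start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            length = i - start
            if length >= min_len:
                clusters.append((start, i - 1, length))
            start = None
    return clusters


def _max_cluster_lengths_from_flips(
    diffs: np.ndarray, flips: np.ndarray, alpha: float, min_len: int, sidedness: str
) -> np.ndarray:
    """Largest cluster length per sign-flip assignment (vectorized).

    Sign flips leave per-participant squared differences unchanged, so
    permutation t statistics reduce to matrix products with the flip matrix.
    """
    n, T = diffs.shape
    mean = (flips @ diffs) / n  # (n_perm, T)
    msq = np.mean(diffs**2, axis=0)  # constant across flips
    var = (msq - mean**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if sidedness == "two":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    else:
        p = stats.t.sf(t, df=n - 1)
    sig = p < alpha
    return _max_run_lengths(sig, min_len)


def _max_run_lengths(sig: np.ndarray, min_len: int) -> np.ndarray:
    """Longest run of True per row (0 if shorter than min_len), vectorized."""
    sig = np.atleast_2d(sig)
    c = np.cumsum(sig, axis=1)
    # value of the cumulative count at the most recent False position
    base = np.maximum.accumulate(np.where(~sig, c, 0), axis=1)
    runs = np.where(sig, c - base, 0)
    best = runs.max(axis=1)
    return np.where(best >= min_len, best, 0).astype(int)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values))
    rank = int(np.ceil(q / 100.0 * len(v)))
    return float(v[max(rank, 1) - 1])


def cluster_permutation_test(
    erp: ErpMatrix, cond_a, cond_b, config: ClusterTestConfig
) -> ClusterResult:
    """Maximum-cluster-size permutation contrast between two conditions.

    Per permutation each participant's condition labels are independently
    swapped or kept — a sign flip of the difference waveform. When
    ``n_permutations`` is at least the 2^n distinct relabelings, the test
    switches to exhaustive enumeration.
    """
    if erp.values.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    diffs = (
        erp.values[:, erp.condition_index(cond_a)]
        - erp.values[:, erp.condition_index(cond_b)]
    )
    return cluster_permutation_from_diffs(diffs, erp.times, config)


def cluster_permutation_from_diffs(
    diffs: np.ndarray, times: np.ndarray, config: ClusterTestConfig
) -> ClusterResult:
    """Core sign-flip cluster test on (participant, time) differences."""
    n, T = diffs.shape
    _, p_obs = _paired_t_from_diffs(diffs, config.sidedness)
    observed = find_clusters(p_obs, config.alpha_pointwise, config.min_cluster_length)

    exhaustive = n <= 62 and config.n_permutations >= 2**n
    if exhaustive:
        m = 2**n
        flips = 1.0 - 2.0 * (
            (np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1
        ).astype(float)
    else:
        rng = np.random.default_rng(config.seed)
        flips = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    null = _max_cluster_lengths_from_flips(
        diffs, flips, config.alpha_pointwise, config.min_cluster_length, config.sidedness
    )
    threshold = int(nearest_rank_percentile(null, config.null_percentile))
    clusters_ms = [
        (float(times[s]), float(times[e]), int(l)) for s, e, l in observed
    ]
    significant = [c for c in clusters_ms if c[2] > threshold]
    return ClusterResult(
        clusters=clusters_ms,
        null_max_cluster_sizes=null,
        size_threshold=threshold,
        significant_clusters=significant,
        exhaustive=exhaustive,
    )
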