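"""Behavioral statistics battery for retrieval-phase accuracy and RT.

Omnibus: one-way repeated-measures ANOVA with Mauchly's sphericity test and
Greenhouse–Geisser correction, plus the non-parametric Friedman test with
Kendall's W. Pairwise: paired t with Cohen's d_av and a 95% CI on the mean
difference, Wilcoxon signed-rank with r = z/sqrt(n), Benjamini–Hochberg FDR
adjustment across a family of contrasts, and the default (JZS) Bayes factor
for the paired t-test with a Cauchy prior on the standardized effect size.

Parametric and non-parametric results are always computed side by side; a
Lilliefors normality screen is reported but never gates which test runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats


@dataclass
class ConditionMatrix:
    """(participant x condition) summary values, complete cells required."""

    values: np.ndarray
    conditions: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (participant x condition)")
        if self.values.shape[1] != len(self.conditions):
            raise ValueError("condition labels must match the number of columns")
        if self.values.shape[1] < 2 or self.values.shape[0] < 3:
            raise ValueError("need >= 2 conditions and >= 3 participants")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed")

    def column(self, cond) -> np.ndarray:
        return self.values[:, list(self.conditions).index(cond)]


def condition_matrix_from_table(
    table: pd.DataFrame, value: str = "accuracy", by: str = "condition"
) -> ConditionMatrix:
    """Per-participant condition means from a trial-level behavior table."""
    pivot = table.pivot_table(index="participant", columns=by, values=value, aggfunc="mean")
    if pivot.isna().any().any():
        raise ValueError("missing participant x condition cells")
    return ConditionMatrix(pivot.to_numpy(), list(pivot.columns))


@dataclass
class OmnibusResult:
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    mauchly_chi2: float
    mauchly_p: float
    epsilon_gg: float
    p_corrected: float
    partial_eta_sq: float
    lilliefors_p: list | None = None


def rm_anova_gg(data: ConditionMatrix) -> OmnibusResult:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction.

    Sums of squares are decomposed into condition, subject and residual
    terms; epsilon_GG comes from the double-centered condition covariance
    matrix; Mauchly's W is computed on the (k-1) orthonormal contrasts of
    the conditions with its chi-square approximation.
    """
    Y = data.values
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = k - 1.0
    df_den = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den if df_den > 0 else np.nan
    F = ms_cond / ms_err if ms_err > 0 else 0.0 if ss_cond == 0 else np.inf
    p_unc = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0

    # Greenhouse-Geisser epsilon from the double-centered covariance
    S = np.cov(Y, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = (np.trace(Sc)) ** 2
    den = (k - 1) * np.sum(Sc**2)
    eps = float(num / den) if den > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    # Mauchly's test on orthonormal contrasts
    C = _orthonormal_contrasts(k)
    Sb = C @ S @ C.T
    detSb = np.linalg.det(Sb)
    trSb = np.trace(Sb)
    p_dim = k - 1
    if detSb <= 0 or trSb <= 0:
        W, chi2, p_mauchly = 0.0, np.inf, 0.0
    else:
        W = float(detSb / (trSb / p_dim) ** p_dim)
        d = 1.0 - (2.0 * p_dim**2 + p_dim + 2.0) / (6.0 * p_dim * (n - 1.0))
        chi2 = float(-(n - 1.0) * d * np.log(W))
        df_m = p_dim * (p_dim + 1.0) / 2.0 - 1.0
        p_mauchly = float(stats.chi2.sf(chi2, df_m)) if df_m > 0 else 1.0

    p_corr = (
        float(stats.f.sf(F, df_num * eps, df_den * eps)) if np.isfinite(F) else 0.0
    )
    eta = float(ss_cond / (ss_cond + ss_err)) if (ss_cond + ss_err) > 0 else 0.0
    lillie = _lilliefors_screen(Y)
    return OmnibusResult(
        F=float(F),
        df_num=df_num,
        df_den=df_den,
        p_uncorrected=p_unc,
        mauchly_chi2=chi2,
        mauchly_p=p_mauchly,
        epsilon_gg=eps,
        p_corrected=p_corr,
        partial_eta_sq=eta,
        lilliefors_p=lillie,
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    H = np.eye(k) - np.full((k, k), 1.0 / k)
    # eigenvectors of the centering matrix with eigenvalue 1
    vals, vecs = np.linalg.eigh(H)
    return vecs[:, vals > 0.5].T


def _lilliefors_screen(Y: np.ndarray) -> list:
    try:
        from statsmodels.stats.diagnostic import lilliefors

        return [float(lilliefors(Y[:, j])[1]) for j in range(Y.shape[1])]
    except Exception:
        return []


def friedman_kendall_w(data: ConditionMatrix):
    """Friedman chi-square with mid-rank ties + tie correction; W = chi2/(n(k-1))."""
    Y = data.values
    n, k = Y.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, Y)
    Rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)
    # tie correction: divide by 1 - sum(t^3 - t)/(n k (k^2 - 1))
    tie_sum = 0.0
    for row in Y:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += np.sum(counts**3 - counts)
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1.0))
    chi2 = chi2 / denom if denom > 0 else 0.0
    p = float(stats.chi2.sf(chi2, k - 1))
    w = float(chi2 / (n * (k - 1.0)))
    return float(chi2), p, w


@dataclass
class PairedResult:
    t: float
    df: int
    p: float
    d_av: float
    ci95: tuple
    mean_diff: float


def paired_t_dav(x, y, alternative: str = "two-sided") -> PairedResult:
    """Paired t-test with Cohen's d_av and a 95% CI on the mean difference.

    d_av divides the mean difference by the average of the two conditions'
    standard deviations. Zero-variance degenerate input follows the
    documented convention: t = 0 / p = 1 when the mean difference is 0,
    otherwise p = 0 with infinite t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    d = x - y
    n = len(d)
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if md == 0 else np.inf * np.sign(md)
        p = 1.0 if md == 0 else 0.0
        ci = (md, md)
    else:
        se = sd / np.sqrt(n)
        t = md / se
        if alternative == "two-sided":
            p = 2.0 * stats.t.sf(abs(t), n - 1)
        elif alternative == "greater":
            p = stats.t.sf(t, n - 1)
        else:
            p = stats.t.cdf(t, n - 1)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (md - tcrit * se, md + tcrit * se)
    s_av = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    d_av = float(md / s_av) if s_av > 0 else 0.0
    return PairedResult(
        t=float(t), df=n - 1, p=float(p), d_av=d_av,
        ci95=(float(ci[0]), float(ci[1])), mean_diff=float(md),
    )


@dataclass
class WilcoxonResult:
    W: float  # min of the signed-rank sums
    w_plus: float  # positive-rank sum
    z: float
    p: float
    r: float
    n_effective: int
    exact: bool


def wilcoxon_signed_rank(x, y, exact_threshold: int = 12) -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped. p is exact (full sign enumeration,
    two-sided, conditional on the observed ranks) for n <= exact_threshold,
    otherwise from the normal approximation with tie correction and a 0.5
    continuity correction. r = z / sqrt(n) uses the *original* sample size,
    matching the common reporting convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n_orig = len(x)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / sigma if sigma > 0 else 0.0
    if n <= exact_threshold:
        # enumerate all 2^n sign assignments of the observed ranks
        sums = np.zeros(1)
        for rk in ranks:
            sums = np.concatenate([sums, sums + rk])
        stat = min(w_plus, w_minus)
        counts_le = np.sum(np.minimum(sums, n * (n + 1) / 2.0 - sums) <= stat)
        p = float(min(1.0, counts_le / len(sums)))
        exact = True
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        exact = False
    return WilcoxonResult(
        W=float(W), w_plus=w_plus, z=float(z), p=p,
        r=float(z / np.sqrt(n_orig)), n_effective=n, exact=exact,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def jzs_bf_paired(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """Default (JZS) Bayes factor BF10 for a paired/one-sample t statistic.

    The alternative places a Cauchy(0, scale) prior on the standardized
    effect size delta; BF10 is the ratio of the marginal likelihood of t
    under that prior (noncentral-t likelihood integrated over delta) to the
    central-t likelihood under the point null.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    null_like = stats.t.pdf(t, df)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * np.sqrt(n)) * stats.cauchy.pdf(
            delta, 0.0, cauchy_scale
        )

    alt_like, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    return float(alt_like / null_like)


def pairwise_battery(
    data: ConditionMatrix, cauchy_scale: float = 0.707
) -> pd.DataFrame:
    """All pairwise contrasts with FDR-adjusted p-values and Bayes factors."""
    rows = []
    pairs = list(itertools.combinations(range(len(data.conditions)), 2))
    for i, j in pairs:
        x, y = data.values[:, i], data.values[:, j]
        t_res = paired_t_dav(x, y)
        w_res = wilcoxon_signed_rank(x, y)
        bf = jzs_bf_paired(t_res.t, len(x), cauchy_scale) if np.isfinite(t_res.t) else np.inf
        rows.append(
            {
                "contrast": f"{data.conditions[i]} vs {data.conditions[j]}",
                "t": t_res.t,
                "df": t_res.df,
                "p_raw": t_res.p,
                "d_av": t_res.d_av,
                "ci95_low": t_res.ci95[0],
                "ci95_high": t_res.ci95[1],
                "bf10": bf,
                "wilcoxon_W": w_res.W,
                "wilcoxon_w_plus": w_res.w_plus,
                "z": w_res.z,
                "wilcoxon_p_raw": w_res.p,
                "r": w_res.r,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p_raw"].to_numpy())
    df["wilcoxon_p_adj"] = bh_fdr(df["wilcoxon_p_raw"].to_numpy())
    return df
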