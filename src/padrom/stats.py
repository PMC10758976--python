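"""Repeated-measures inference for condition-wise ROM and survey data.

The central test is a one-way repeated-measures ANOVA across pad conditions
with Greenhouse-Geisser (GG) sphericity correction.  With ``n`` participants
and ``k`` conditions the within-subject decomposition is

    SS_total = SS_conditions + SS_subjects + SS_error
    F = (SS_conditions / (k-1)) / (SS_error / ((n-1)(k-1)))

and the GG epsilon is estimated from the double-centred sample covariance
``S*`` of the condition columns as ``eps = tr(S*)^2 / ((k-1) tr(S*^2))``,
bounded in ``[1/(k-1), 1]``.  The corrected p-value uses an F distribution
with ``(eps (k-1), eps (k-1)(n-1))`` degrees of freedom and is reported
unconditionally (no sphericity pre-test gate).  Effect size is partial
eta-squared, ``SS_cond / (SS_cond + SS_error)``.

Post-hoc "least significant difference" comparisons are uncorrected paired
t-tests, gated on a significant omnibus effect by the caller.  Survey scores
are treated as ordinal: Friedman test across pads, Wilcoxon signed-rank
pairwise (zero differences dropped, average ranks for ties, exact small-n
null distributions), and Spearman rank correlation for the comfort-ROM
relationship (exact permutation p for n <= 8).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "PosthocTable",
    "shapiro_wilk",
    "rm_anova_gg",
    "lsd_posthoc",
    "classify_eta_sq",
    "friedman_test",
    "wilcoxon_signed_rank",
    "spearman_corr",
    "classify_correlation",
    "rm_anova_type_i_error",
    "rm_anova_power",
]

ALPHA = 0.05  # study-wide significance level


def _as_matrix(data) -> tuple[np.ndarray, list]:
    """Coerce a participants x conditions table to ndarray + column labels."""
    if isinstance(data, pd.DataFrame):
        labels = list(data.columns)
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        labels = list(range(mat.shape[1])) if mat.ndim == 2 else []
    if mat.ndim != 2:
        raise ValueError("expected a 2-D participants x conditions matrix")
    if np.isnan(mat).any():
        raise ValueError("condition matrix has missing cells")
    return mat, labels


# ------------------------------------------------------------ normality


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one sample of ROM values (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("W undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------ RM-ANOVA


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA outcome for a condition matrix."""

    f_stat: float
    df_effect: float
    df_error: float
    p_value: float  # Greenhouse-Geisser corrected
    p_uncorrected: float
    gg_epsilon: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


def gg_epsilon(data) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    mat, _ = _as_matrix(data)
    n, k = mat.shape
    cov = np.cov(mat, rowvar=False, ddof=1)
    centering = np.eye(k) - np.full((k, k), 1.0 / k)
    sc = centering @ cov @ centering
    denom = (k - 1) * float(np.sum(sc * sc))
    if denom <= 0.0:
        return 1.0
    eps = float(np.trace(sc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data) -> RmAnovaResult:
    """One-way RM-ANOVA with Greenhouse-Geisser correction and eta_p^2."""
    mat, _ = _as_matrix(data)
    n, k = mat.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 participants")
    grand = mat.mean()
    cond_means = mat.mean(axis=0)
    subj_means = mat.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((mat - grand) ** 2))
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    eps = gg_epsilon(mat)
    if ss_err <= 1e-300:
        if ss_cond <= 1e-300:  # identical columns: no effect, no error
            return RmAnovaResult(0.0, df1, df2, 1.0, 1.0, eps, 0.0, ss_cond, ss_err)
        f = np.inf
    else:
        f = (ss_cond / df1) / (ss_err / df2)
    p_unc = float(sps.f.sf(f, df1, df2))
    p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return RmAnovaResult(float(f), df1, df2, p_gg, p_unc, eps, float(eta), ss_cond, ss_err)


# ------------------------------------------------------------ post hoc


@dataclass(frozen=True)
class PosthocTable:
    """Pairwise paired-t (LSD) outcomes: symmetric p, antisymmetric mean diff."""

    p: pd.DataFrame
    t: pd.DataFrame
    mean_diff: pd.DataFrame

    def significant_pairs(self, alpha: float = ALPHA) -> list[tuple]:
        out = []
        cols = list(self.p.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if self.p.loc[a, b] < alpha:
                    out.append((a, b))
        return out


def lsd_posthoc(data) -> PosthocTable:
    """Uncorrected pairwise paired t-tests over all condition pairs."""
    mat, labels = _as_matrix(data)
    n, k = mat.shape
    if n < 2:
        raise ValueError("need at least 2 participants for paired comparisons")
    p = np.full((k, k), np.nan)
    t = np.full((k, k), np.nan)
    md = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        diff = mat[:, i] - mat[:, j]
        md[i, j] = float(diff.mean())
        md[j, i] = -md[i, j]
        if np.allclose(diff, diff[0]) and abs(diff[0]) < 1e-12:
            t_ij, p_ij = 0.0, 1.0
        else:
            res = sps.ttest_rel(mat[:, i], mat[:, j])
            t_ij, p_ij = float(res.statistic), float(res.pvalue)
        t[i, j], t[j, i] = t_ij, -t_ij
        p[i, j] = p[j, i] = p_ij
    frames = [pd.DataFrame(m, index=labels, columns=labels) for m in (p, t, md)]
    return PosthocTable(*frames)


# ------------------------------------------------------------ effect bands


def classify_eta_sq(eta: float) -> str:
    """Band a partial eta-squared: below_small / small / medium / large."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta_p^2 must lie in [0, 1], got {eta}")
    if eta < 0.01:
        return "below_small"
    if eta < 0.06:
        return "small"
    if eta < 0.14:
        return "medium"
    return "large"


def classify_correlation(r: float) -> str:
    """Band |r|: negligible (<0.1) / low / moderate / high (>=0.5)."""
    if abs(r) > 1.0:
        raise ValueError(f"|r| must not exceed 1, got {r}")
    a = abs(r)
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "low"
    if a < 0.5:
        return "moderate"
    return "high"


# ------------------------------------------------------------ nonparametric


def friedman_test(scores) -> tuple[float, float]:
    """Friedman chi-square over a complete participants x pads ordinal matrix.

    Average ranks for ties; a fully tied matrix yields statistic 0, p 1.
    """
    mat, _ = _as_matrix(scores)
    n, k = mat.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    ranks = np.apply_along_axis(sps.rankdata, 1, mat)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums**2))
    # tie correction over within-row tie groups
    tie_term = 0.0
    for row in mat:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0.0:
        return 0.0, 1.0
    chi_sq = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / correction
    chi_sq = max(chi_sq, 0.0)
    return float(chi_sq), float(sps.chi2.sf(chi_sq, k - 1))


def _wilcoxon_exact_enum(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p over all 2^n sign assignments of the observed ranks."""
    n = len(ranks)
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    w_all = signs @ ranks
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    a, b, exact_max_n: int = 25, enum_max_n: int = 14
) -> tuple[float, float]:
    """Wilcoxon signed-rank W (sum of positive ranks) and two-sided p.

    Zero differences are dropped; ties of |difference| receive average ranks.
    The null distribution is exact for small samples (the classical tie-free
    distribution up to ``exact_max_n``; full 2^n enumeration of the observed
    tied ranks up to ``enum_max_n``) and a normal approximation beyond.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: no information")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if not has_ties and n <= exact_max_n:
        res = sps.wilcoxon(x, y, zero_method="wilcox", method="exact")
        return w, float(res.pvalue)
    if n <= enum_max_n:
        return w, _wilcoxon_exact_enum(ranks, w)
    res = sps.wilcoxon(x, y, zero_method="wilcox", method="approx", correction=False)
    return w, float(res.pvalue)


def spearman_corr(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of average ranks) and two-sided p.

    p is exact (all n! rank permutations) for n <= ``exact_max_n``, otherwise
    the usual t approximation with n-2 degrees of freedom.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D samples of equal length")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ValueError("correlation undefined for a constant input vector")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if 1.0 - abs(rho) < 1e-12:  # snap float noise at the boundary
        rho = 1.0 if rho > 0 else -1.0
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt(np.sum(rx_c**2) * np.sum(perms_c**2, axis=1))
        rhos = (perms_c @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(t), n - 2))


# ------------------------------------------------------------ calibration


def rm_anova_type_i_error(
    n: int = 9,
    k: int = 6,
    n_sims: int = 2000,
    alpha: float = ALPHA,
    seed: int = 0,
    subject_sd: float = 8.0,
    resid_sd: float = 3.0,
) -> float:
    """Empirical rejection rate of the GG-corrected test under the null.

    Data are simulated as subject random effect + spherical Gaussian noise
    with no condition effect.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        subj = rng.normal(0.0, subject_sd, size=(n, 1))
        y = subj + rng.normal(0.0, resid_sd, size=(n, k))
        if rm_anova_gg(y).p_value < alpha:
            rejections += 1
    return rejections / n_sims


def rm_anova_power(
    condition_means,
    n: int = 9,
    n_sims: int = 500,
    alpha: float = ALPHA,
    seed: int = 0,
    subject_sd: float = 8.0,
    resid_sd: float = 3.0,
) -> float:
    """Empirical power of the GG-corrected test at a fixed condition profile."""
    means = np.asarray(condition_means, dtype=float)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        subj = rng.normal(0.0, subject_sd, size=(n, 1))
        y = means[None, :] + subj + rng.normal(0.0, resid_sd, size=(n, len(means)))
        if rm_anova_gg(y).p_value < alpha:
            rejections += 1
    return rejections / n_sims
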