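"""Scoring functions for kinase activity inference.

Each scorer turns the measured levels of a kinase's target sites (and,
for competitive methods, the full site background) into a single
activity score for one experiment or sample. The catalog covers simple
location statistics (mean, median, sum, upper quantile), background-
standardized means (KSEA, the RoKAI z-score, KARP), rank tests
(Kolmogorov-Smirnov, Mann-Whitney U), over-representation tests
(Fisher, chi-square), linear models (univariate, multivariate, ridge),
running-sum enrichment scores (weighted GSEA-style ES, its
rank-normalized / permutation-normalized variants, a two-tail rank
enrichment), a permutation-normalized mean, a PCA score, and a
number-of-measured-targets control.

Conventions shared by all scorers:

* sample standard deviations use the n-1 denominator;
* rank tests report ``-ln(p)``, over-representation tests ``-log10(p)``,
  each multiplied by the sign of the target-vs-background location
  shift so that undirected tests still carry a direction (the
  benchmarks multiply scores by the perturbation sign);
* degenerate inputs (zero background spread, empty targets, no residual
  degrees of freedom) yield ``nan`` rather than raising.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "score_location",
    "score_ksea",
    "score_zscore_rokai",
    "score_karp",
    "score_rank_test",
    "score_overrep",
    "score_ulm",
    "score_mlm",
    "score_lm_rokai",
    "fgsea_running_sum",
    "score_fgsea_es",
    "score_norm_mean",
    "score_ptmsea",
    "score_viper",
    "score_pca",
]

_EPS_P = np.finfo(float).tiny


def _as1d(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


# ---------------------------------------------------------------------------
# location statistics
# ---------------------------------------------------------------------------


def score_location(values_targets, stat: str = "mean") -> float:
    """Elementary location statistic over the target values only.

    ``uq`` is the 0.75 quantile with Hyndman-Fan type-7 (linear
    interpolation) convention, i.e. the value below which 75% of the
    target levels fall.
    """
    v = _as1d(values_targets)
    if v.size == 0:
        return np.nan
    if stat == "mean":
        return float(np.mean(v))
    if stat == "median":
        return float(np.median(v))
    if stat == "sum":
        return float(np.sum(v))
    if stat == "uq":
        return float(np.quantile(v, 0.75, method="linear"))
    raise ValueError(f"unknown location statistic {stat!r}")


# ---------------------------------------------------------------------------
# background-standardized means
# ---------------------------------------------------------------------------


def score_ksea(values_targets, values_all) -> float:
    """KSEA z-score.

    z = (mean(targets) - mean(all)) * sqrt(m) / sd(all), where m is the
    number of measured targets and sd uses the n-1 denominator over all
    measured sites of the experiment.
    """
    t = _as1d(values_targets)
    a = _as1d(values_all)
    if t.size == 0 or a.size < 2:
        return np.nan
    sd = float(np.std(a, ddof=1))
    if sd == 0:
        return np.nan
    return float((t.mean() - a.mean()) * np.sqrt(t.size) / sd)


def score_zscore_rokai(values_targets, values_all) -> float:
    """RoKAI-style z-score: mean(targets) * sqrt(m) / sd(all).

    Unlike KSEA the background mean is not subtracted; on fold-change
    data centered near zero the two nearly coincide, but this variant
    is shift-sensitive.
    """
    t = _as1d(values_targets)
    a = _as1d(values_all)
    if t.size == 0 or a.size < 2:
        return np.nan
    sd = float(np.std(a, ddof=1))
    if sd == 0:
        return np.nan
    return float(t.mean() * np.sqrt(t.size) / sd)


def score_karp(values_targets, values_all, t_known: int, scale: float = 1.0) -> float:
    """KARP K-score: (sum targets / sum all) * sqrt(m / t).

    ``t_known`` is the total number of known library targets of the
    kinase; the sqrt factor penalizes kinases for which only a small
    fraction of known targets was measured. ``scale`` is an optional
    multiplicative constant (the original formulation used 1e6; ranks
    are unaffected).
    """
    t = _as1d(values_targets)
    a = _as1d(values_all)
    if t.size == 0 or a.size == 0 or t_known < 1:
        return np.nan
    denom = float(np.sum(a))
    if denom == 0:
        return np.nan
    return float(scale * (np.sum(t) / denom) * np.sqrt(t.size / t_known))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def score_rank_test(values_targets, values_nontargets, test: str = "mwu") -> float:
    """Signed -ln(p) of a two-sample rank test of targets vs non-targets.

    ``test`` is ``ks`` (two-sample Kolmogorov-Smirnov) or ``mwu``
    (two-sided Mann-Whitney U with midrank tie handling). The test
    itself is undirected, so the score is given the sign of
    mean(targets) - mean(non-targets).
    """
    t = _as1d(values_targets)
    n = _as1d(values_nontargets)
    if t.size == 0 or n.size == 0:
        return np.nan
    if test == "ks":
        p = float(stats.ks_2samp(t, n, method="auto").pvalue)
    elif test == "mwu":
        p = float(stats.mannwhitneyu(t, n, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown rank test {test!r}")
    if p <= 0.0:
        warnings.warn("rank-test p-value underflow; capping")
        p = _EPS_P
    sign = np.sign(t.mean() - n.mean())
    if sign == 0:
        sign = 1.0
    return float(sign * -np.log(min(p, 1.0)))


# ---------------------------------------------------------------------------
# over-representation tests
# ---------------------------------------------------------------------------


def score_overrep(
    values_targets, values_nontargets, test: str = "fisher", tau: float = 1.0
) -> float:
    """Signed -log10(p) of a 2x2 over-representation test.

    Sites are called deregulated when ``|value| >= tau`` (the
    conventional cutoff of 1 on log fold-changes). The contingency
    table crosses target/non-target with deregulated/not. ``fisher``
    uses the one-sided (enrichment) hypergeometric tail; ``chisq`` the
    Pearson chi-square without continuity correction and returns nan
    when any expected cell falls below 1. The sign is that of the mean
    of the deregulated target values.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = _as1d(values_targets)
    n = _as1d(values_nontargets)
    if t.size == 0 or n.size == 0:
        return np.nan
    dt = np.abs(t) >= tau
    dn = np.abs(n) >= tau
    a, b = int(dt.sum()), int((~dt).sum())
    c, d = int(dn.sum()), int((~dn).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    if a + c == 0:  # no deregulated sites anywhere
        return 0.0
    if test == "fisher":
        p = float(stats.fisher_exact(table, alternative="greater")[1])
    elif test == "chisq":
        expected = stats.contingency.expected_freq(table)
        if np.any(expected < 1):
            warnings.warn("chi-square expected cell < 1; score set to nan")
            return np.nan
        p = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        raise ValueError(f"unknown over-representation test {test!r}")
    if p <= 0.0:
        warnings.warn("over-representation p-value underflow; capping")
        p = _EPS_P
    sign = np.sign(t[dt].mean()) if a > 0 else 1.0
    if sign == 0:
        sign = 1.0
    return float(sign * -np.log10(min(p, 1.0)))


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


def _ols_t_stats(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t-statistics of all coefficients of an OLS fit (X includes intercept)."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        return np.full(p, np.nan)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    s2 = sse / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t[~np.isfinite(t)] = np.nan
    return t


def score_ulm(column_values, membership) -> float:
    """Univariate linear model: t-statistic of the target-membership slope.

    Ordinary least squares of all site values on a 0/1 membership
    indicator plus intercept; the slope's t-value is the activity.
    """
    y = _as1d(column_values)
    x = np.asarray(membership, dtype=float).ravel()
    if y.size < 3 or y.size != x.size:
        return np.nan
    if x.sum() == 0 or x.sum() == x.size:
        return np.nan
    X = np.column_stack([np.ones_like(x), x])
    return float(_ols_t_stats(X, y)[1])


def score_mlm(
    column_values, design: np.ndarray, kinases: Sequence[str]
) -> Tuple[np.ndarray, list]:
    """Multivariate linear model: joint OLS on the all-kinase 0/1 design.

    Site values are regressed simultaneously on every kinase's
    membership column plus an intercept; each coefficient's t-statistic
    is that kinase's activity. Duplicate membership columns (kinases
    with identical measured target sets) are dropped with a warning and
    reported as nan.

    Returns
    -------
    (t_values, kept_kinases)
        ``t_values`` is aligned with ``kinases`` (nan for dropped
        columns); ``kept_kinases`` lists the columns actually fitted.
    """
    y = _as1d(column_values)
    A = np.asarray(design, dtype=float)
    n_kin = A.shape[1]
    out = np.full(n_kin, np.nan)

    # drop exact duplicate columns (collinear by construction)
    keep: list = []
    seen = {}
    for j in range(n_kin):
        key = A[:, j].tobytes()
        if key in seen:
            warnings.warn(
                f"mlm design: kinase {kinases[j]!r} duplicates {kinases[seen[key]]!r}; dropped"
            )
            continue
        seen[key] = j
        keep.append(j)
    if not keep:
        return out, []
    Ak = A[:, keep]
    if y.size <= Ak.shape[1] + 1:
        return out, []
    X = np.column_stack([np.ones(y.size), Ak])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("mlm design rank-deficient after duplicate removal")
    t = _ols_t_stats(X, y)[1:]
    for idx, j in enumerate(keep):
        out[j] = t[idx]
    return out, [kinases[j] for j in keep]


def score_lm_rokai(column_values, design: np.ndarray, lam: float = 0.1) -> np.ndarray:
    """RoKAI-style ridge linear model.

    Each site value is modeled as the sum of the activities of its
    linked kinases; activities solve the ridge-regularized least
    squares system (A'A + lam*I) x = A'y, without an intercept (fold
    changes and centered intensities are already near zero, so a
    single kinase's fit reduces to the mean of its target values).
    """
    y = _as1d(column_values)
    A = np.asarray(design, dtype=float)
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    AtA = A.T @ A
    if lam == 0:
        if np.linalg.matrix_rank(AtA) < AtA.shape[0]:
            raise np.linalg.LinAlgError(
                "singular normal equations at lam=0; use a positive ridge penalty"
            )
        return np.linalg.solve(AtA, A.T @ y)
    return np.linalg.solve(AtA + lam * np.eye(AtA.shape[0]), A.T @ y)


# ---------------------------------------------------------------------------
# running-sum enrichment
# ---------------------------------------------------------------------------


def fgsea_running_sum(values, in_set) -> np.ndarray:
    """Weighted Kolmogorov running sum over values sorted descending.

    In-set steps increase the sum by |value| / sum(|in-set values|);
    out-of-set steps decrease it by 1/(N-m). The returned array holds
    the running sum after each of the N positions.
    """
    v = _as1d(values)
    mask = np.asarray(in_set, dtype=bool).ravel()
    order = np.argsort(-v, kind="stable")
    v_sorted = v[order]
    m_sorted = mask[order]
    m = int(mask.sum())
    N = v.size
    if m == 0 or m == N:
        raise ValueError("target set must be a proper non-empty subset of the sites")
    w = np.abs(v_sorted)
    wsum = w[m_sorted].sum()
    steps = np.where(
        m_sorted,
        (w / wsum) if wsum > 0 else (1.0 / m),
        -1.0 / (N - m),
    )
    if wsum == 0:  # all in-set values zero: fall back to unweighted increments
        steps = np.where(m_sorted, 1.0 / m, -1.0 / (N - m))
    return np.cumsum(steps)


def score_fgsea_es(values, in_set) -> float:
    """Enrichment score: the running sum's signed maximal deviation from zero."""
    try:
        rs = fgsea_running_sum(values, in_set)
    except ValueError:
        return np.nan
    i = int(np.argmax(np.abs(rs)))
    return float(rs[i])


def score_norm_mean(values_targets, values_all, n_perm: int = 1000, rng=None) -> float:
    """Permutation-normalized mean.

    The target mean is standardized against a null distribution of
    means of same-size random site draws (without replacement) from the
    experiment: (mean_targets - mean(null)) / sd(null).
    """
    t = _as1d(values_targets)
    a = _as1d(values_all)
    if t.size == 0 or a.size < 2 or t.size > a.size:
        return np.nan
    rng = np.random.default_rng(rng)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rng.choice(a, size=t.size, replace=False).mean()
    sd = null.std(ddof=1)
    if sd == 0:
        return np.nan
    return float((t.mean() - null.mean()) / sd)


def score_ptmsea(values, in_set, n_perm: int = 1000, rng=None) -> float:
    """Rank-based normalized enrichment score.

    The running-sum enrichment score is computed on rank-normalized
    values (midranks centered at zero) and normalized into an NES by
    dividing by the mean |ES| of same-signed null scores from random
    target-set draws.
    """
    v = _as1d(values)
    mask = np.asarray(in_set, dtype=bool).ravel()
    m = int(mask.sum())
    if m == 0 or m == v.size:
        return np.nan
    ranks = stats.rankdata(v) - (v.size + 1) / 2.0
    es = score_fgsea_es(ranks, mask)
    if not np.isfinite(es):
        return np.nan
    rng = np.random.default_rng(rng)
    null = np.empty(n_perm)
    idx = np.arange(v.size)
    for i in range(n_perm):
        pick = rng.choice(idx, size=m, replace=False)
        null_mask = np.zeros(v.size, dtype=bool)
        null_mask[pick] = True
        null[i] = score_fgsea_es(ranks, null_mask)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(null))
    if denom == 0:
        return np.nan
    return float(es / denom)


def score_viper(values, in_set, n_perm: int = 1000, rng=None) -> float:
    """Two-tail analytic-rank enrichment (simplified VIPER-style NES).

    Site values are converted to normal scores through their midrank
    quantiles; the kinase statistic is the mean normal score of its
    targets, standardized against a permutation null of random
    same-size target sets. This is a two-tail rank-enrichment
    approximation and does not model the three-tail mode-of-regulation
    machinery of the full method.
    """
    v = _as1d(values)
    mask = np.asarray(in_set, dtype=bool).ravel()
    m = int(mask.sum())
    if m == 0 or m >= v.size:
        return np.nan
    q = (stats.rankdata(v) - 0.5) / v.size
    z = stats.norm.ppf(q)
    es = z[mask].mean()
    rng = np.random.default_rng(rng)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rng.choice(z, size=m, replace=False).mean()
    sd = null.std(ddof=1)
    if sd == 0:
        return np.nan
    return float((es - null.mean()) / sd)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def score_pca(target_block: np.ndarray) -> Tuple[np.ndarray, float]:
    """PCA across samples on a kinase's target-site block.

    ``target_block`` is (target sites x columns) with no missing
    values. Columns play the role of observations and sites of
    variables (no scaling). Returns the per-column PC1 coordinates,
    sign-oriented to correlate positively with the per-column target
    means, together with PC1's variance-explained fraction.
    """
    B = np.asarray(target_block, dtype=float)
    if B.ndim != 2 or B.shape[1] < 2:
        return np.full(B.shape[1] if B.ndim == 2 else 0, np.nan), np.nan
    X = B.T  # columns = observations
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        return np.full(B.shape[1], np.nan), np.nan
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    col_means = B.mean(axis=0)
    orient = np.sign(np.corrcoef(scores, col_means)[0, 1]) if np.std(col_means) > 0 else 1.0
    if not np.isfinite(orient) or orient == 0:
        orient = 1.0
    return scores * orient, var_explained
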