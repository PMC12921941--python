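"""Nonparametric cohort statistics implemented from first principles.

The severity-group battery used in the analysis: Kruskal–Wallis omnibus test
(tie-corrected), Dunn pairwise posthoc z-tests with Holm step-down adjustment,
Cliff's delta effect size with conventional magnitude bands, Spearman rank
correlation with a t-approximation p-value, percentile-bootstrap confidence
intervals, and exploratory PCA of the standardized clinical feature set.

These routines are implemented here rather than delegated so that the exact
conventions (tie handling, degrees of freedom, step-down order, interpolation)
are pinned by the test suite against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KruskalResult",
    "PCAResult",
    "rankdata_average",
    "kruskal_wallis",
    "dunn_posthoc_holm",
    "holm_adjust",
    "cliffs_delta",
    "spearman",
    "bootstrap_ci",
    "pca_explore",
    "CLIFF_BANDS",
]

# Conventional |delta| cutoffs: negligible < 0.147 <= small < 0.33 <= medium < 0.474 <= large.
CLIFF_BANDS = (0.147, 0.33, 0.474)


def rankdata_average(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _as_groups(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        groups = list(groups.values())
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in out:
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    return out


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@dataclass
class KruskalResult:
    H: float
    p: float
    df: int
    status: str = "ok"  # "degenerate" when all pooled values are identical


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal–Wallis H test from pooled average ranks with tie correction.

    H = [12 / (N(N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2] / C, where
    C = 1 - sum(t^3 - t) / (N^3 - N); p from chi-square with g-1 df.
    When every pooled value is identical the tie-correction divisor is zero
    and the statistic is undefined: reported as NaN with status "degenerate".
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group")
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least three observations in total")
    df = len(gs) - 1

    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction == 0.0:
        return KruskalResult(H=float("nan"), p=float("nan"), df=df, status="degenerate")

    ranks = rankdata_average(pooled)
    grand_mean = (n_total + 1) / 2.0
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - grand_mean) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    h /= correction
    p = float(sps.chi2.sf(h, df))
    return KruskalResult(H=float(h), p=p, df=df)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running_max = max(running_max, val)
        adjusted[idx] = min(running_max, 1.0)
    return adjusted


def dunn_posthoc_holm(groups, labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn pairwise z-tests on pooled mean ranks, Holm-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with tie term T = sum(t^3 - t); two-sided normal p-values.  When the
    variance term degenerates (all pooled values identical), z = 0, p = 1.
    """
    gs = _as_groups(groups)
    if isinstance(groups, dict) and labels is None:
        labels = list(groups.keys())
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("empty group")

    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = rankdata_average(pooled)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)

    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            if var_base <= 0.0:
                z = 0.0
            else:
                se = np.sqrt(var_base * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
                z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            rows.append({"group1": labels[i], "group2": labels[j], "z": float(z), "p_raw": p_raw})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    return table


def cliffs_delta(a, b) -> tuple[float, str]:
    """Cliff's delta: [#(a > b) - #(a < b)] / (|a| |b|) over all cross pairs,
    with the conventional magnitude band."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    diff = a[:, None] - b[None, :]
    delta = float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(a) * len(b)))
    mag = abs(delta)
    if mag < CLIFF_BANDS[0]:
        band = "negligible"
    elif mag < CLIFF_BANDS[1]:
        band = "small"
    elif mag < CLIFF_BANDS[2]:
        band = "medium"
    else:
        band = "large"
    return delta, band


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p via
    the t-approximation with n-2 df.  Returns (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    rx = rankdata_average(x)
    ry = rankdata_average(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if n <= 2:
        return rho, float("nan")
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p


def bootstrap_ci(
    values, statistic=np.mean, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval for a statistic."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    stats_boot = np.empty(n_boot)
    for i in range(n_boot):
        resample = x[rng.integers(0, len(x), size=len(x))]
        s = float(statistic(resample))
        if not np.isfinite(s):
            raise ValueError(f"statistic returned non-finite value on resample {i}")
        stats_boot[i] = s
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats_boot, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class PCAResult:
    """Exploratory PCA of a standardized matrix.

    ``loadings`` columns are unit-norm principal axes (sign-fixed so the
    largest-|loading| element of each is positive); ``scores`` are the
    per-patient projections; ``explained_fractions`` sum to 1 over all
    components.
    """

    loadings: np.ndarray
    explained_fractions: np.ndarray
    scores: np.ndarray
    mean: np.ndarray
    columns: list[str] = field(default_factory=list)


def pca_explore(matrix, columns: list[str] | None = None) -> PCAResult:
    """Eigendecomposition of the covariance of standardized columns."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if np.isnan(X).any():
        raise ValueError("input contains NaNs")
    n, d = X.shape
    if n < 2 or d < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # Sign convention: largest-|loading| element of each component positive.
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = Xc @ eigvecs
    return PCAResult(
        loadings=eigvecs,
        explained_fractions=fractions,
        scores=scores,
        mean=mean,
        columns=list(columns) if columns is not None else [],
    )
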