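"""Univariate and discriminant statistics for the cross-sectional and
longitudinal analyses.

Rank-based two-group and k-group comparisons (Mann-Whitney U,
Kruskal-Wallis with Dunn's post-hoc z tests), partial Spearman correlation
by rank residualization, the paired Wilcoxon signed-rank comparison for
two-wave data, and a two-class Fisher linear discriminant with
cross-validated allocation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold
from statsmodels.stats.multitest import multipletests

DUNN_ADJUSTMENTS = ("none", "bonferroni", "holm")


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: tuple
    effect: float = float("nan")  # signed summary (e.g. median difference, rho)

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _clean(x):
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact enumeration for small untied samples, tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    effect = float(np.median(x) - np.median(y))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mann-whitney",
        n=(len(x), len(y)),
        effect=effect,
    )


def kruskal_dunn(groups, adjust: str = "holm"):
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc z tests.

    Parameters
    ----------
    groups : sequence of samples (>= 2)
    adjust : p-adjustment for the pairwise matrix ('none'|'bonferroni'|'holm')

    Returns
    -------
    (omnibus, pairwise) : TestResult and a tidy DataFrame with one row per
        pair (i, j, z, p_raw, p_adj).

    Dunn's z for pair (i, j) compares mean ranks over the pooled sample:
    ``z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj))`` with tie
    correction ``T = sum(t^3 - t) / (12 (N - 1))``.
    """
    if adjust not in DUNN_ADJUSTMENTS:
        raise ValueError(f"adjust must be one of {DUNN_ADJUSTMENTS}")
    samples = [_clean(g) for g in groups]
    if len(samples) < 2:
        raise ValueError("kruskal_dunn requires k >= 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_dunn: empty group")
    hstat, pval = stats.kruskal(*samples)
    omnibus = TestResult(
        statistic=float(hstat),
        p_value=float(pval),
        method="kruskal-wallis",
        n=tuple(len(s) for s in samples),
    )

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    idx = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = [ranks[idx[i]: idx[i + 1]].mean() for i in range(len(samples))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(samples)), 2):
        se = np.sqrt(base_var * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p_raw": min(p_raw, 1.0)})
    pairwise = pd.DataFrame(rows)
    if adjust == "none" or pairwise.empty:
        pairwise["p_adj"] = pairwise.get("p_raw")
    else:
        pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=adjust)[1]
    return omnibus, pairwise


def partial_spearman(x, y, covariates=None) -> TestResult:
    """Partial Spearman correlation controlling for confounders.

    All variables are rank-transformed, x and y residualized on the
    covariates (plus intercept) by least squares, and the Pearson
    correlation of the residuals is reported with a t-approximation p-value
    on ``n - 2 - k`` degrees of freedom. With no covariates this reduces to
    the ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        z = np.empty((len(x), 0))
    else:
        z = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z).all(axis=1)
    x, y, z = x[mask], y[mask], z[mask]
    n, k = len(x), z.shape[1]
    if n < k + 3:
        raise ValueError(f"partial_spearman needs >= covariates+3 complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("partial_spearman: constant variable, correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] + [stats.rankdata(z[:, i]) for i in range(k)])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    dof = n - 2 - k
    tstat = rho * np.sqrt(dof / max(1e-300, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return TestResult(
        statistic=rho, p_value=min(p, 1.0), method="partial-spearman", n=(n,), effect=rho
    )


def wilcoxon_paired(before, after) -> tuple[TestResult, dict]:
    """Paired Wilcoxon signed-rank test on (after - before) differences.

    Zero differences are dropped (Wilcoxon convention). Returns the test
    plus a summary dict with mean/median difference and counts. With all
    differences zero the test is undefined (NaN statistic/p) but the
    summary is still reported.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before and after must be paired (equal length)")
    mask = np.isfinite(a) & np.isfinite(b)
    d = a[mask] - b[mask]
    summary = {
        "n_pairs": int(len(d)),
        "n_nonzero": int((d != 0).sum()),
        "mean_diff": float(d.mean()) if len(d) else float("nan"),
        "median_diff": float(np.median(d)) if len(d) else float("nan"),
    }
    if summary["n_nonzero"] == 0:
        result = TestResult(
            statistic=float("nan"),
            p_value=float("nan"),
            method="wilcoxon-signed-rank",
            n=(len(d),),
            effect=summary["mean_diff"],
        )
        return result, summary
    res = stats.wilcoxon(d[d != 0], zero_method="wilcox", method="auto")
    result = TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon-signed-rank",
        n=(len(d),),
        effect=summary["mean_diff"],
    )
    return result, summary


# ---------------------------------------------------------------------------
# Two-class Fisher discriminant

@dataclass
class DiscriminantResult:
    """Fisher discriminant separation of two groups."""

    weights: np.ndarray
    threshold: float
    scores: np.ndarray
    separation: TestResult
    accuracy_mean: float
    accuracy_sd: float
    confusion: np.ndarray  # 2x2, rows true (low, high), cols predicted
    classes: tuple = ("low", "high")


def _fisher_weights(X0, X1, ridge_factor: float):
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    s0 = np.cov(X0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((X0.shape[1],) * 2)
    s1 = np.cov(X1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((X1.shape[1],) * 2)
    pooled = ((n0 - 1) * s0 + (n1 - 1) * s1) / max(1, n0 + n1 - 2)
    pooled = np.atleast_2d(pooled)
    ridge = ridge_factor * np.mean(np.diag(pooled))
    pooled = pooled + ridge * np.eye(pooled.shape[0])
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"pooled within-class covariance singular even after ridge: {err}"
        ) from err
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return w, threshold


def lda_two_class(
    features,
    labels,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
    ridge_factor: float = 1e-6,
) -> DiscriminantResult:
    """Fisher linear discriminant between two groups with CV accuracy.

    The projection uses the pooled within-class covariance with a small
    ridge (``ridge_factor * mean diagonal``) for conditioning. Discriminant
    scores fitted on the full data feed a Mann-Whitney separation test;
    allocation accuracy is mean +/- SD over repeated stratified
    cross-validation, with the confusion matrix aggregated over held-out
    folds (averaged across repeats, so its entries sum to n).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    mask = np.isfinite(X).all(axis=1) & pd.notna(y)
    X, y = X[mask], y[mask]
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"lda_two_class requires exactly 2 classes, got {classes}")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("lda_two_class: constant feature")
    y01 = (y == classes[1]).astype(int)
    if y01.sum() < 2 or (1 - y01).sum() < 2:
        raise ValueError("lda_two_class requires >= 2 members per class")

    w, threshold = _fisher_weights(X[y01 == 0], X[y01 == 1], ridge_factor)
    scores = X @ w
    separation = mann_whitney(scores[y01 == 0], scores[y01 == 1])

    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    accs_by_repeat = np.zeros(cv_repeats)
    confusion = np.zeros((2, 2))
    correct_by_repeat = np.zeros(cv_repeats)
    for split_i, (train, test) in enumerate(cv.split(X, y01)):
        repeat = split_i // cv_folds
        w_cv, thr_cv = _fisher_weights(
            X[train][y01[train] == 0], X[train][y01[train] == 1], ridge_factor
        )
        pred = (X[test] @ w_cv > thr_cv).astype(int)
        correct_by_repeat[repeat] += (pred == y01[test]).sum()
        for t, p in zip(y01[test], pred):
            confusion[t, p] += 1.0
    n = len(y01)
    accs_by_repeat = correct_by_repeat / n
    confusion /= cv_repeats
    return DiscriminantResult(
        weights=w,
        threshold=threshold,
        scores=scores,
        separation=separation,
        accuracy_mean=float(accs_by_repeat.mean()),
        accuracy_sd=float(accs_by_repeat.std(ddof=1)) if cv_repeats > 1 else 0.0,
        confusion=confusion,
        classes=classes,
    )
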