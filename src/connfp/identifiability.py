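"""Whole-brain fingerprint metrics from the identifiability matrix.

The identifiability matrix M is N x N with M[i, j] the Pearson correlation
between subject i's *test* FC edge vector and subject j's *retest* edge
vector.  Its diagonal carries each subject's self-similarity (ISelf); the
off-diagonal entries feed the between-subject similarity::

    IOthers(s) = ( sum_{i != s} M[s, i] + sum_{i != s} M[i, s] ) / (2N - 2)

IDiff = mean(ISelf) - mean(IOthers) is the group-level fingerprint strength,
and the success rate is the percentage of subjects whose self-similarity
wins the identification, under either of two rules:

* ``"max"`` (default): M[s, s] strictly exceeds every off-diagonal entry of
  row s and column s — the classic identification procedure;
* ``"mean"``: ISelf(s) strictly exceeds IOthers(s).

Ties count as identification failures under both rules.  Statistical
inference uses permutation schemes throughout: a shuffled-matrix null for
IDiff / success rate, and a Freedman-Lane permutation ANOVA for group
effects on per-subject metrics with nuisance covariates.  All permutation
p-values use the add-one correction p = (1 + #extreme) / (B + 1), so p is
never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class IdentifiabilityMetrics:
    iself: np.ndarray
    iothers: np.ndarray
    idiff: float
    success_rate: float  # percent, in [0, 100]
    success_rule: str
    n_subjects: int
    p_idiff: float | None = None
    p_success: float | None = None

    def to_dict(self) -> dict:
        return {
            "iself": self.iself.tolist(),
            "iothers": self.iothers.tolist(),
            "idiff": self.idiff,
            "success_rate": self.success_rate,
            "success_rule": self.success_rule,
            "n_subjects": self.n_subjects,
            "p_idiff": self.p_idiff,
            "p_success": self.p_success,
        }


@dataclass
class PermutationNull:
    p_idiff: float
    p_success: float
    null_idiff: np.ndarray
    null_success: np.ndarray
    n_permutations: int


@dataclass
class PairedTestResult:
    chosen: str  # "t-test" or "wilcoxon"
    statistic: float
    p_value: float
    shapiro_p: float
    t_statistic: float
    t_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float


@dataclass
class GroupANOVAResult:
    f_statistic: float
    p_value: float
    df_group: int
    df_residual: int
    n_permutations: int


# ---------------------------------------------------------------------------


def _standardize_rows(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    if (norms == 0).any():
        bad = np.flatnonzero(norms.ravel() == 0)
        raise ValueError(f"constant {what} edge vector(s) at row(s) {bad.tolist()}")
    return centered / norms


def build_identifiability_matrix(
    test_edges: np.ndarray, retest_edges: np.ndarray
) -> np.ndarray:
    """Pearson correlation of every test edge vector with every retest one.

    Rows are subjects in a fixed shared order and edges are assumed aligned
    (same parcellation, canonical edge ordering).  Edges that are NaN for
    any subject (masked ROIs) are removed for all subjects, so the metric
    is computed with available data only.
    """
    test = np.atleast_2d(np.asarray(test_edges, dtype=float))
    retest = np.atleast_2d(np.asarray(retest_edges, dtype=float))
    if test.shape != retest.shape:
        raise ValueError("test and retest edge arrays must have identical shape")
    if test.shape[0] < 2:
        raise ValueError("need at least two subjects")
    keep = np.isfinite(test).all(axis=0) & np.isfinite(retest).all(axis=0)
    if not keep.all():
        test, retest = test[:, keep], retest[:, keep]
    if test.shape[1] < 3:
        raise ValueError("fewer than 3 usable edges")
    return _standardize_rows(test, "test") @ _standardize_rows(retest, "retest").T


def _success_flags(m: np.ndarray, iself: np.ndarray, iothers: np.ndarray, rule: str):
    n = m.shape[0]
    if rule == "max":
        off = m.copy()
        np.fill_diagonal(off, -np.inf)
        return (iself > off.max(axis=1)) & (iself > off.max(axis=0))
    if rule == "mean":
        return iself > iothers
    raise ValueError(f"unknown success rule {rule!r}")


def identifiability_metrics(
    matrix: np.ndarray, success_rule: str = "max"
) -> IdentifiabilityMetrics:
    """ISelf, IOthers, IDiff and identification success rate of a matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValueError("matrix must be square with at least 2 subjects")
    n = m.shape[0]
    iself = m.diagonal().copy()
    iothers = (m.sum(axis=1) - iself + m.sum(axis=0) - iself) / (2 * n - 2)
    flags = _success_flags(m, iself, iothers, success_rule)
    return IdentifiabilityMetrics(
        iself=iself,
        iothers=iothers,
        idiff=float(iself.mean() - iothers.mean()),
        success_rate=100.0 * float(flags.mean()),
        success_rule=success_rule,
        n_subjects=n,
    )


def permutation_null(
    matrix: np.ndarray,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
    success_rule: str = "max",
) -> PermutationNull:
    """Shuffled-matrix null for IDiff and success rate.

    Each surrogate permutes all N^2 entries of the matrix uniformly at
    random (so it has the same multiset of values as the observed matrix)
    and recomputes both statistics; p = (1 + #{null >= observed}) / (B + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    m = np.asarray(matrix, dtype=float)
    obs = identifiability_metrics(m, success_rule)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # sorted so the surrogate stream depends only on the multiset of entries,
    # making p-values exactly invariant to subject relabeling
    flat = np.sort(m.ravel())
    null_idiff = np.empty(n_permutations)
    null_success = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(flat).reshape(m.shape)
        surr = identifiability_metrics(perm, success_rule)
        null_idiff[b] = surr.idiff
        null_success[b] = surr.success_rate
    p_idiff = (1 + int((null_idiff >= obs.idiff).sum())) / (n_permutations + 1)
    p_success = (1 + int((null_success >= obs.success_rate).sum())) / (n_permutations + 1)
    return PermutationNull(p_idiff, p_success, null_idiff, null_success, n_permutations)


def identifiability_analysis(
    test_edges: np.ndarray,
    retest_edges: np.ndarray,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
    success_rule: str = "max",
) -> tuple[np.ndarray, IdentifiabilityMetrics]:
    """Matrix + metrics + permutation p-values in one call."""
    m = build_identifiability_matrix(test_edges, retest_edges)
    metrics = identifiability_metrics(m, success_rule)
    null = permutation_null(m, n_permutations, seed, success_rule)
    metrics.p_idiff = null.p_idiff
    metrics.p_success = null.p_success
    return m, metrics


def paired_self_other_test(
    iself: np.ndarray, iothers: np.ndarray, alpha_normality: float = 0.05
) -> PairedTestResult:
    """Paired comparison of ISelf vs IOthers with a normality gate.

    A Shapiro-Wilk test on the paired differences (alpha 0.05) selects
    between a paired t-test (normal) and the Wilcoxon signed-rank test;
    both results are always reported alongside the gated choice.
    """
    iself = np.asarray(iself, dtype=float)
    iothers = np.asarray(iothers, dtype=float)
    if iself.shape != iothers.shape or iself.ndim != 1:
        raise ValueError("iself and iothers must be equal-length vectors")
    if len(iself) < 3:
        raise ValueError("need at least 3 paired observations")
    diffs = iself - iothers
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; degenerate comparison")
        return PairedTestResult("t-test", 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0)
    if np.ptp(diffs) == 0:
        shapiro_p = 0.0  # constant nonzero shift: trivially non-normal sample
    else:
        shapiro_p = float(stats.shapiro(diffs).pvalue)
    t_res = stats.ttest_rel(iself, iothers)
    w_res = stats.wilcoxon(iself, iothers)
    if shapiro_p >= alpha_normality:
        chosen, statistic, p = "t-test", float(t_res.statistic), float(t_res.pvalue)
    else:
        chosen, statistic, p = "wilcoxon", float(w_res.statistic), float(w_res.pvalue)
    return PairedTestResult(
        chosen=chosen,
        statistic=statistic,
        p_value=p,
        shapiro_p=shapiro_p,
        t_statistic=float(t_res.statistic),
        t_p=float(t_res.pvalue),
        wilcoxon_statistic=float(w_res.statistic),
        wilcoxon_p=float(w_res.pvalue),
    )


# ---------------------------------------------------------------------------
# permutation ANOVA (Freedman-Lane)
# ---------------------------------------------------------------------------


def _design(groups: Sequence, covariates) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    levels = pd.unique(pd.Series(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    dummies = (groups[:, None] == np.asarray(levels[1:])[None, :]).astype(float)
    n = len(groups)
    cols = [np.ones((n, 1))]
    if covariates is not None:
        c = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        c = np.atleast_2d(c)
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("covariates do not match the number of subjects")
        cols.append(c)
    x_reduced = np.hstack(cols)
    x_full = np.hstack([x_reduced, dummies])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return x_reduced, x_full


def _residual_maker(x: np.ndarray) -> np.ndarray:
    return np.eye(x.shape[0]) - x @ np.linalg.pinv(x)


def permutation_group_anova(
    y: np.ndarray,
    groups: Sequence,
    covariates=None,
    n_permutations: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> GroupANOVAResult:
    """Permutation F-test for a group factor with nuisance covariates.

    Freedman-Lane scheme: the covariate-only (reduced) model is fitted once,
    its residuals are permuted and added back to the reduced-model fit, and
    the group F-statistic of the full model is recomputed on each permuted
    response.  p = (1 + #{F_perm >= F_obs}) / (n_permutations + 1).  The
    permutation distribution is exact under exchangeability of the reduced
    residuals and controls for unequal group sizes by construction.
    """
    y = np.asarray(y, dtype=float).ravel()
    x_reduced, x_full = _design(groups, covariates)
    n, p_full = x_full.shape
    df_group = x_full.shape[1] - x_reduced.shape[1]
    df_resid = n - p_full
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")
    r_reduced = _residual_maker(x_reduced)
    r_full = _residual_maker(x_full)

    def f_stat(rss_reduced, rss_full):
        return ((rss_reduced - rss_full) / df_group) / (rss_full / df_resid)

    e = r_reduced @ y
    fitted = y - e
    f_obs = f_stat(float(e @ e), float(y @ (r_full @ y)))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1).T  # n x B
    y_perm = fitted[:, None] + e[perm_idx]
    res_reduced = r_reduced @ y_perm
    res_full = r_full @ y_perm
    f_perm = f_stat((res_reduced**2).sum(axis=0), (res_full**2).sum(axis=0))
    p = (1 + int((f_perm >= f_obs).sum())) / (n_permutations + 1)
    return GroupANOVAResult(float(f_obs), float(p), df_group, df_resid, n_permutations)
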