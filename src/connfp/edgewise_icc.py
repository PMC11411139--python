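"""Edgewise intraclass correlation: per-edge test-retest fingerprint maps.

For each edge, subjects are the random "rows" of a one-way random-effects
ANOVA with k = 2 sessions (test, retest)::

    MS_R = k * sum_s (ybar_s - ybar)^2 / (n - 1)        between subjects
    MS_W = sum_s sum_j (y_sj - ybar_s)^2 / (n (k - 1))  within subjects
    ICC(1,1) = (MS_R - MS_W) / (MS_R + (k - 1) MS_W)

A high ICC means most of the edge's variance is between subjects rather
than between sessions — the edge is a stable individual "fingerprint".
Negative estimates are kept as computed (they are informative small-sample
outcomes, and the downstream 0.6 threshold makes truncation immaterial).

ICC(2,1) (two-way random, absolute agreement) and ICC(3,1) (two-way mixed,
consistency) are provided as alternatives; the fingerprinting analysis uses
ICC(1,1) because session-level error sources are left unspecified.

To compare groups of unequal size, :func:`bootstrap_group_icc` recomputes
the map on random subject subsets (without replacement by default, since
with-replacement duplicates would violate the ANOVA's independence across
rows) and averages the maps over runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import devectorize_edges, n_edges


@dataclass
class EdgewiseICC:
    """Per-edge ICC values in canonical edge order, with provenance."""

    values: np.ndarray
    form: str = "icc1"
    group: str | None = None
    provenance: dict = field(default_factory=lambda: {"kind": "plain"})

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.max() > 1 + 1e-9:
            raise ValueError("ICC values cannot exceed 1")

    @property
    def n_regions(self) -> int:
        e = len(self.values)
        r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        if n_edges(r) != e:
            raise ValueError(f"edge count {e} is not R(R-1)/2 for any integer R")
        return r

    def to_matrix(self) -> np.ndarray:
        """Symmetric R x R matrix; the (undefined) diagonal is stored as 0."""
        return devectorize_edges(self.values, self.n_regions, diag=0.0)


@dataclass
class OverlapMask:
    """Supra-threshold edge mask (optionally the AND of two cohorts)."""

    edges: np.ndarray  # boolean, canonical edge order
    threshold: float

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=bool)

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum())

    @property
    def n_regions(self) -> int:
        return EdgewiseICC(self.edges.astype(float)).n_regions

    def to_matrix(self) -> np.ndarray:
        return devectorize_edges(self.edges.astype(float), self.n_regions, diag=0.0)


# ---------------------------------------------------------------------------


def _session_stack(test: np.ndarray, retest: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    test = np.atleast_2d(np.asarray(test, dtype=float))
    retest = np.atleast_2d(np.asarray(retest, dtype=float))
    if test.shape != retest.shape:
        raise ValueError("test and retest must have identical shape (n_subjects, n_edges)")
    if test.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return test, retest


def _sums_of_squares(test, retest):
    """Per-edge ANOVA pieces with per-edge handling of missing subjects."""
    valid = np.isfinite(test) & np.isfinite(retest)
    n_e = valid.sum(axis=0).astype(float)
    t = np.where(valid, test, 0.0)
    r = np.where(valid, retest, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_mean = np.where(valid, (t + r) / 2.0, 0.0)
        grand = (t + r).sum(axis=0) / (2.0 * n_e)
        col_half_diff = (r - t).sum(axis=0) / (2.0 * n_e)  # (col2 mean - grand)
        ss_rows = 2.0 * (valid * (row_mean - grand) ** 2).sum(axis=0)
        ss_within = (valid * ((t - row_mean) ** 2 + (r - row_mean) ** 2)).sum(axis=0)
        ss_cols = 2.0 * n_e * col_half_diff**2
    return n_e, ss_rows, ss_within, ss_cols


def icc_edgewise(
    test: np.ndarray,
    retest: np.ndarray,
    form: str = "icc1",
    group: str | None = None,
) -> EdgewiseICC:
    """ICC per edge across subjects, two sessions per subject.

    ``test`` and ``retest`` are (n_subjects, n_edges) arrays in canonical
    edge order.  Subjects with a missing (NaN) value at an edge are dropped
    for that edge only; edges left with fewer than 2 subjects come back as
    NaN with a warning.
    """
    test, retest = _session_stack(test, retest)
    k = 2.0
    n_e, ss_rows, ss_within, ss_cols = _sums_of_squares(test, retest)
    short = n_e < 2
    if short.any():
        warnings.warn(
            f"{int(short.sum())} edge(s) have fewer than 2 complete subjects; "
            "returned as NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_rows = ss_rows / (n_e - 1)
        if form == "icc1":
            ms_within = ss_within / (n_e * (k - 1))
            icc = (ms_rows - ms_within) / (ms_rows + (k - 1) * ms_within)
        elif form in ("icc2", "icc3"):
            ss_err = ss_within - ss_cols
            ms_err = ss_err / ((n_e - 1) * (k - 1))
            if form == "icc3":
                icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
            else:
                ms_cols = ss_cols / (k - 1)
                icc = (ms_rows - ms_err) / (
                    ms_rows + (k - 1) * ms_err + k / n_e * (ms_cols - ms_err)
                )
        else:
            raise ValueError(f"unknown ICC form {form!r}")
    icc = np.where(short, np.nan, icc)
    return EdgewiseICC(values=icc, form=form, group=group)


def icc_one_way(test: np.ndarray, retest: np.ndarray, group: str | None = None) -> EdgewiseICC:
    """ICC(1,1) — the fingerprinting default."""
    return icc_edgewise(test, retest, form="icc1", group=group)


def bootstrap_group_icc(
    test: np.ndarray,
    retest: np.ndarray,
    subset_size: int,
    n_runs: int = 1000,
    seed: int | np.random.Generator | None = None,
    replace: bool = False,
    form: str = "icc1",
    group: str | None = None,
) -> EdgewiseICC:
    """Subject-subsampled, run-averaged ICC map.

    Each run draws ``subset_size`` subjects (without replacement by default)
    and recomputes the edgewise ICC; maps are averaged across runs.  This
    equalizes the effective sample size across groups of different sizes.
    When ``subset_size`` equals the group size (without replacement), every
    run uses the full group and the average equals the plain map exactly.
    """
    test, retest = _session_stack(test, retest)
    n = test.shape[0]
    if subset_size < 2:
        raise ValueError("subset_size must be at least 2")
    if not replace and subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds group size {n}")
    if n_runs < 1:
        raise ValueError("need at least one run")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = np.zeros(test.shape[1])
    for _ in range(n_runs):
        idx = rng.choice(n, size=subset_size, replace=replace)
        acc += icc_edgewise(test[idx], retest[idx], form=form).values
    return EdgewiseICC(
        values=acc / n_runs,
        form=form,
        group=group,
        provenance={
            "kind": "bootstrap-averaged",
            "n_runs": n_runs,
            "subset_size": subset_size,
            "replace": replace,
        },
    )


def binarize(icc: EdgewiseICC | np.ndarray, threshold: float = 0.6) -> OverlapMask:
    """Supra-threshold mask at strict ``ICC > threshold`` (default 0.6,
    the conventional lower bound for a 'good' ICC).  NaN edges are False."""
    values = icc.values if isinstance(icc, EdgewiseICC) else np.asarray(icc, float)
    with np.errstate(invalid="ignore"):
        edges = np.where(np.isfinite(values), values > threshold, False)
    return OverlapMask(edges=edges, threshold=threshold)


def binarize_and_overlap(
    icc_a: EdgewiseICC | np.ndarray,
    icc_b: EdgewiseICC | np.ndarray,
    threshold: float = 0.6,
) -> OverlapMask:
    """Edges supra-threshold in *both* maps (e.g. two independent cohorts)."""
    a = binarize(icc_a, threshold)
    b = binarize(icc_b, threshold)
    if a.edges.shape != b.edges.shape:
        raise ValueError("ICC maps have different numbers of edges")
    return OverlapMask(edges=a.edges & b.edges, threshold=threshold)
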