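"""Functional connectomes from regional time series, with motion QC and ROI filters.

A functional connectome (FC) is the symmetric matrix of pairwise Pearson
correlations between regional BOLD-like time series.  Within-session
fingerprinting splits a single acquisition into a first ("test") and second
("retest") half and builds one FC per half.  This module owns:

* the canonical edge ordering used by every downstream stage (strict upper
  triangle, row-major, shared across subjects under a common parcellation);
* motion quality control: per-volume tagging from framewise displacement
  (FD, mm), standardized DVARS and whole-brain signal SD, and the
  subject-level exclusion rule (tagged fraction strictly above 30%);
* the ROI-availability filter: a region missing in strictly more than 10%
  of subjects is dropped for everyone, sporadic missingness is masked and
  downstream statistics use available data only.

Tagged volumes are flagged but never removed from the series; motion enters
the analysis as a nuisance covariate instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The eight resting-state network labels: seven cortical systems plus a
#: subcortical block.
NETWORKS = ("VIS", "SMT", "DA", "SA", "L", "FPN", "DMN", "SBC")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parcellation:
    """Region -> resting-state-network assignment.

    Parameters
    ----------
    region_ids:
        Ordered region identifiers (length R).
    networks:
        Network label per region, each one of :data:`NETWORKS`.
    """

    region_ids: tuple[str, ...]
    networks: tuple[str, ...]

    def __post_init__(self):
        if len(self.region_ids) != len(self.networks):
            raise ValueError("region_ids and networks must have equal length")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region ids in parcellation")
        bad = set(self.networks) - set(NETWORKS)
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def network_array(self) -> np.ndarray:
        return np.asarray(self.networks, dtype=object)


@dataclass
class RegionalTimeSeries:
    """One subject-session block of regional signals (T volumes x R regions).

    Columns that are entirely NaN are treated as missing ROIs: they are
    flagged, never silently dropped, and propagate as masked rows/columns of
    the derived connectome.
    """

    subject_id: str
    session: str  # "full", "test" or "retest"
    data: np.ndarray
    region_ids: tuple[str, ...]
    sampling_interval: float = 2.0  # TR in seconds

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x R matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least two volumes")
        if self.data.shape[1] != len(self.region_ids):
            raise ValueError("column count does not match region_ids")
        if self.session not in ("full", "test", "retest"):
            raise ValueError(f"unknown session label {self.session!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def missing_regions(self) -> np.ndarray:
        """Boolean flag per region: True where the whole column is NaN."""
        return np.isnan(self.data).all(axis=0)


@dataclass
class FunctionalConnectome:
    """Symmetric R x R Pearson-correlation matrix for one subject-session.

    Missing regions carry NaN rows/columns; the edge vector (strict upper
    triangle, row-major) keeps those entries as NaN so edge ordering stays
    aligned across subjects.
    """

    subject_id: str
    session: str
    matrix: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if m.shape[0] != len(self.region_ids):
            raise ValueError("matrix size does not match region_ids")
        finite = np.isfinite(m)
        sym_ok = np.allclose(
            np.where(finite, m, 0.0), np.where(finite.T, m.T, 0.0), atol=1e-12, rtol=0.0
        ) and bool((finite == finite.T).all())
        if not sym_ok:
            raise ValueError("connectome matrix is not symmetric to 1e-12")
        valid = finite.diagonal()
        if not np.allclose(m.diagonal()[valid], 1.0, atol=1e-12):
            raise ValueError("diagonal must be 1 for available regions")
        self.matrix = m

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_vector(self) -> np.ndarray:
        return vectorize_edges(self.matrix)

    def missing_regions(self) -> np.ndarray:
        return ~np.isfinite(self.matrix.diagonal())


@dataclass(frozen=True)
class QCTrace:
    """Per-volume motion/artifact summary traces for one subject.

    fd is framewise displacement in mm (non-negative), dvars is standardized
    DVARS and sd the per-volume whole-brain signal standard deviation; all
    three have one value per volume.
    """

    subject_id: str
    fd: np.ndarray
    dvars: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        for name in ("fd", "dvars", "sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.fd) == len(self.dvars) == len(self.sd)):
            raise ValueError("fd, dvars and sd must have equal length")
        if (self.fd < 0).any():
            raise ValueError("framewise displacement cannot be negative")

    @property
    def n_volumes(self) -> int:
        return len(self.fd)


@dataclass(frozen=True)
class QCRules:
    """Thresholds for per-volume motion tagging.

    A volume is tagged when every enabled criterion fires (``combine="all"``,
    the conjunctive rule) or when any does (``combine="any"``).  The SD
    criterion is relative to the subject's own trace: SD above the 75th
    percentile plus 1.5 interquartile ranges (boxplot outlier fence,
    linear-interpolation percentiles).
    """

    fd_threshold: float = 0.3
    dvars_threshold: float | None = 1.7
    sd_boxplot: bool = True
    combine: str = "all"
    name: str = "custom"

    def __post_init__(self):
        if self.combine not in ("all", "any"):
            raise ValueError("combine must be 'all' or 'any'")


#: Conjunctive tagging rule: FD > 0.3 mm AND standardized DVARS > 1.7 AND
#: SD above the per-subject boxplot fence.
CONJUNCTIVE_RULES = QCRules(fd_threshold=0.3, dvars_threshold=1.7, sd_boxplot=True,
                       combine="all", name="fd-dvars-sd")
#: FD-only rule: FD > 0.5 mm.
FD_ONLY_RULES = QCRules(fd_threshold=0.5, dvars_threshold=None, sd_boxplot=False,
                     combine="all", name="fd-only")

QC_RULE_SETS = {"fd-dvars-sd": CONJUNCTIVE_RULES, "fd-only": FD_ONLY_RULES}


@dataclass(frozen=True)
class QCReport:
    subject_id: str
    tagged: np.ndarray  # boolean per-volume mask
    tagged_fraction: float
    exclude_subject: bool
    rules: QCRules


# ---------------------------------------------------------------------------
# edge ordering
# ---------------------------------------------------------------------------


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the canonical edge order (strict upper triangle,
    row-major). Every module uses this single definition."""
    return np.triu_indices(n_regions, k=1)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def vectorize_edges(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Strict-upper-triangle edge vector of a symmetric matrix.

    Raises if the matrix is asymmetric beyond ``atol`` (NaN entries must be
    symmetric as well).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    finite = np.isfinite(m)
    if (finite != finite.T).any() or not np.allclose(
        np.where(finite, m, 0.0), np.where(finite, m, 0.0).T, atol=atol, rtol=0.0
    ):
        raise ValueError(f"matrix asymmetric beyond atol={atol}")
    iu = edge_index(m.shape[0])
    return m[iu]


def devectorize_edges(edges: np.ndarray, n_regions: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`: rebuild the symmetric matrix."""
    edges = np.asarray(edges, dtype=float)
    if len(edges) != n_edges(n_regions):
        raise ValueError(
            f"edge vector of length {len(edges)} does not match R={n_regions}"
        )
    m = np.full((n_regions, n_regions), float(diag))
    iu = edge_index(n_regions)
    m[iu] = edges
    m[iu[1], iu[0]] = edges
    return m


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def split_halves(
    ts: RegionalTimeSeries, policy: str = "drop_middle"
) -> tuple[RegionalTimeSeries, RegionalTimeSeries]:
    """Split a full session into equal-length test and retest halves.

    The test half is the first floor(T/2) volumes and the retest half the
    last floor(T/2).  With odd T the default policy drops the single middle
    volume, keeping the halves equal-length and symmetric about the session
    midpoint; ``policy="drop_end"`` instead uses volumes [0, T/2) and
    [T/2, 2*floor(T/2)), discarding the tail.
    """
    T = ts.n_volumes
    if T < 4:
        raise ValueError(f"need at least 4 volumes to split, got {T}")
    half = T // 2
    if policy == "drop_middle":
        first, second = ts.data[:half], ts.data[T - half:]
    elif policy == "drop_end":
        first, second = ts.data[:half], ts.data[half: 2 * half]
    else:
        raise ValueError(f"unknown split policy {policy!r}")
    mk = lambda session, block: RegionalTimeSeries(
        subject_id=ts.subject_id,
        session=session,
        data=block.copy(),
        region_ids=ts.region_ids,
        sampling_interval=ts.sampling_interval,
    )
    return mk("test", first), mk("retest", second)


def compute_fc(ts: RegionalTimeSeries) -> FunctionalConnectome:
    """Pearson FC of a regional time-series block.

    Missing (all-NaN) columns produce NaN rows/columns.  A retained column
    with zero variance is auto-flagged missing with a warning rather than
    producing undefined correlations.
    """
    data = ts.data
    R = ts.n_regions
    missing = ts.missing_regions().copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(data, axis=0)
    degenerate = (~missing) & ((variances == 0) | ~np.isfinite(variances))
    if degenerate.any():
        bad = [ts.region_ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance region(s) {bad} in {ts.subject_id}/{ts.session}: "
            "flagged missing",
            stacklevel=2,
        )
        missing |= degenerate
    valid = np.flatnonzero(~missing)
    matrix = np.full((R, R), np.nan)
    if len(valid) >= 1:
        sub = data[:, valid]
        if np.isnan(sub).any():
            raise ValueError("retained regions contain sporadic NaNs within a column")
        c = np.corrcoef(sub.T) if len(valid) > 1 else np.ones((1, 1))
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        matrix[np.ix_(valid, valid)] = c
    return FunctionalConnectome(
        subject_id=ts.subject_id, session=ts.session, matrix=matrix,
        region_ids=ts.region_ids,
    )


def filter_rois(
    missing_table: np.ndarray,
    region_ids: Sequence[str],
    threshold: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Cohort-level ROI-availability filter.

    ``missing_table`` is a subjects x regions boolean array (True = region
    missing for that subject).  A region is excluded for all subjects iff its
    missing fraction strictly exceeds ``threshold`` (default 10%); regions
    with sporadic missingness at or below the threshold are retained and
    handled per-subject downstream.

    Returns ``(retained_ids, excluded_ids)``.  The operation is idempotent:
    re-filtering the retained columns never excludes more regions.
    """
    table = np.asarray(missing_table, dtype=bool)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("missing_table must be a non-empty subjects x regions array")
    if table.shape[1] != len(region_ids):
        raise ValueError("missing_table columns do not match region_ids")
    frac = table.mean(axis=0)
    excluded = frac > threshold
    ids = list(region_ids)
    return (
        [r for r, e in zip(ids, excluded) if not e],
        [r for r, e in zip(ids, excluded) if e],
    )


def qc_tag_and_exclude(
    trace: QCTrace,
    rules: QCRules = CONJUNCTIVE_RULES,
    subject_exclusion_fraction: float = 0.30,
) -> QCReport:
    """Tag high-motion volumes and decide subject-level exclusion.

    A subject is excluded iff the tagged fraction strictly exceeds
    ``subject_exclusion_fraction`` (default 30%).  Tagged volumes are only
    flagged — the series itself is untouched.
    """
    criteria = [trace.fd > rules.fd_threshold]
    if rules.dvars_threshold is not None:
        criteria.append(trace.dvars > rules.dvars_threshold)
    if rules.sd_boxplot:
        q75, q25 = np.percentile(trace.sd, [75, 25])
        criteria.append(trace.sd > q75 + 1.5 * (q75 - q25))
    stacked = np.vstack(criteria)
    tagged = stacked.all(axis=0) if rules.combine == "all" else stacked.any(axis=0)
    frac = float(tagged.mean())
    return QCReport(
        subject_id=trace.subject_id,
        tagged=tagged,
        tagged_fraction=frac,
        exclude_subject=frac > subject_exclusion_fraction,
        rules=rules,
    )


def edge_network_labels(parcellation: Parcellation) -> tuple[np.ndarray, np.ndarray]:
    """Network label of both endpoints for every edge, in canonical order."""
    nets = parcellation.network_array()
    iu = edge_index(parcellation.n_regions)
    return nets[iu[0]], nets[iu[1]]
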