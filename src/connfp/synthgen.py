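"""Synthetic two-session connectome cohorts with analytically known reliability.

The generator implements the minimal variance-components model under which
test-retest identifiability and edgewise intraclass correlation are
well-defined.  For subject s, edge e and session j in {test, retest}::

    y[s, e, j] = mu[e] + b[s, e] + eps[s, e, j]
    b   ~ Normal(0, sigma_b[e]^2)   (subject-specific edge signature)
    eps ~ Normal(0, sigma_w[e]^2)   (session/measurement noise)

all draws independent.  Under this model the one-way random-effects ICC of
edge e is exactly::

    ICC_true(e) = sigma_b[e]^2 / (sigma_b[e]^2 + sigma_w[e]^2)

which is the ground truth every recovery test is checked against.  Two
output levels are supported: edge panels (test/retest edge vectors drawn
directly from the model — exact analytic ICC, used for calibration) and
regional time series (per-subject multivariate-normal series whose split-half
FCs inherit the subject-specific structure — used to exercise the full
pipeline from raw series).

Group differences are expressed through an *effect map*: an ordered list of
per-group modifications of sigma_b / sigma_w over network blocks (or explicit
edge sets).  :func:`plant_topology_shift` uses it to move high-variance
("fingerprint") edges from one block to another in a single group, emulating
a within-network -> between-network reconfiguration of reliable edges.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .connectome import (
    NETWORKS,
    Parcellation,
    QCTrace,
    RegionalTimeSeries,
    devectorize_edges,
    edge_index,
    n_edges,
)

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = {"CU": 16, "MCI": 32, "AD": 6}


def default_partition(n_regions: int, networks: Sequence[str] = NETWORKS) -> tuple[str, ...]:
    """Contiguous near-equal network blocks over ``n_regions`` regions."""
    if n_regions < len(networks):
        raise ValueError("need at least one region per network")
    sizes = [len(block) for block in np.array_split(np.arange(n_regions), len(networks))]
    labels: list[str] = []
    for net, size in zip(networks, sizes):
        labels.extend([net] * size)
    return tuple(labels)


def parse_block(block_id: str) -> tuple[str, str]:
    """Parse a network-block id of the form ``"within:FPN"`` / ``"between:FPN"``."""
    try:
        kind, net = block_id.split(":")
    except ValueError as exc:
        raise ValueError(
            f"block id {block_id!r} is not of the form 'within:NET' or 'between:NET'"
        ) from exc
    if kind not in ("within", "between"):
        raise ValueError(f"unknown block kind {kind!r}")
    return kind, net


def edge_block_mask(partition: Sequence[str], block_id: str) -> np.ndarray:
    """Boolean mask over canonical edges selecting a within/between block."""
    kind, net = parse_block(block_id)
    nets = np.asarray(partition, dtype=object)
    if net not in set(partition):
        raise ValueError(f"network {net!r} not present in partition")
    iu = edge_index(len(partition))
    a, b = nets[iu[0]] == net, nets[iu[1]] == net
    return (a & b) if kind == "within" else (a ^ b)


@dataclass
class SyntheticModelSpec:
    """Full parameterization of the synthetic cohort generator.

    sigma_b / sigma_w are dimensionless edge-level standard deviations
    (scalar or per-edge arrays); ``effect_map`` maps a group label to an
    ordered list of modification dicts, each selecting edges through a
    ``"block"`` id or an explicit ``"edges"`` index list and overriding
    (``"sigma_b"``, ``"sigma_w"``) or rescaling (``"sigma_b_scale"``,
    ``"sigma_w_scale"``) the selected edges for that group only.

    Identical spec + identical seed produces bit-identical output; each
    subject draws from its own spawned RNG substream, so subsetting subjects
    does not reshuffle the data of the others.
    """

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    n_regions: int = 40
    partition: tuple[str, ...] | None = None
    mu_edge: float | np.ndarray = 0.3
    sigma_b: float | np.ndarray = 0.15
    sigma_w: float | np.ndarray = 0.10
    effect_map: dict[str, list[dict]] = field(default_factory=dict)
    T: int = 200
    seed: int = 0
    clip: bool = False  # clip edge values into (-1, 1); off to preserve true ICC

    def __post_init__(self):
        if self.n_regions <= 1:
            raise ValueError("n_regions must be at least 2")
        if any(n <= 0 for n in self.n_subjects_per_group.values()):
            raise ValueError("subject counts must be positive")
        if self.partition is None:
            self.partition = default_partition(self.n_regions)
        self.partition = tuple(self.partition)
        if len(self.partition) != self.n_regions:
            raise ValueError("partition length must equal n_regions")
        for grp in self.effect_map:
            if grp not in self.n_subjects_per_group:
                raise ValueError(f"effect_map group {grp!r} not in cohort")
        for name in ("sigma_b", "sigma_w"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), float), (self.n_edges,))
            if (arr < 0).any():
                raise ValueError(f"{name} must be non-negative")
        for grp in self.group_labels:
            sb, sw = self.edge_sigmas(grp)
            if ((sb == 0) & (sw == 0)).any():
                raise ValueError(
                    f"sigma_b and sigma_w both zero on some edge for group {grp!r}"
                )

    # -- derived quantities ------------------------------------------------

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.n_subjects_per_group)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_subjects_per_group.values())

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_regions)

    def _edge_array(self, value) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=float), (self.n_edges,)).copy()

    def _effect_edges(self, entry: dict) -> np.ndarray:
        if "edges" in entry:
            mask = np.zeros(self.n_edges, dtype=bool)
            mask[np.asarray(entry["edges"], dtype=int)] = True
            return mask
        if "block" in entry:
            return edge_block_mask(self.partition, entry["block"])
        raise ValueError("effect entry needs an 'edges' list or a 'block' id")

    def edge_sigmas(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge (sigma_b, sigma_w) for one group, effect map applied."""
        if group not in self.n_subjects_per_group:
            raise ValueError(f"unknown group {group!r}")
        sb = self._edge_array(self.sigma_b)
        sw = self._edge_array(self.sigma_w)
        for entry in self.effect_map.get(group, []):
            sel = self._effect_edges(entry)
            if "sigma_b_scale" in entry:
                sb[sel] *= entry["sigma_b_scale"]
            if "sigma_w_scale" in entry:
                sw[sel] *= entry["sigma_w_scale"]
            if "sigma_b" in entry:
                sb[sel] = entry["sigma_b"]
            if "sigma_w" in entry:
                sw[sel] = entry["sigma_w"]
        return sb, sw

    def true_icc(self, group: str) -> np.ndarray:
        """Analytic ICC per edge: sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
        sb, sw = self.edge_sigmas(group)
        return sb**2 / (sb**2 + sw**2)

    def mu(self) -> np.ndarray:
        return self._edge_array(self.mu_edge)

    def parcellation(self) -> Parcellation:
        ids = tuple(f"R{i:03d}" for i in range(self.n_regions))
        return Parcellation(region_ids=ids, networks=self.partition)

    def subject_table(self) -> list[tuple[str, str]]:
        """Ordered (subject_id, group) pairs for the whole cohort."""
        rows = []
        for grp, n in self.n_subjects_per_group.items():
            rows.extend((f"{grp}{i + 1:03d}", grp) for i in range(n))
        return rows

    def subject_streams(self) -> list[np.random.SeedSequence]:
        """One RNG substream per subject, keyed by (group index, subject
        index) so dropping subjects or whole groups never reshuffles the
        draws of the remaining subjects."""
        streams = []
        for gi, (grp, n) in enumerate(self.n_subjects_per_group.items()):
            streams.extend(
                np.random.SeedSequence(entropy=self.seed, spawn_key=(gi, si))
                for si in range(n)
            )
        return streams

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def plain(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        return {
            "n_subjects_per_group": dict(self.n_subjects_per_group),
            "n_regions": self.n_regions,
            "partition": list(self.partition),
            "mu_edge": plain(self.mu_edge),
            "sigma_b": plain(self.sigma_b),
            "sigma_w": plain(self.sigma_w),
            "effect_map": copy.deepcopy(self.effect_map),
            "T": self.T,
            "seed": self.seed,
            "clip": self.clip,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticModelSpec":
        d = dict(d)
        for name in ("mu_edge", "sigma_b", "sigma_w"):
            if isinstance(d.get(name), list):
                d[name] = np.asarray(d[name], dtype=float)
        if d.get("partition") is not None:
            d["partition"] = tuple(d["partition"])
        return cls(**d)


def fingerprint_cohort_spec(
    n_subjects_per_group: Mapping[str, int] | None = None,
    n_regions: int = 40,
    icc_within: float = 0.8,
    icc_between: float = 0.2,
    sigma_w: float = 0.10,
    between_reliable_fraction: float = 0.10,
    mu_edge: float = 0.3,
    T: int = 200,
    seed: int = 0,
) -> SyntheticModelSpec:
    """Cohort spec whose reliable ("fingerprint") edges sit within networks.

    Within-network edges get subject variance tuned to ``icc_within``;
    between-network edges get ``icc_between``, except for an evenly spaced
    ``between_reliable_fraction`` of them which are made as reliable as
    within-network edges — mirroring the fact that real cohorts also carry a
    minority of reliable long-range connections, and keeping between-block
    supra-threshold proportions strictly positive so disease/health ratios
    are defined.
    """

    def sb_for(icc):
        return sigma_w * math.sqrt(icc / (1.0 - icc))

    partition = default_partition(n_regions)
    nets = np.asarray(partition, dtype=object)
    iu = edge_index(n_regions)
    within = nets[iu[0]] == nets[iu[1]]
    sb = np.where(within, sb_for(icc_within), sb_for(icc_between))
    between_idx = np.flatnonzero(~within)
    k = int(round(between_reliable_fraction * len(between_idx)))
    if k > 0:
        chosen = between_idx[np.linspace(0, len(between_idx) - 1, k).astype(int)]
        sb[chosen] = sb_for(icc_within)
    return SyntheticModelSpec(
        n_subjects_per_group=dict(n_subjects_per_group or DEFAULT_GROUPS),
        n_regions=n_regions,
        partition=partition,
        mu_edge=mu_edge,
        sigma_b=sb,
        sigma_w=sigma_w,
        T=T,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# edge-level generation
# ---------------------------------------------------------------------------


@dataclass
class EdgePanel:
    """Two-session edge data for a whole cohort.

    test / retest are n_subjects x n_edges arrays in canonical edge order;
    ``true_icc`` maps each group label to its analytic per-edge ICC.
    """

    subject_ids: list[str]
    groups: np.ndarray  # group label per subject
    test: np.ndarray
    retest: np.ndarray
    true_icc: dict[str, np.ndarray]
    spec: SyntheticModelSpec

    def group_panel(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.groups == group
        if not sel.any():
            raise ValueError(f"no subjects in group {group!r}")
        return self.test[sel], self.retest[sel]


def generate_edge_panel(spec: SyntheticModelSpec) -> EdgePanel:
    """Draw test/retest edge vectors for every subject from the model.

    Edge values are *not* clipped into (-1, 1) unless ``spec.clip`` is set:
    clipping would bias the analytic ICC that recovery tests target.
    """
    table = spec.subject_table()
    streams = spec.subject_streams()
    E = spec.n_edges
    mu = spec.mu()
    sigmas = {g: spec.edge_sigmas(g) for g in spec.group_labels}
    test = np.empty((len(table), E))
    retest = np.empty((len(table), E))
    for row, ((sid, grp), stream) in enumerate(zip(table, streams)):
        rng = np.random.default_rng(stream)
        sb, sw = sigmas[grp]
        b = rng.normal(0.0, 1.0, E) * sb
        test[row] = mu + b + rng.normal(0.0, 1.0, E) * sw
        retest[row] = mu + b + rng.normal(0.0, 1.0, E) * sw
    if spec.clip:
        np.clip(test, -0.999, 0.999, out=test)
        np.clip(retest, -0.999, 0.999, out=retest)
    return EdgePanel(
        subject_ids=[sid for sid, _ in table],
        groups=np.asarray([grp for _, grp in table], dtype=object),
        test=test,
        retest=retest,
        true_icc={g: spec.true_icc(g) for g in spec.group_labels},
        spec=spec,
    )


# ---------------------------------------------------------------------------
# time-series generation
# ---------------------------------------------------------------------------


def nearest_positive_definite_correlation(
    matrix: np.ndarray, eigen_floor: float = 1e-8
) -> np.ndarray:
    """Deterministic projection to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eigen_floor`` and the result renormalized to
    unit diagonal.  Idempotent on matrices that are already valid.
    """
    a = np.asarray(matrix, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10, rtol=0.0):
        raise ValueError("template matrix is not symmetrizable")
    a = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(a)
    if vals.min() >= eigen_floor and np.allclose(a.diagonal(), 1.0, atol=1e-12):
        return a
    fixed = (vecs * np.maximum(vals, eigen_floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


def template_correlation(spec: SyntheticModelSpec) -> np.ndarray:
    """Group-level template correlation matrix implied by mu_edge."""
    return nearest_positive_definite_correlation(
        devectorize_edges(spec.mu(), spec.n_regions, diag=1.0)
    )


def generate_cohort_timeseries(
    spec: SyntheticModelSpec, tau: float = 1.0
) -> list[RegionalTimeSeries]:
    """Full-length regional series per subject, with subject-specific FC.

    Each subject's target correlation is the template plus ``tau`` times a
    subject-specific perturbation whose edgewise scale follows sigma_b (so
    reliable edges are exactly the ones where subjects differ), projected to
    the nearest positive-definite correlation matrix.  The series is a
    zero-mean multivariate normal draw of length T with that correlation, so
    split-half FCs of the same subject share its signature while different
    subjects' FCs do not.
    """
    R, T = spec.n_regions, spec.T
    if T < 2 * R:
        logger.warning(
            "T=%d < 2R=%d: split-half FC estimates will be unstable", T, 2 * R
        )
    template = template_correlation(spec)
    table = spec.subject_table()
    streams = spec.subject_streams()
    out = []
    region_ids = spec.parcellation().region_ids
    for (sid, grp), stream in zip(table, streams):
        rng = np.random.default_rng(stream)
        sb, _ = spec.edge_sigmas(grp)
        target = template
        if tau != 0.0:
            pert = tau * sb * rng.normal(0.0, 1.0, spec.n_edges)
            target = nearest_positive_definite_correlation(
                template + devectorize_edges(pert, R, diag=0.0)
            )
        chol = np.linalg.cholesky(target + 1e-10 * np.eye(R))
        series = rng.standard_normal((T, R)) @ chol.T
        out.append(
            RegionalTimeSeries(
                subject_id=sid, session="full", data=series, region_ids=region_ids
            )
        )
    return out


# ---------------------------------------------------------------------------
# planted effects and QC fixtures
# ---------------------------------------------------------------------------


def plant_topology_shift(
    spec: SyntheticModelSpec,
    source_block: str,
    target_block: str,
    group: str,
    threshold: float = 0.6,
) -> SyntheticModelSpec:
    """Move high-subject-variance edges from one block to another in a group.

    The source block's supra-threshold edges (true ICC > ``threshold``) lose
    their subject variance (set to the target block's typical sub-threshold
    sigma_b) and an equal number of sub-threshold target-block edges —
    lowest edge index first, deterministically — gain it.  Other groups are
    untouched; edge counts of reliable edges are conserved, only their
    topology changes.
    """
    if group not in spec.n_subjects_per_group:
        raise ValueError(f"unknown group {group!r}")
    src_mask = edge_block_mask(spec.partition, source_block)
    tgt_mask = edge_block_mask(spec.partition, target_block)
    sb, sw = spec.edge_sigmas(group)
    icc = sb**2 / (sb**2 + sw**2)
    src_hot = np.flatnonzero(src_mask & (icc > threshold))
    if len(src_hot) == 0:
        raise ValueError(f"no supra-threshold edges in source block {source_block!r}")
    tgt_cold = np.flatnonzero(tgt_mask & (icc <= threshold))
    k = min(len(src_hot), len(tgt_cold))
    tgt_sel = tgt_cold[:k]
    src_sel = src_hot[:k]
    hot_sigma = float(np.median(sb[src_sel]))
    cold_pool = sb[tgt_mask & (icc <= threshold)]
    cold_sigma = float(np.median(cold_pool)) if len(cold_pool) else float(np.median(sb))
    new_map = copy.deepcopy(spec.effect_map)
    new_map.setdefault(group, [])
    new_map[group] = new_map[group] + [
        {"edges": src_sel.tolist(), "sigma_b": cold_sigma},
        {"edges": tgt_sel.tolist(), "sigma_b": hot_sigma},
    ]
    return replace(spec, effect_map=new_map)


def generate_qc_traces(
    T: int, outlier_rate: float, seed: int, subject_id: str = "sim"
) -> QCTrace:
    """Low-motion baseline trace with a planted fraction of outlier volumes.

    Outlier volumes jointly exceed the FD thresholds (0.3 and 0.5 mm), the
    standardized-DVARS threshold (1.7) and the per-trace SD boxplot fence;
    baseline volumes exceed none of them (FD capped at 0.25 mm, DVARS at
    1.6).  The number of outliers is round(outlier_rate * T).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError("outlier_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fd = np.clip(np.abs(rng.normal(0.08, 0.03, T)), 0.0, 0.25)
    dvars = np.clip(rng.normal(1.0, 0.15, T), 0.0, 1.6)
    sd = rng.normal(1.0, 0.02, T)
    k = int(round(outlier_rate * T))
    if k > 0:
        idx = rng.choice(T, size=k, replace=False)
        fd[idx] = rng.uniform(0.55, 1.2, k)
        dvars[idx] = rng.uniform(2.0, 3.0, k)
        sd[idx] = sd[idx] + rng.uniform(3.0, 5.0, k)
    return QCTrace(subject_id=subject_id, fd=fd, dvars=dvars, sd=sd)
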