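"""End-to-end fingerprinting pipeline: QC -> FC -> identifiability -> ICC ->
network statistics -> fingerprint hubs.

The pipeline consumes either raw regional time series (one full-session TSV
per subject, split into test/retest halves here), precomputed test/retest
FC matrices, or a synthetic-cohort spec, and produces one result bundle per
run: identifiability matrices and metrics per group, bootstrap-averaged ICC
maps, supra-threshold masks, the network reconfiguration table, and nodal
fingerprint strengths with hub masks.  The resolved configuration (every
seed and parameter included) is written next to the outputs so any artifact
is regenerable from it alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as fio
from .connectome import (
    QC_RULE_SETS,
    Parcellation,
    compute_fc,
    filter_rois,
    qc_tag_and_exclude,
    split_halves,
    vectorize_edges,
)
from .edgewise_icc import EdgewiseICC, binarize, bootstrap_group_icc
from .identifiability import (
    identifiability_analysis,
    paired_self_other_test,
)
from .network_stats import network_reconfiguration_table
from .nodal_hubs import nodal_fingerprint, surrogate_icc_null
from .synthgen import SyntheticModelSpec, generate_edge_panel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run (all serializable)."""

    # input: exactly one of the three
    timeseries_dir: str | None = None
    fc_dir: str | None = None
    simulate: dict | None = None  # SyntheticModelSpec.to_dict() payload
    parcellation_path: str | None = None
    qc_dir: str | None = None

    qc_rules: str = "fd-dvars-sd"
    subject_exclusion_fraction: float = 0.30
    roi_threshold: float = 0.10
    split_policy: str = "drop_middle"

    icc_threshold: float = 0.6
    bootstrap_runs: int = 1000
    bootstrap_subset: int = 5
    surrogate_runs: int = 1000
    surrogate_draw: int = 5
    permutation_runs: int = 1000
    success_rule: str = "max"
    healthy_group: str = "CU"

    seed: int = 0
    outdir: str = "connfp_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(payload) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**dict(payload))


@dataclass
class CohortResults:
    """In-memory result bundle for one cohort."""

    groups: tuple[str, ...]
    identifiability: dict[str, dict]  # per group: matrix, metrics, paired test
    icc: dict[str, EdgewiseICC]
    masks: dict[str, np.ndarray]  # per-group supra-threshold edge masks
    network_table: pd.DataFrame
    nodal: dict[str, dict]  # per group: p, significant, strength, hubs
    surrogate_mean: np.ndarray
    subject_ids: list[str] = field(default_factory=list)


def analyze_edge_cohort(
    test: np.ndarray,
    retest: np.ndarray,
    group_labels: np.ndarray,
    parcellation: Parcellation,
    config: PipelineConfig,
    subject_ids: list[str] | None = None,
) -> CohortResults:
    """Run every analysis stage on aligned test/retest edge arrays.

    Subjects are rows (any group ordering); ``group_labels`` assigns each
    row to a group.  Groups are analysed separately for identifiability and
    ICC, then compared through the reconfiguration table and the
    group-unspecific surrogate null.
    """
    group_labels = np.asarray(group_labels, dtype=object)
    groups = tuple(pd.unique(pd.Series(group_labels)))
    rng_root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("identify", "bootstrap", "surrogate"), rng_root.spawn(3)
        )
    }

    identifiability: dict[str, dict] = {}
    icc_maps: dict[str, EdgewiseICC] = {}
    masks: dict[str, np.ndarray] = {}
    for group in groups:
        sel = group_labels == group
        g_test, g_retest = test[sel], retest[sel]
        t0 = time.perf_counter()
        matrix, metrics = identifiability_analysis(
            g_test,
            g_retest,
            n_permutations=config.permutation_runs,
            seed=streams["identify"],
            success_rule=config.success_rule,
        )
        paired = paired_self_other_test(metrics.iself, metrics.iothers)
        identifiability[group] = {
            "matrix": matrix,
            "metrics": metrics,
            "paired_test": paired,
        }
        subset = min(config.bootstrap_subset, int(sel.sum()))
        icc_maps[group] = bootstrap_group_icc(
            g_test,
            g_retest,
            subset_size=subset,
            n_runs=config.bootstrap_runs,
            seed=streams["bootstrap"],
            group=group,
        )
        masks[group] = binarize(icc_maps[group], config.icc_threshold).edges
        logger.info(
            "group %s: identifiability + ICC in %.2fs", group, time.perf_counter() - t0
        )

    from .edgewise_icc import OverlapMask

    network_table = network_reconfiguration_table(
        {g: OverlapMask(edges=masks[g], threshold=config.icc_threshold) for g in groups},
        parcellation,
        healthy_group=config.healthy_group if config.healthy_group in groups else groups[0],
    )

    draw = min(config.surrogate_draw, min(int((group_labels == g).sum()) for g in groups))
    null = surrogate_icc_null(
        {g: (test[group_labels == g], retest[group_labels == g]) for g in groups},
        real={g: icc_maps[g] for g in groups},
        draw_per_group=draw,
        n_runs=config.surrogate_runs,
        seed=streams["surrogate"],
    )
    nodal: dict[str, dict] = {}
    for group in groups:
        nf = nodal_fingerprint(icc_maps[group], null, group)
        from .nodal_hubs import hub_mask

        nodal[group] = {
            "p": nf.p_matrix,
            "significant": nf.significant,
            "strength": nf.strength,
            "hubs": hub_mask(nf.strength),
        }
    return CohortResults(
        groups=groups,
        identifiability=identifiability,
        icc=icc_maps,
        masks=masks,
        network_table=network_table,
        nodal=nodal,
        surrogate_mean=null.mean,
        subject_ids=list(subject_ids or []),
    )


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------


def _edges_from_timeseries(config: PipelineConfig, parcellation: Parcellation | None):
    series = fio.read_timeseries_dir(config.timeseries_dir, parcellation)
    full = [ts for ts in series if ts.session == "full"]
    if not full:
        raise ValueError("time-series input requires *_full.tsv files")
    if parcellation is None:
        raise ValueError("a parcellation is required for time-series input")

    kept = []
    if config.qc_dir:
        rules = QC_RULE_SETS[config.qc_rules]
        for ts in full:
            trace_path = Path(config.qc_dir) / f"{ts.subject_id}_qc.tsv"
            report = qc_tag_and_exclude(
                fio.read_qc_trace(trace_path, ts.subject_id),
                rules,
                config.subject_exclusion_fraction,
            )
            if report.exclude_subject:
                logger.info(
                    "excluding %s: %.0f%% volumes tagged",
                    ts.subject_id,
                    100 * report.tagged_fraction,
                )
            else:
                kept.append(ts)
    else:
        kept = full
    if len(kept) < 2:
        raise ValueError("fewer than 2 subjects survive QC")

    missing = np.vstack([ts.missing_regions() for ts in kept])
    retained, excluded = filter_rois(
        missing, parcellation.region_ids, config.roi_threshold
    )
    if excluded:
        logger.info("ROI filter excluded %d region(s): %s", len(excluded), excluded)
    keep_idx = [parcellation.region_ids.index(r) for r in retained]
    sub_parc = Parcellation(
        region_ids=tuple(retained),
        networks=tuple(parcellation.networks[i] for i in keep_idx),
    )

    test_rows, retest_rows, ids = [], [], []
    for ts in kept:
        ts_kept = dataclasses.replace(
            ts, data=ts.data[:, keep_idx], region_ids=sub_parc.region_ids
        )
        t, r = split_halves(ts_kept, config.split_policy)
        test_rows.append(vectorize_edges(compute_fc(t).matrix))
        retest_rows.append(vectorize_edges(compute_fc(r).matrix))
        ids.append(ts.subject_id)
    return np.vstack(test_rows), np.vstack(retest_rows), ids, sub_parc


def _edges_from_fc_dir(config: PipelineConfig, parcellation: Parcellation):
    directory = Path(config.fc_dir)
    test_files = sorted(directory.glob("*_test.csv"))
    if not test_files:
        raise FileNotFoundError(f"no *_test.csv matrices under {directory}")
    test_rows, retest_rows, ids = [], [], []
    for tf in test_files:
        subject = tf.stem.removesuffix("_test")
        rf = directory / f"{subject}_retest.csv"
        if not rf.exists():
            raise FileNotFoundError(f"missing retest matrix for {subject}")
        mt, _ = fio.read_matrix(
            tf, expect_labels=parcellation.region_ids, expect_symmetric=True
        )
        mr, _ = fio.read_matrix(
            rf, expect_labels=parcellation.region_ids, expect_symmetric=True
        )
        test_rows.append(vectorize_edges(mt))
        retest_rows.append(vectorize_edges(mr))
        ids.append(subject)
    return np.vstack(test_rows), np.vstack(retest_rows), ids, parcellation


def _group_lookup(config: PipelineConfig, ids: list[str]) -> np.ndarray:
    meta_path = None
    for base in (config.timeseries_dir, config.fc_dir):
        if base and (Path(base) / "metadata.tsv").exists():
            meta_path = Path(base) / "metadata.tsv"
    if meta_path is None:
        raise ValueError("metadata.tsv with subject_id/group columns is required")
    meta = fio.read_metadata(meta_path).set_index("subject_id")
    return np.asarray([meta.loc[s, "group"] for s in ids], dtype=object)


def run_pipeline(config: PipelineConfig) -> CohortResults:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    modes = [m for m in (config.timeseries_dir, config.fc_dir, config.simulate) if m]
    if len(modes) != 1:
        raise ValueError(
            "config must set exactly one of timeseries_dir, fc_dir or simulate"
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_yaml(outdir / "config.yaml", config.to_dict())

    if config.simulate:
        spec = SyntheticModelSpec.from_dict(config.simulate)
        panel = generate_edge_panel(spec)
        test, retest, ids = panel.test, panel.retest, panel.subject_ids
        groups = panel.groups
        parcellation = spec.parcellation()
    else:
        if config.parcellation_path is None:
            raise ValueError("parcellation_path is required for file input")
        parcellation = fio.read_parcellation(config.parcellation_path)
        if config.timeseries_dir:
            test, retest, ids, parcellation = _edges_from_timeseries(config, parcellation)
        else:
            test, retest, ids, parcellation = _edges_from_fc_dir(config, parcellation)
        groups = _group_lookup(config, ids)

    results = analyze_edge_cohort(
        test, retest, groups, parcellation, config, subject_ids=ids
    )
    _write_results(results, parcellation, outdir)
    return results


def _write_results(
    results: CohortResults, parcellation: Parcellation, outdir: Path
) -> None:
    region_ids = list(parcellation.region_ids)
    metrics_payload = {}
    for group in results.groups:
        bundle = results.identifiability[group]
        subject_axis = [f"s{i}" for i in range(bundle["matrix"].shape[0])]
        fio.write_matrix(
            outdir / f"identifiability_{group}.csv", bundle["matrix"], subject_axis
        )
        icc = results.icc[group]
        fio.write_matrix(outdir / f"icc_{group}.csv", icc.to_matrix(), region_ids)
        fio.write_mask(
            outdir / f"mask_{group}.csv",
            EdgewiseICC(results.masks[group].astype(float)).to_matrix().astype(int),
            region_ids,
        )
        nodal = results.nodal[group]
        pd.DataFrame(
            {
                "region_id": region_ids,
                "strength": nodal["strength"],
                "hub": nodal["hubs"].astype(int),
            }
        ).to_csv(outdir / f"nodal_{group}.tsv", sep="\t", index=False)
        paired = bundle["paired_test"]
        metrics_payload[group] = {
            **bundle["metrics"].to_dict(),
            "paired_test": {
                "chosen": paired.chosen,
                "statistic": paired.statistic,
                "p_value": paired.p_value,
                "shapiro_p": paired.shapiro_p,
            },
        }
    fio.write_json(outdir / "metrics.json", metrics_payload)
    results.network_table.to_csv(outdir / "network_stats.csv", index=False)
    fio.write_matrix(
        outdir / "surrogate_icc_mean.csv",
        EdgewiseICC(results.surrogate_mean).to_matrix(),
        region_ids,
    )
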