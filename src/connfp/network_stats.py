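"""Within- vs between-network distribution of supra-threshold fingerprint edges.

Given a binary edge mask (supra-threshold ICC) and a parcellation into the
eight resting-state networks, each network ``net`` with m regions out of R
has m(m-1)/2 possible within-network edges and m(R-m) possible between-network
edges (edges with exactly one endpoint in the network).  Per block we report:

* ICC_o: the count of supra-threshold edges in the block;
* P_ICCo: that count divided by the block's total edge count;
* R(net) = P_ICCo(disease) / P_ICCo(health) - 1: fold-change relative to the
  healthy reference (positive = fingerprint gain in disease);
* a 2x2 chi-square of homogeneity comparing supra/sub-threshold proportions
  within vs between the network, Bonferroni-corrected over the 8 networks.

Between-block edges are attributed to both endpoint networks, so summing
between counts over networks double-counts each between edge; the global
conservation identity is sum(within) + sum(between)/2 = total supra edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Parcellation, edge_network_labels
from .edgewise_icc import OverlapMask


@dataclass
class Chi2Result:
    chi2: float
    p_value: float
    p_bonferroni: float
    n_comparisons: int


def block_edge_counts(mask: OverlapMask, parcellation: Parcellation) -> pd.DataFrame:
    """Per-network supra-threshold edge counts and proportions.

    Returns a DataFrame indexed by network with columns ``m`` (regions),
    ``within_total``, ``between_total``, ``within_count``, ``between_count``,
    ``p_within`` and ``p_between``.
    """
    edges = mask.edges
    R = parcellation.n_regions
    if len(edges) != R * (R - 1) // 2:
        raise ValueError("mask does not match parcellation size")
    net_a, net_b = edge_network_labels(parcellation)
    nets = sorted(set(parcellation.networks), key=parcellation.networks.index)
    rows = []
    for net in nets:
        a, b = net_a == net, net_b == net
        within, between = a & b, a ^ b
        m = int((parcellation.network_array() == net).sum())
        wt, bt = m * (m - 1) // 2, m * (R - m)
        wc, bc = int(edges[within].sum()), int(edges[between].sum())
        rows.append(
            {
                "network": net,
                "m": m,
                "within_total": wt,
                "between_total": bt,
                "within_count": wc,
                "between_count": bc,
                "p_within": wc / wt if wt else np.nan,
                "p_between": bc / bt if bt else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("network")


def ratio_vs_health(p_disease: float, p_health: float) -> float:
    """Fold-change of a supra-threshold proportion relative to health.

    R = P_disease / P_health - 1; zero means no change.  Undefined when the
    healthy proportion is zero — returned as NaN with a warning.
    """
    if p_health == 0:
        warnings.warn("healthy proportion is zero; ratio undefined (NaN)")
        return float("nan")
    return p_disease / p_health - 1.0


def within_between_chisq(
    within: tuple[int, int],
    between: tuple[int, int],
    n_comparisons: int = 8,
    correction: bool = False,
) -> Chi2Result:
    """Chi-square of homogeneity: supra/sub-threshold proportions, within vs
    between a network.

    ``within`` and ``between`` are (supra_count, sub_count) pairs.  No
    continuity correction by default; p is Bonferroni-multiplied by
    ``n_comparisons`` (default 8, one comparison per network) and capped at 1.
    A zero marginal leaves the statistic undefined (NaN).
    """
    table = np.asarray([within, between], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero marginal in contingency table; chi-square undefined")
        return Chi2Result(float("nan"), float("nan"), float("nan"), n_comparisons)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return Chi2Result(
        chi2=float(chi2),
        p_value=float(p),
        p_bonferroni=min(1.0, n_comparisons * float(p)),
        n_comparisons=n_comparisons,
    )


def network_reconfiguration_table(
    masks_by_group: Mapping[str, OverlapMask],
    parcellation: Parcellation,
    healthy_group: str = "CU",
    n_comparisons: int = 8,
) -> pd.DataFrame:
    """Per-group, per-network reconfiguration statistics (one row per
    group x network): P_ICCo within/between, R(net) relative to the healthy
    group, and the within-vs-between chi-square with Bonferroni correction.
    """
    if healthy_group not in masks_by_group:
        raise ValueError(f"healthy group {healthy_group!r} missing from masks")
    counts = {g: block_edge_counts(m, parcellation) for g, m in masks_by_group.items()}
    healthy = counts[healthy_group]
    rows = []
    for group, table in counts.items():
        for net, row in table.iterrows():
            chi = within_between_chisq(
                (row.within_count, row.within_total - row.within_count),
                (row.between_count, row.between_total - row.between_count),
                n_comparisons=n_comparisons,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r_within = (
                    np.nan
                    if group == healthy_group
                    else ratio_vs_health(row.p_within, healthy.loc[net, "p_within"])
                )
                r_between = (
                    np.nan
                    if group == healthy_group
                    else ratio_vs_health(row.p_between, healthy.loc[net, "p_between"])
                )
            rows.append(
                {
                    "group": group,
                    "network": net,
                    "p_within": row.p_within,
                    "p_between": row.p_between,
                    "within_count": row.within_count,
                    "between_count": row.between_count,
                    "r_within": r_within,
                    "r_between": r_between,
                    "chi2": chi.chi2,
                    "p": chi.p_value,
                    "p_bonferroni": chi.p_bonferroni,
                }
            )
    return pd.DataFrame(rows)
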