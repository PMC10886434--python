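"""Condition-dependent analysis of the activity (A) matrix.

The A matrix gives each iModulon's activity in every sample, relative to
the reference condition. This module summarizes activities by condition,
ranks condition-responsive iModulons for a contrast, builds weighted
TF-gene correlation networks, quantifies trade-offs between gene
programs as activity-activity Pearson correlations, and compares
aggregate (total log) expression of gene sets across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .compendium import ExpressionCompendium
from .extraction import IModulon


@dataclass
class ActivityProfile:
    im_id: str
    activities: pd.Series  # per sample
    condition_means: pd.Series
    condition_sds: pd.Series  # NaN for singleton conditions


def condition_activity_table(
    A: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping: str = "condition",
) -> list[ActivityProfile]:
    """Per-iModulon, per-condition mean activity and standard deviation.

    Spread is reported as NaN (absent) for singleton conditions rather
    than zero.
    """
    if grouping not in metadata.columns:
        raise KeyError(f"grouping key {grouping!r} not in metadata")
    cond = metadata.set_index("sample_id")[grouping].astype(str)
    cond = cond.loc[A.columns]
    profiles = []
    for im_id, row in A.iterrows():
        grouped = row.groupby(cond)
        means = grouped.mean()
        sds = grouped.std(ddof=1)  # NaN when n == 1
        profiles.append(ActivityProfile(str(im_id), row, means, sds))
    return profiles


def activity_heatmap_table(profiles: list[ActivityProfile]) -> pd.DataFrame:
    """Conditions x iModulons table of mean activities (heatmap export)."""
    return pd.DataFrame({p.im_id: p.condition_means for p in profiles})


def rank_active_ims(
    profiles: list[ActivityProfile],
    contrast: tuple[str, str],
    top_k: int = 4,
) -> pd.DataFrame:
    """Rank iModulons by |mean activity difference| between two conditions.

    A z-like score (difference / pooled within-condition sd) is attached
    when replicate spreads exist; the top ``top_k`` are flagged active.
    This formalizes the visual reading of an activity heatmap as a ranked
    contrast.
    """
    cond, ref = contrast
    rows = []
    for p in profiles:
        for c in (cond, ref):
            if c not in p.condition_means.index:
                raise KeyError(f"condition {c!r} absent from activity profiles")
        diff = float(p.condition_means[cond] - p.condition_means[ref])
        sds = [p.condition_sds.get(c, np.nan) for c in (cond, ref)]
        pooled = np.sqrt(np.nanmean(np.square(sds))) if not all(np.isnan(sds)) else np.nan
        z = diff / pooled if pooled and pooled > 0 else np.nan
        rows.append({"im_id": p.im_id, "activity_difference": diff, "z_score": z})
    table = pd.DataFrame(rows)
    table["abs_difference"] = table["activity_difference"].abs()
    table = table.sort_values("abs_difference", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table["active"] = table["rank"] <= top_k
    return table.reset_index(drop=True)


def build_network(
    tf_genes: list[str],
    im: IModulon,
    compendium: ExpressionCompendium,
    p_cutoff: float = 0.05,
) -> nx.Graph:
    """Weighted TF-member correlation network.

    Nodes are typed ('tf' or 'member'); edges carry the signed Pearson r
    (negative edges flag repressor candidates) and are kept only at
    p < ``p_cutoff``. Constant expression rows are skipped with a note.
    """
    g = nx.Graph()
    skipped = []
    members = sorted(im.members)
    for tf in tf_genes:
        if tf not in compendium.values.index:
            raise KeyError(f"TF gene {tf!r} not in compendium")
        g.add_node(tf, kind="tf")
    for m in members:
        if m not in compendium.values.index:
            raise KeyError(f"member gene {m!r} not in compendium")
        g.add_node(m, kind="member")
    for tf in tf_genes:
        tf_row = compendium.values.loc[tf].to_numpy(dtype=float)
        for m in members:
            if m == tf:
                continue
            row = compendium.values.loc[m].to_numpy(dtype=float)
            if np.ptp(tf_row) == 0 or np.ptp(row) == 0:
                skipped.append((tf, m))
                continue
            r, p = stats.pearsonr(tf_row, row)
            if p < p_cutoff:
                g.add_edge(tf, m, weight=float(r), p=float(p))
    g.graph["p_cutoff"] = p_cutoff
    g.graph["skipped_constant_pairs"] = skipped
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "r": d["weight"], "p": d["p"]}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p"])


def tradeoff_correlations(
    A: pd.DataFrame,
    im_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson r and two-sided p between pairs of activity rows, across
    all samples — the activity-level trade-off statistic."""
    rows = []
    for a, b in im_pairs:
        for im_id in (a, b):
            if im_id not in A.index:
                raise KeyError(f"iModulon {im_id!r} not in A matrix")
        if a == b:
            rows.append({"im_a": a, "im_b": b, "r": 1.0, "p": 0.0})
            continue
        r, p = stats.pearsonr(A.loc[a], A.loc[b])
        rows.append({"im_a": a, "im_b": b, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def aggregate_expression(
    compendium: ExpressionCompendium,
    gene_set_a: set[str],
    gene_set_b: set[str],
    grouping: str = "condition",
) -> dict:
    """Total log expression of two gene programs per sample and per
    condition, with the Pearson correlation between the two totals.

    Missing genes are excluded (and reported); expression must be in the
    log state so totals are sums of log values.
    """
    if compendium.state not in ("log", "centered"):
        raise ValueError("aggregate_expression expects log-state values")
    if not gene_set_a or not gene_set_b:
        raise ValueError("gene sets must be nonempty")
    present = set(compendium.values.index)
    missing = sorted((gene_set_a | gene_set_b) - present)
    a_genes = sorted(gene_set_a & present)
    b_genes = sorted(gene_set_b & present)
    if not a_genes or not b_genes:
        raise ValueError("no genes of a set are present in the compendium")
    totals = pd.DataFrame(
        {
            "total_a": compendium.values.loc[a_genes].sum(axis=0),
            "total_b": compendium.values.loc[b_genes].sum(axis=0),
        }
    )
    cond = compendium.metadata.set_index("sample_id")[grouping].astype(str)
    by_condition = totals.groupby(cond.loc[totals.index]).mean()
    if totals["total_a"].nunique() > 1 and totals["total_b"].nunique() > 1:
        r, p = (float(x) for x in stats.pearsonr(totals["total_a"], totals["total_b"]))
    else:
        r = 1.0 if a_genes == b_genes else float("nan")
        p = float("nan")
    return {
        "per_sample": totals,
        "per_condition": by_condition,
        "r": r,
        "p": p,
        "missing_genes": missing,
    }
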