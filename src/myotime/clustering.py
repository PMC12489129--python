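"""Temporal-profile clustering of significant features and shape labeling.

The clustering half of the two-step time-course analysis: features passing
the likelihood-ratio gate are summarized as z-scale per-day profiles
(batch-removed, averaged over cell lines and replicates), grouped by Ward
hierarchical clustering into k=5 clusters, and the cluster centroids are
named by deterministic shape rules (Down, Early-Down, Early-Up, Up, Up-Down,
Mix).  Cross-tabulations relate isoform clusters to their parent genes'
clusters and windowed fold-change directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io_formats import CountMatrix
from .normalization import normalize_chain


def temporal_profiles(
    cm: CountMatrix,
    lrt_results: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-day mean z-scale expression for features passing the LRT gate.

    Normalizes (TMM -> logCPM -> cell-line batch removal -> per-gene z),
    averages columns within each day across cell lines and replicates, and
    restricts to features with ``padj <= alpha`` when results are supplied.
    """
    z = normalize_chain(cm).values
    days = sorted(pd.unique(cm.metadata["day"]))
    prof = pd.DataFrame(
        {d: z.loc[:, cm.metadata["day"] == d].mean(axis=1) for d in days}
    )
    if lrt_results is not None:
        keep = lrt_results.index[lrt_results["padj"] <= alpha]
        prof = prof.loc[prof.index.intersection(keep)]
    return prof


@dataclass
class ClusterResult:
    assignments: pd.Series    # feature -> cluster index (0..k-1)
    labels: dict[int, str]    # cluster index -> shape label
    centroids: pd.DataFrame   # cluster x day


def cluster_profiles(profiles: pd.DataFrame, k: int = 5) -> tuple[pd.Series, pd.DataFrame]:
    """Ward/Euclidean agglomerative clustering cut at ``k`` clusters.

    Rows are sorted by feature id before linkage so the partition does not
    depend on input order.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    prof = profiles.sort_index()
    Z = sch.linkage(prof.to_numpy(), method="ward")
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by order of first appearance for determinism
    remap: dict[int, int] = {}
    for c in raw:
        if c not in remap:
            remap[c] = len(remap)
    assign = pd.Series([remap[c] for c in raw], index=prof.index, name="cluster")
    centroids = prof.groupby(assign).mean()
    return assign, centroids


def _label_margins(c: np.ndarray, theta: float) -> dict[str, float]:
    """Rule margins per shape label; a label applies iff its margin > 0.

    Rules operate on z-scale centroids over days 0..5 via the contrasts
    d1 = c(1)-c(0), dmid = c(3)-c(1), dlate = c(5)-c(3).
    """
    d1 = c[1] - c[0]
    dmid = c[3] - c[1]
    dlate = c[5] - c[3]
    rise03 = c[3] - c[0]
    diffs_to3 = np.diff(c[:4])
    mono_down = (diffs_to3 <= 1e-9).all()
    mono_up = (diffs_to3 >= -1e-9).all()

    margins: dict[str, float] = {}
    # Up-Down: initial rise then late fall
    margins["UpDown"] = min(d1 - theta, -dlate - theta)
    # Early-Down: immediate drop then stable
    margins["EarlyDown"] = min(-d1 - theta, theta - abs(dmid))
    # Early-Up: immediate rise then stable
    margins["EarlyUp"] = min(d1 - theta, theta - abs(dmid))
    # Down: sustained non-increasing decline to day 3
    down_m = max(-d1 - theta, -dmid - theta)
    margins["Down"] = down_m if mono_down else -np.inf
    # Up: cumulative rise to day 3 (gradual, or strictly monotone)
    up_m = rise03 - theta if (d1 <= theta or mono_up) else -np.inf
    margins["Up"] = up_m
    return margins


LABEL_PRECEDENCE = ("UpDown", "EarlyDown", "EarlyUp", "Down", "Up")


def label_clusters(centroids: pd.DataFrame, theta: float = 0.5) -> dict[int, str]:
    """Name each centroid by shape rules; unmatched centroids become Mix.

    Labels are assigned in precedence order with ties broken by the largest
    rule margin; if two centroids claim the same label the larger margin
    wins and the loser falls back to Mix.
    """
    picks: dict[int, tuple[str, float]] = {}
    for idx, row in centroids.iterrows():
        margins = _label_margins(row.to_numpy(dtype=float), theta)
        best_label, best_margin = "Mix", 0.0
        for lab in LABEL_PRECEDENCE:
            if margins[lab] > 0:
                best_label, best_margin = lab, margins[lab]
                break
        picks[idx] = (best_label, best_margin)

    # resolve duplicate labels: keep the largest margin, losers -> Mix
    out: dict[int, str] = {}
    by_label: dict[str, list[tuple[float, int]]] = {}
    for idx, (lab, marg) in picks.items():
        by_label.setdefault(lab, []).append((marg, idx))
    for lab, entries in by_label.items():
        if lab == "Mix" or len(entries) == 1:
            for _, idx in entries:
                out[idx] = lab
            continue
        entries.sort(reverse=True)
        out[entries[0][1]] = lab
        for _, idx in entries[1:]:
            out[idx] = "Mix"
    return out


def cluster_and_label(profiles: pd.DataFrame, k: int = 5, theta: float = 0.5) -> ClusterResult:
    assign, centroids = cluster_profiles(profiles, k)
    labels = label_clusters(centroids, theta)
    return ClusterResult(assign, labels, centroids)


def cross_tabulate(
    isoform_assignments: pd.Series,
    gene_assignments: pd.Series,
    t2g: pd.Series,
) -> pd.DataFrame:
    """Contingency table of isoforms per (isoform cluster, parent-gene cluster).

    Isoforms whose gene carries no assignment are counted in an
    ``unclustered`` column; an isoform with no gene mapping is an error.
    """
    if isoform_assignments.empty or gene_assignments.empty:
        raise ValueError("both partitions must be nonempty")
    missing = [i for i in isoform_assignments.index if i not in t2g.index]
    if missing:
        raise ValueError(f"isoform without gene mapping: {missing[0]!r}")
    genes = t2g.loc[isoform_assignments.index]
    gene_cluster = genes.map(gene_assignments).fillna("unclustered")
    table = pd.crosstab(isoform_assignments, gene_cluster)
    table.index.name = "isoform_cluster"
    table.columns.name = "gene_cluster"
    return table


def direction_concordance(
    isoform_assignments: pd.Series,
    gene_window_results: pd.DataFrame,
    t2g: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per isoform cluster, counts of parent genes up/down/non-significant.

    A parent gene is "up" when its windowed slope is positive with
    ``padj < alpha``, "down" when negative, else "ns" (including genes with
    no windowed result).
    """
    genes = t2g.loc[isoform_assignments.index]
    states = []
    for g in genes:
        if g in gene_window_results.index:
            row = gene_window_results.loc[g]
            if pd.notna(row["padj"]) and row["padj"] < alpha:
                states.append("up" if row["beta"] > 0 else "down")
                continue
        states.append("ns")
    table = pd.crosstab(
        isoform_assignments, pd.Series(states, index=isoform_assignments.index)
    )
    for col in ("up", "down", "ns"):
        if col not in table.columns:
            table[col] = 0
    table.index.name = "isoform_cluster"
    return table[["up", "down", "ns"]]
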