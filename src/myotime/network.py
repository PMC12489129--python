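"""Thresholded protein-interaction network from pairwise confidence scores.

Pairwise interface-confidence (iPTM) scores for n proteins cover all
n(n+1)/2 unordered pairs including self-pairs; an edge is drawn when the
score strictly exceeds the threshold (default 0.7), a self-loop marks a
candidate homodimer, and connected components are reported with a
homodimer-only flag for singleton components whose only evidence is a
self-loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

IPTM_THRESHOLD = 0.7


def pair_count(n: int) -> int:
    """Unordered pairs of n proteins including self-pairs: n(n+1)/2."""
    if n < 1:
        raise ValueError("need at least one protein")
    return n * (n + 1) // 2


def validate_iptm(table: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Validate (and symmetrize, by maximum) a pairwise score table."""
    if list(table.index) != list(table.columns):
        raise ValueError("iPTM table must be square with matching ids")
    arr = table.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("iPTM table contains missing values")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("iPTM scores must lie in [0, 1]")
    if np.abs(arr - arr.T).max() > tol:
        # direction-dependent scores from the prediction tool: keep the max
        arr = np.maximum(arr, arr.T)
    return pd.DataFrame(arr, index=table.index, columns=table.columns)


@dataclass
class ThresholdedNetwork:
    graph: nx.Graph             # non-self edges only
    homodimers: list[str]       # nodes with a self-loop above threshold
    retained_nodes: list[str]   # nodes with any incident evidence
    dropped_nodes: list[str]    # nodes with no edge or self-loop


def threshold_network(
    table: pd.DataFrame, threshold: float = IPTM_THRESHOLD
) -> ThresholdedNetwork:
    """Edges where score > threshold (strict); isolated nodes are dropped but listed."""
    table = validate_iptm(table)
    ids = list(table.index)
    arr = table.to_numpy()
    g = nx.Graph()
    homodimers = []
    for i, a in enumerate(ids):
        if arr[i, i] > threshold:
            homodimers.append(a)
        for j in range(i + 1, len(ids)):
            if arr[i, j] > threshold:
                g.add_edge(a, ids[j], score=float(arr[i, j]))
    retained = sorted(set(g.nodes) | set(homodimers))
    dropped = [a for a in ids if a not in retained]
    return ThresholdedNetwork(g, homodimers, retained, dropped)


def components(net: ThresholdedNetwork) -> pd.DataFrame:
    """Connected components plus self-loop-only singletons.

    Each row is one component with its size, member list, a
    ``homodimer_only`` flag (singleton whose only evidence is a self-loop)
    and whether the component is a clique in the thresholded graph.
    """
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    for h in net.homodimers:
        if h not in net.graph.nodes:
            comps.append([h])
    comps.sort(key=lambda c: (-len(c), c))
    rows = []
    for c in comps:
        homodimer_only = len(c) == 1 and c[0] not in net.graph.nodes
        if len(c) <= 1:
            clique = True
        else:
            sub = net.graph.subgraph(c)
            clique = sub.number_of_edges() == len(c) * (len(c) - 1) // 2
        rows.append(
            {
                "size": len(c),
                "members": ",".join(c),
                "homodimer_only": homodimer_only,
                "is_clique": clique,
            }
        )
    return pd.DataFrame(rows)
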