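"""Opt-in strict cluster re-check before flagging.

Upstream cluster membership is normally trusted as given — clustering
mistakes then propagate into flagging (a documented failure mode of the
workflow).  Strict mode re-applies the manual-annotation criterion inside
each cluster before any flagging: members must be connected by edges with
Pearson r >= min_pearson on biological heights AND |dRT| <= cluster_rt_tol;
components that fall apart become separate clusters.  This trades a little
recall (legitimately co-clustered but borderline members) for precision.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .model import Attribution, PeakTable
from .prefilter import FilterConfig


def strict_filter_clusters(table: PeakTable, cfg: FilterConfig) -> int:
    """Split each cluster by the strict edge rule (in place).

    Returns the number of clusters that were split.
    """
    bio = table.biological_ids
    by_cluster: dict[str, list] = {}
    for f in table.features:
        if f.attribution == Attribution.INTERFERENCE or f.cluster_id is None:
            continue
        by_cluster.setdefault(f.cluster_id, []).append(f)

    n_split = 0
    for cid, members in sorted(by_cluster.items()):
        if len(members) < 2:
            continue
        heights = np.array([[f.heights.get(s, 0.0) for s in bio] for f in members])
        variable = heights.std(axis=1) > 0
        graph = nx.Graph()
        graph.add_nodes_from(f.feature_id for f in members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if not (variable[a] and variable[b]):
                    continue
                if abs(members[a].rt - members[b].rt) > cfg.cluster_rt_tol:
                    continue
                r = np.corrcoef(heights[a], heights[b])[0, 1]
                if r >= cfg.min_pearson:
                    graph.add_edge(members[a].feature_id, members[b].feature_id)
        comps = sorted(
            nx.connected_components(graph),
            key=lambda c: min(f.mz for f in members if f.feature_id in c),
        )
        if len(comps) > 1:
            n_split += 1
            for i, comp in enumerate(comps, start=1):
                for f in members:
                    if f.feature_id in comp:
                        f.cluster_id = f"{cid}.s{i}"
            table.log(f"strict mode split cluster {cid} into {len(comps)} parts")
    return n_split
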