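"""Generic cleaning upstream of feature rating.

A minimal, self-contained counterpart of the cleaning normally done with
MS-CleanR: internal-standard normalisation, blank filtering, within-class
RSD filtering, and correlation/RT feature clustering.  Filters never delete
rows — removed features are attributed ``interference`` and stay in the
table for audit; downstream stages skip them.

Clustering builds an undirected graph with an edge between two features
when they co-elute (|ΔRT| ≤ ``cluster_rt_tol``) and their biological-sample
height vectors correlate (Pearson r ≥ ``min_pearson``); clusters are the
connected components, so correlation is effectively closed transitively,
as aligned-table clustering tools do.  If the input table already carries
cluster ids from an upstream tool, they are honoured; re-clustering is
opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigError, ValidationError
from .model import Attribution, FeatureCluster, PeakTable, SampleRole

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the generic filters and clustering.

    min_blank_ratio
        a feature survives if its maximum biological height is at least
        this multiple of its mean blank height (0 disables the filter);
    max_class_rsd
        a feature survives if at least one biological class with >= 2
        replicates has relative standard deviation (sd/mean) below this;
    min_pearson / cluster_rt_tol
        the edge rule for feature clustering.
    """

    min_blank_ratio: float = 0.8
    max_class_rsd: float = 0.30
    min_pearson: float = 0.8
    cluster_rt_tol: float = 0.03

    def __post_init__(self) -> None:
        if self.min_blank_ratio < 0:
            raise ConfigError("min_blank_ratio must be >= 0")
        if self.max_class_rsd <= 0:
            raise ConfigError("max_class_rsd must be > 0")
        if not (-1.0 <= self.min_pearson <= 1.0):
            raise ConfigError("min_pearson must be in [-1, 1]")
        if self.cluster_rt_tol <= 0:
            raise ConfigError("cluster_rt_tol must be > 0")


def normalize_internal_standard(table: PeakTable, is_feature_id: str) -> PeakTable:
    """Divide heights by the internal standard's height per sample, rescale by
    the IS median over biological samples, and drop the IS row.

    Only biological and QC samples are normalised; blank heights are left
    as acquired (the IS is typically absent from the solvent blank).
    """
    out = table.copy()
    try:
        is_feat = out.feature(is_feature_id)
    except KeyError:
        raise ValidationError(f"internal standard {is_feature_id!r} not in table") from None
    norm_samples = out.biological_ids + out.qc_ids
    missing = [s for s in norm_samples if is_feat.heights.get(s, 0.0) <= 0]
    if missing:
        raise ValidationError(
            f"internal standard {is_feature_id!r} has no signal in samples {missing}"
        )
    bio_heights = [is_feat.heights[s] for s in out.biological_ids]
    scale = float(np.median(bio_heights))
    for f in out.features:
        if f.feature_id == is_feature_id:
            continue
        for s in norm_samples:
            f.heights[s] = f.heights.get(s, 0.0) / is_feat.heights[s] * scale
    out.features = [f for f in out.features if f.feature_id != is_feature_id]
    out.log(f"normalized to internal standard {is_feature_id} (median height {scale:g})")
    return out


def blank_filter(table: PeakTable, cfg: FilterConfig) -> PeakTable:
    """Attribute features dominated by the solvent blank as interference.

    Retention rule: max biological height >= min_blank_ratio x mean blank
    height.  A feature absent from the blank always survives; with ratio 0
    the filter is disabled.  With no blank samples declared the filter is a
    warning no-op.
    """
    out = table.copy()
    blanks = out.blank_ids
    if not blanks:
        logger.warning("blank_filter: no blank samples declared; skipping")
        out.log("blank_filter skipped (no blanks)")
        return out
    bio = out.biological_ids
    removed = 0
    for f in out.features:
        if f.attribution != Attribution.UNRATED:
            continue
        blank_mean = float(np.mean([f.heights.get(s, 0.0) for s in blanks]))
        bio_max = max((f.heights.get(s, 0.0) for s in bio), default=0.0)
        if bio_max < cfg.min_blank_ratio * blank_mean:
            f.set_attribution(Attribution.INTERFERENCE)
            removed += 1
    out.log(f"blank_filter removed {removed} features (ratio {cfg.min_blank_ratio})")
    return out


def _rsd(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return np.inf
    return float(values.std(ddof=1) / mean)


def rsd_filter(table: PeakTable, cfg: FilterConfig) -> PeakTable:
    """Attribute features unstable in every sample class as interference.

    Retention rule: the best (lowest) within-class RSD over classes with
    >= 2 replicates is <= max_class_rsd.  Classes with a single replicate
    carry no spread information and are skipped; if no class has
    replicates the filter is a warning no-op.
    """
    out = table.copy()
    classes = {c: ids for c, ids in out.classes().items() if len(ids) >= 2}
    if not classes:
        logger.warning("rsd_filter: no biological class has >= 2 replicates; skipping")
        out.log("rsd_filter skipped (no replicated classes)")
        return out
    removed = 0
    for f in out.features:
        if f.attribution != Attribution.UNRATED:
            continue
        best = min(
            _rsd(np.array([f.heights.get(s, 0.0) for s in ids], dtype=float))
            for ids in classes.values()
        )
        if not best <= cfg.max_class_rsd:
            f.set_attribution(Attribution.INTERFERENCE)
            removed += 1
    out.log(f"rsd_filter removed {removed} features (max RSD {cfg.max_class_rsd})")
    return out


def cluster_features(table: PeakTable, cfg: FilterConfig) -> list[FeatureCluster]:
    """Partition active features into co-elution/correlation clusters.

    Edge rule: |rt_i - rt_j| <= cluster_rt_tol AND Pearson r of
    biological-sample height vectors >= min_pearson; clusters are the
    connected components (singletons included).  Constant-height features
    have undefined correlation and become singletons.  Cluster ids are
    deterministic, ordered by each cluster's lowest member m/z, so the
    partition is invariant under row permutation of the input.
    """
    bio = table.biological_ids
    if len(bio) < 3:
        raise ValidationError(
            f"clustering needs >= 3 biological samples, have {len(bio)}"
        )
    active = [f for f in table.features if f.attribution != Attribution.INTERFERENCE]
    heights = np.array([[f.heights.get(s, 0.0) for s in bio] for f in active], dtype=float)
    variable = heights.std(axis=1) > 0
    for f, ok in zip(active, variable):
        if not ok:
            logger.warning(
                "feature %s has constant heights; correlation undefined, kept as singleton",
                f.feature_id,
            )

    graph = nx.Graph()
    graph.add_nodes_from(f.feature_id for f in active)
    if len(active) >= 2 and variable.any():
        idx = np.flatnonzero(variable)
        corr = np.corrcoef(heights[idx])
        corr = np.atleast_2d(corr)
        rts = np.array([active[i].rt for i in idx])
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if (
                    abs(rts[a] - rts[b]) <= cfg.cluster_rt_tol
                    and corr[a, b] >= cfg.min_pearson
                ):
                    graph.add_edge(active[idx[a]].feature_id, active[idx[b]].feature_id)

    mz = {f.feature_id: f.mz for f in active}
    comps = sorted(nx.connected_components(graph), key=lambda c: min(mz[i] for i in c))
    clusters = [
        FeatureCluster(f"C{i:04d}", frozenset(comp)) for i, comp in enumerate(comps, start=1)
    ]
    return clusters


def apply_clusters(table: PeakTable, clusters: list[FeatureCluster]) -> None:
    """Write cluster ids back onto the table's features (in place)."""
    assignment = {fid: c.cluster_id for c in clusters for fid in c.member_ids}
    for f in table.features:
        f.cluster_id = assignment.get(f.feature_id, f.cluster_id)
    table.log(f"assigned {len(clusters)} clusters")


def clusters_from_table(table: PeakTable) -> list[FeatureCluster]:
    """Recover FeatureCluster objects from cluster ids already on the table
    (upstream-tool clusters), skipping interference features."""
    by_id: dict[str, set[str]] = {}
    for f in table.features:
        if f.attribution == Attribution.INTERFERENCE:
            continue
        if f.cluster_id is None:
            raise ValidationError(
                f"feature {f.feature_id!r} has no cluster id; run cluster_features first"
            )
        by_id.setdefault(f.cluster_id, set()).add(f.feature_id)
    return [FeatureCluster(cid, frozenset(m)) for cid, m in sorted(by_id.items())]
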