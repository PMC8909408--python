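"""Table-wide feature rating.

Per feature cluster: adduct-correlation flagging (TRFs), in-source
fragment removal, then SRF classification of the survivors.  The result is
a total partition of the input features into TRF / SRF / fragment /
interference.  From each TRF correlation group the most intense member is
selected as the group's representative; representatives plus SRFs form the
final, cleaned peak table.

"Most intense" defaults to the mean peak height over biological samples;
ties break to the lower m/z, then the lexicographically smaller feature id,
so rating is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adducts import CorrelationRule, flag_cluster
from .errors import ValidationError
from .fragments import DEFAULT_FRAGMENT_TOLERANCE, FragmentCall, classify_srf, screen_fragments
from .model import Attribution, PeakTable
from .prefilter import clusters_from_table

INTENSITY_METRICS = ("mean_biological", "max_sample", "mean_qc")


@dataclass
class RatingResult:
    """The final partition plus TRF groups, representatives, and final ids."""

    attributions: dict[str, Attribution] = field(default_factory=dict)
    adduct_labels: dict[str, str] = field(default_factory=dict)
    groups: dict[str, set[str]] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)
    fragment_calls: list[FragmentCall] = field(default_factory=list)
    final_ids: list[str] = field(default_factory=list)


@dataclass
class RatingSummary:
    n_total: int
    n_trf: int
    n_srf: int
    n_fragment: int
    n_interference: int
    real_fraction: float
    fragment_fraction: float
    final_size: int
    empty: bool = False


def _intensity(fid: str, table: PeakTable, metric: str) -> float:
    f = table.feature(fid)
    if metric == "mean_biological":
        ids = table.biological_ids
        return float(np.mean([f.heights.get(s, 0.0) for s in ids])) if ids else 0.0
    if metric == "max_sample":
        return max(f.heights.values(), default=0.0)
    if metric == "mean_qc":
        ids = table.qc_ids
        return float(np.mean([f.heights.get(s, 0.0) for s in ids])) if ids else 0.0
    raise ValidationError(f"unknown intensity metric {metric!r}; choose from {INTENSITY_METRICS}")


def select_representative(
    group: Sequence[str] | set[str], table: PeakTable, metric: str = "mean_biological"
) -> str:
    """The most intense member of a TRF group (ties: lower m/z, then id)."""
    if not group:
        raise ValidationError("empty TRF group")
    return min(
        group,
        key=lambda fid: (-_intensity(fid, table, metric), table.feature(fid).mz, fid),
    )


def rate_table(
    table: PeakTable,
    rules: Sequence[CorrelationRule],
    fragment_tolerance: float = DEFAULT_FRAGMENT_TOLERANCE,
    intensity_metric: str = "mean_biological",
) -> RatingResult:
    """Run flagging -> fragment screening -> SRF classification over all clusters.

    The table must be clustered (every non-interference feature carries a
    cluster id, from an upstream tool or from ``prefilter.cluster_features``).
    Attributions, adduct labels and group ids are written back onto the
    table's features; the returned RatingResult is the authoritative record.
    """
    clusters = clusters_from_table(table)  # raises if any feature is unclustered
    result = RatingResult()
    for f in table.features:
        if f.attribution == Attribution.INTERFERENCE:
            result.attributions[f.feature_id] = Attribution.INTERFERENCE

    # Group ids are renumbered table-wide, ordered by lowest member m/z, so
    # they are stable under input row permutation.
    raw_groups: list[tuple[float, set[str], dict[str, str]]] = []
    for cluster in clusters:
        assignments = flag_cluster(cluster, table, rules)
        by_group: dict[str, dict[str, str]] = {}
        for a in assignments:
            by_group.setdefault(a.group_id, {})[a.feature_id] = a.adduct_label
        for members in by_group.values():
            low_mz = min(table.feature(fid).mz for fid in members)
            raw_groups.append((low_mz, set(members), members))
        trf_ids = {a.feature_id for a in assignments}
        calls = screen_fragments(cluster, table, trf_ids, fragment_tolerance)
        fragment_ids = {c.fragment_id for c in calls}
        srf_ids = classify_srf(cluster, table, trf_ids, fragment_ids)
        result.fragment_calls.extend(calls)
        for fid in trf_ids:
            result.attributions[fid] = Attribution.TRF
        for fid in fragment_ids:
            result.attributions[fid] = Attribution.FRAGMENT
        for fid in srf_ids:
            result.attributions[fid] = Attribution.SRF

    raw_groups.sort(key=lambda g: g[0])
    for gi, (_, member_set, labels) in enumerate(raw_groups, start=1):
        gid = f"G{gi:04d}"
        result.groups[gid] = member_set
        result.representatives[gid] = select_representative(member_set, table, intensity_metric)
        for fid, label in labels.items():
            result.adduct_labels[fid] = label

    # write back onto the table
    fid_to_group = {fid: gid for gid, members in result.groups.items() for fid in members}
    for f in table.features:
        attr = result.attributions[f.feature_id]
        if f.attribution != attr:
            f.set_attribution(attr)
        f.adduct_label = result.adduct_labels.get(f.feature_id)
        f.group_id = fid_to_group.get(f.feature_id)
        if f.upstream_adduct and f.adduct_label and f.upstream_adduct != f.adduct_label:
            table.log(
                f"upstream adduct {f.upstream_adduct} for {f.feature_id} "
                f"disagrees with computed {f.adduct_label}"
            )

    keep = set(result.representatives.values())
    keep |= {fid for fid, a in result.attributions.items() if a == Attribution.SRF}
    result.final_ids = sorted(
        keep, key=lambda fid: (table.feature(fid).rt, table.feature(fid).mz)
    )
    table.log(
        f"rated {len(table)} features: "
        f"{sum(1 for a in result.attributions.values() if a == Attribution.TRF)} TRF, "
        f"{sum(1 for a in result.attributions.values() if a == Attribution.SRF)} SRF, "
        f"{sum(1 for a in result.attributions.values() if a == Attribution.FRAGMENT)} fragment; "
        f"final table {len(result.final_ids)}"
    )
    return result


def summarize_attributions(result: RatingResult) -> RatingSummary:
    """Counts and fractions of the partition (fractions 0 with a flag if empty)."""
    counts = {a: 0 for a in Attribution}
    for a in result.attributions.values():
        counts[a] += 1
    total = len(result.attributions)
    if total == 0:
        return RatingSummary(0, 0, 0, 0, 0, 0.0, 0.0, 0, empty=True)
    real = counts[Attribution.TRF] + counts[Attribution.SRF]
    return RatingSummary(
        n_total=total,
        n_trf=counts[Attribution.TRF],
        n_srf=counts[Attribution.SRF],
        n_fragment=counts[Attribution.FRAGMENT],
        n_interference=counts[Attribution.INTERFERENCE],
        real_fraction=real / total,
        fragment_fraction=counts[Attribution.FRAGMENT] / total,
        final_size=len(result.final_ids),
    )
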