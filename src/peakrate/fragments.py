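"""In-source fragment removal and second-rated-feature (SRF) classification.

An in-source fragment is a product ion generated in the ion source rather
than by intentional collision; it aligns as its own MS1 feature, co-elutes
and correlates with its parent, and so lands in the parent's feature
cluster.  The screening rule: a cluster member f is a fragment when some
other member g carries f's MS1 m/z as a peak in g's MS2 spectrum, within
an absolute tolerance (default 0.05 Da).

Two refinements:

* features already flagged as TRFs are exempt — an adduct correlation is
  stronger evidence of parenthood than an MS2 coincidence;
* the owner must have the larger precursor m/z (a fragment cannot outweigh
  its parent), which also rules out mutual-removal cycles.

Survivors without adduct flags are the SRFs: parental features present
only as isolated quasi-molecular ions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, ValidationError
from .model import FeatureCluster, PeakTable

DEFAULT_FRAGMENT_TOLERANCE = 0.05


@dataclass(frozen=True)
class FragmentCall:
    """One fragment/owner match: f's MS1 m/z found in g's MS2."""

    fragment_id: str
    owner_id: str
    matched_ms2_mz: float
    error: float
    primary: bool = False


def screen_fragments(
    cluster: FeatureCluster,
    table: PeakTable,
    trf_ids: set[str],
    tolerance: float = DEFAULT_FRAGMENT_TOLERANCE,
) -> list[FragmentCall]:
    """Call the in-source fragments of one cluster (single pass, no cascade).

    Every qualifying (fragment, owner) pair is reported — one call per pair,
    carrying that pair's best-matching MS2 peak — and the minimal-error call
    of each fragment is marked primary.  Calls are evaluated against the
    cluster as given; removing a called fragment never changes later calls.
    """
    if tolerance <= 0:
        raise ConfigError("fragment tolerance must be > 0")
    feats = {fid: table.feature(fid) for fid in cluster.member_ids}
    order = sorted(feats.values(), key=lambda f: (f.mz, f.feature_id))
    calls: list[FragmentCall] = []
    for f in order:
        if f.feature_id in trf_ids:
            continue
        pair_calls: list[FragmentCall] = []
        for g in order:
            if g.feature_id == f.feature_id or g.mz <= f.mz:
                continue
            best = None
            for pmz, _ in g.ms2:
                err = abs(f.mz - pmz)
                if err <= tolerance and (best is None or err < best[1]):
                    best = (pmz, err)
            if best is not None:
                pair_calls.append(FragmentCall(f.feature_id, g.feature_id, best[0], best[1]))
        if pair_calls:
            prim = min(range(len(pair_calls)), key=lambda i: (pair_calls[i].error, feats[pair_calls[i].owner_id].mz))
            pair_calls[prim] = FragmentCall(
                pair_calls[prim].fragment_id,
                pair_calls[prim].owner_id,
                pair_calls[prim].matched_ms2_mz,
                pair_calls[prim].error,
                primary=True,
            )
            calls.extend(pair_calls)
    return calls


def classify_srf(
    cluster: FeatureCluster,
    table: PeakTable,
    trf_ids: set[str],
    fragment_ids: set[str],
) -> set[str]:
    """SRFs of one cluster: members that are neither TRFs nor fragments."""
    overlap = trf_ids & fragment_ids
    if overlap:
        raise ValidationError(f"features both TRF and fragment: {sorted(overlap)}")
    return set(cluster.member_ids) - trf_ids - fragment_ids
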