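"""Adduct-correlation flagging of top-rated features (TRFs).

In electrospray, one neutral molecule M commonly appears as several ion
forms at fixed m/z offsets — [M+H]+, [M+NH4]+, [M+Na]+, [M+K]+ in positive
mode.  Inside a feature cluster (co-eluting, intensity-correlated signals
presumed to come from one compound), the *difference* between two member
m/z values therefore betrays the adduct identities of both, even when the
quasi-molecular ion itself was never detected.

A :class:`CorrelationRule` is one expected difference (e.g. the Na+/K+ pair
differs by 15.97394 Da).  Flagging scans every member pair of a cluster
against every rule at an absolute tolerance (default 0.01 Da), resolves
conflicting candidate matches greedily in ascending mass error, and groups
mutually-consistent features into TRF correlation groups.  Every flagged
feature is a TRF.

Cation mass offsets include the electron-mass correction (the ion lacks
one electron), which matters at the 0.01 Da scale of high-resolution data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import ConfigError, ValidationError
from .model import FeatureCluster, PeakTable  # noqa: F401  (re-export convenience)

#: Monoisotopic masses of common positive-mode charge carriers, electron-corrected (Da).
PROTON = 1.007276
AMMONIUM = 18.033823
SODIUM = 22.989218
POTASSIUM = 38.963158

DEFAULT_ADDUCT_TOLERANCE = 0.01


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: canonical label plus signed m/z offset from M."""

    name: str
    mass_offset: float
    polarity: str = "positive"
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ConfigError("only singly charged adducts are supported")


POSITIVE_SPECS: tuple[AdductSpec, ...] = (
    AdductSpec("[M+H]+", PROTON),
    AdductSpec("[M+NH4]+", AMMONIUM),
    AdductSpec("[M+Na]+", SODIUM),
    AdductSpec("[M+K]+", POTASSIUM),
)

#: A documented negative-mode example set (deprotonated, chloride, formate).
NEGATIVE_SPECS: tuple[AdductSpec, ...] = (
    AdductSpec("[M-H]-", -1.007276, polarity="negative"),
    AdductSpec("[M+Cl]-", 34.969402, polarity="negative"),
    AdductSpec("[M+FA-H]-", 44.998201, polarity="negative"),
)


@dataclass(frozen=True)
class CorrelationRule:
    """Expected m/z difference between the two adduct forms of one molecule."""

    low_adduct: AdductSpec
    high_adduct: AdductSpec
    tolerance: float = DEFAULT_ADDUCT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigError("rule tolerance must be > 0")
        if self.delta <= 0:
            raise ConfigError(
                f"degenerate rule {self.low_adduct.name} -> {self.high_adduct.name}: delta <= 0"
            )

    @property
    def delta(self) -> float:
        return self.high_adduct.mass_offset - self.low_adduct.mass_offset


@dataclass(frozen=True)
class Evidence:
    partner_id: str
    rule: CorrelationRule
    error: float


@dataclass
class AdductAssignment:
    feature_id: str
    adduct_label: str
    group_id: str
    evidence: list[Evidence] = field(default_factory=list)


def build_rules(
    specs: Sequence[AdductSpec],
    pairs: Iterable[tuple[str, str]],
    tolerance: float = DEFAULT_ADDUCT_TOLERANCE,
) -> list[CorrelationRule]:
    """Build correlation rules from named adduct pairs.

    Each pair is reordered so the rule's delta is positive; duplicate pairs
    collapse to one rule.  Unknown names and equal-offset pairs are errors.
    """
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ConfigError("duplicate adduct names in spec list")
    seen: set[frozenset[str]] = set()
    rules: list[CorrelationRule] = []
    for a, b in pairs:
        if a not in by_name or b not in by_name:
            unknown = [n for n in (a, b) if n not in by_name]
            raise ConfigError(f"unknown adduct name(s) {unknown}; known: {sorted(by_name)}")
        if a == b:
            raise ConfigError(f"self-pair ({a}, {b}) is not a correlation")
        sa, sb = by_name[a], by_name[b]
        if sa.polarity != sb.polarity:
            raise ConfigError(f"mixed-polarity pair ({a}, {b})")
        if sa.mass_offset == sb.mass_offset:
            raise ConfigError(f"degenerate pair ({a}, {b}): equal mass offsets")
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        low, high = (sa, sb) if sa.mass_offset < sb.mass_offset else (sb, sa)
        rules.append(CorrelationRule(low, high, tolerance))
    return rules


def default_positive_rules(tolerance: float = DEFAULT_ADDUCT_TOLERANCE) -> list[CorrelationRule]:
    """The six positive-mode rules over [M+H]+, [M+NH4]+, [M+Na]+, [M+K]+."""
    pairs = list(itertools.combinations([s.name for s in POSITIVE_SPECS], 2))
    return build_rules(POSITIVE_SPECS, pairs, tolerance)


def neutral_mass(mz: float, adduct: AdductSpec) -> float:
    """Back-calculate the neutral monoisotopic mass from an ion m/z."""
    mass = mz * adduct.charge - adduct.mass_offset
    if mass <= 0:
        raise ValidationError(
            f"non-physical neutral mass {mass:.4f} from m/z {mz} as {adduct.name}"
        )
    return mass


def candidate_edges(
    members: Sequence[tuple[str, float]], rules: Sequence[CorrelationRule]
) -> list[tuple[float, str, str, CorrelationRule]]:
    """All (error, low_id, high_id, rule) candidates within tolerance.

    Candidates are returned in the deterministic order used for greedy
    resolution: ascending error, then low m/z, high m/z, rule delta — so the
    result is invariant under permutation of the input members.
    """
    by_id = dict(members)
    cands = []
    for (id_a, mz_a), (id_b, mz_b) in itertools.combinations(members, 2):
        lo_id, hi_id = (id_a, id_b) if mz_a <= mz_b else (id_b, id_a)
        diff = abs(mz_b - mz_a)
        for rule in rules:
            err = abs(diff - rule.delta)
            if err <= rule.tolerance:
                cands.append((err, lo_id, hi_id, rule))
    cands.sort(key=lambda c: (c[0], by_id[c[1]], by_id[c[2]], c[3].delta, c[3].low_adduct.name))
    return cands


def _resolve_greedy(
    cands: list[tuple[float, str, str, CorrelationRule]],
) -> tuple[dict[str, str], list[int]]:
    """Accept candidates in ascending error when label-compatible (near-optimal)."""
    labels: dict[str, str] = {}
    chosen: list[int] = []
    for i, (err, lo, hi, rule) in enumerate(cands):
        lo_lab, hi_lab = labels.get(lo), labels.get(hi)
        if (lo_lab is None or lo_lab == rule.low_adduct.name) and (
            hi_lab is None or hi_lab == rule.high_adduct.name
        ):
            labels[lo] = rule.low_adduct.name
            labels[hi] = rule.high_adduct.name
            chosen.append(i)
    return labels, chosen


#: above this many candidate edges, fall back from exact search to greedy
_EXACT_LIMIT = 20


def _resolve_exact(
    cands: list[tuple[float, str, str, CorrelationRule]],
) -> tuple[dict[str, str], list[int]]:
    """Exact conflict resolution by branch-and-bound over candidate edges.

    Maximises the number of accepted edges, breaking ties by minimal total
    absolute error, then by first-in-candidate-order; candidates come
    pre-sorted deterministically, so the result is permutation-invariant.
    """
    k = len(cands)
    best: list = [-1, float("inf"), (), {}]  # count, err, idxs, labels

    labels: dict[str, str] = {}
    chosen: list[int] = []

    def dfs(i: int, count: int, err: float) -> None:
        if count + (k - i) < best[0]:
            return
        if i == k:
            key = (-count, err, tuple(chosen))
            if key < (-best[0], best[1], best[2]):
                best[0], best[1], best[2], best[3] = count, err, tuple(chosen), dict(labels)
            return
        e, lo, hi, rule = cands[i]
        lo_lab, hi_lab = labels.get(lo), labels.get(hi)
        if (lo_lab is None or lo_lab == rule.low_adduct.name) and (
            hi_lab is None or hi_lab == rule.high_adduct.name
        ):
            added = []
            if lo_lab is None:
                labels[lo] = rule.low_adduct.name
                added.append(lo)
            if hi_lab is None:
                labels[hi] = rule.high_adduct.name
                added.append(hi)
            chosen.append(i)
            dfs(i + 1, count + 1, err + e)
            chosen.pop()
            for fid in added:
                del labels[fid]
        dfs(i + 1, count, err)

    dfs(0, 0, 0.0)
    return best[3], list(best[2])


def flag_cluster(
    cluster: "FeatureCluster",
    table: PeakTable,
    rules: Sequence[CorrelationRule],
) -> list[AdductAssignment]:
    """Flag the TRFs of one feature cluster by adduct-correlation matching.

    Candidate pair/rule matches are resolved to a consistent labelling (each
    feature carries at most one adduct label) that maximises the number of
    accepted correlation edges, with ties broken by minimal total absolute
    mass error.  Resolution is exact (branch-and-bound) for realistic
    candidate counts; clusters producing more than 20 candidate edges fall
    back to greedy acceptance in ascending error.  Connected components of
    accepted edges become TRF groups.  Group ids are provisional (``g1``,
    ``g2``, ... ordered by lowest member m/z); the rater renumbers them
    table-wide.
    """
    feats = {fid: table.feature(fid) for fid in cluster.member_ids}
    members = sorted(((fid, f.mz) for fid, f in feats.items()), key=lambda m: (m[1], m[0]))
    cands = candidate_edges(members, rules)
    resolve = _resolve_exact if len(cands) <= _EXACT_LIMIT else _resolve_greedy
    labels, chosen = resolve(cands)
    accepted = [cands[i] for i in chosen]

    graph = nx.Graph()
    graph.add_nodes_from(labels)
    graph.add_edges_from((lo, hi) for _, lo, hi, _ in accepted)
    components = sorted(nx.connected_components(graph), key=lambda c: min(feats[i].mz for i in c))

    assignments: dict[str, AdductAssignment] = {}
    for gi, comp in enumerate(components, start=1):
        for fid in sorted(comp, key=lambda i: feats[i].mz):
            assignments[fid] = AdductAssignment(fid, labels[fid], f"g{gi}")
    for err, lo, hi, rule in accepted:
        assignments[lo].evidence.append(Evidence(hi, rule, err))
        assignments[hi].evidence.append(Evidence(lo, rule, err))
    return [assignments[fid] for fid, _ in members if fid in assignments]
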