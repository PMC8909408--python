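"""Synthetic aligned peak tables with planted ground truth.

The generator emulates the table an alignment/cleaning chain exports from a
multi-class plant-extract study: for each simulated compound it plants a
quasi-molecular ion and/or extra adduct forms at exact cation offsets (plus
optional Gaussian m/z jitter), optionally plants in-source fragments whose
m/z is written into the precursor feature's MS2 spectrum, and gives all
features of one compound a shared latent abundance pattern across samples
so they are Pearson-correlated and co-eluting.  Solvent blanks get
near-zero heights for compound features; a configurable fraction of the
uncorrelated noise features is blank-dominated instead.  Pooled QC samples
are per-feature biological means with small noise.

Planted truth is returned alongside the table: per-feature roles
(parental / adduct / fragment / noise), compound membership, adduct
identity, and the expected cluster partition — so recall and precision of
every pipeline stage can be measured exactly.

Construction guards keep the truth recoverable: a fragment's neutral loss
is redrawn whenever the resulting m/z would either sit within 0.02 Da of an
adduct-rule delta relative to any cluster member (which would fake an
adduct correlation) or fall within 0.2 Da of a member m/z (which would
collide with the fragment-screening tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adducts import POSITIVE_SPECS, AdductSpec, default_positive_rules
from .errors import ConfigError, ValidationError
from .model import (
    Attribution,
    Feature,
    PeakTable,
    SampleInfo,
    SampleRole,
    Spectrum,
)
from .rater import RatingResult

#: common neutral losses (water, formic acid, hexose) used for planted fragments
NEUTRAL_LOSSES = (18.0106, 46.0055, 162.0528)

_DELTA_GUARD = 0.02  # Da clearance from any adduct-rule delta
_MZ_GUARD = 0.2  # Da clearance from any cluster-member m/z


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic peak table.

    Defaults describe a mid-sized multi-class profiling study: 200
    compounds over 100-1000 Da, four sample classes of three replicates,
    one solvent blank and two pooled QCs, 30% of compounds shedding one or
    two in-source fragments, 10% of compounds lacking their
    quasi-molecular ion (detectable only through adduct correlations),
    2 mDa m/z jitter and 20% multiplicative intensity noise.
    """

    n_compounds: int = 200
    neutral_mass_range: tuple[float, float] = (100.0, 1000.0)
    adduct_set: tuple[AdductSpec, ...] = POSITIVE_SPECS
    p_extra_adduct: float = 0.35
    p_drop_quasimolecular: float = 0.1
    p_fragment: float = 0.3
    max_fragments_per_parent: int = 2
    n_samples: int = 12
    n_classes: int = 4
    n_blanks: int = 1
    n_qc: int = 2
    intensity_cv: float = 0.2
    class_effect_sd: float = 1.0
    mz_jitter_sd: float = 0.002
    rt_jitter_sd: float = 0.005
    rt_range: tuple[float, float] = (1.0, 30.0)
    n_noise_features: int = 60
    blank_noise_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_extra_adduct, self.p_drop_quasimolecular, self.p_fragment,
                  self.blank_noise_fraction):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.mz_jitter_sd < 0 or self.rt_jitter_sd < 0 or self.intensity_cv < 0:
            raise ConfigError("jitters and cv must be >= 0")
        if self.n_compounds < 0 or self.n_noise_features < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_compounds > 0 and not self.adduct_set:
            raise ConfigError("adduct_set must not be empty")
        if self.p_drop_quasimolecular > 0 and len(self.adduct_set) < 3:
            raise ConfigError(
                "p_drop_quasimolecular > 0 needs >= 3 adduct specs "
                "(a dropped quasi-molecular ion must leave >= 2 correlated adducts)"
            )
        if self.n_samples < 1 or self.n_classes < 1 or self.n_classes > self.n_samples:
            raise ConfigError("need 1 <= n_classes <= n_samples")


@dataclass
class GroundTruth:
    """Planted per-feature roles and the expected cluster partition."""

    roles: dict[str, str] = field(default_factory=dict)  # parental|adduct|fragment|noise
    parent_of: dict[str, str] = field(default_factory=dict)  # feature -> compound id
    adduct_of: dict[str, str] = field(default_factory=dict)  # feature -> adduct name
    expected_clusters: list[frozenset[str]] = field(default_factory=list)

    def expected_trfs(self) -> set[str]:
        """Features that *can* be flagged: adduct-form members of a compound
        with >= 2 adduct-form features in the same expected cluster."""
        by_compound: dict[str, list[str]] = {}
        for fid, role in self.roles.items():
            if role in ("parental", "adduct"):
                by_compound.setdefault(self.parent_of[fid], []).append(fid)
        return {fid for members in by_compound.values() if len(members) >= 2 for fid in members}

    def expected_srfs(self) -> set[str]:
        flaggable = self.expected_trfs()
        return {
            fid
            for fid, role in self.roles.items()
            if role in ("parental", "adduct") and fid not in flaggable
        }

    def fragments(self) -> set[str]:
        return {fid for fid, role in self.roles.items() if role == "fragment"}

    def noise(self) -> set[str]:
        return {fid for fid, role in self.roles.items() if role == "noise"}


@dataclass
class _Row:
    mz: float
    true_mz: float
    rt: float
    role: str
    compound: Optional[str]
    adduct: Optional[str]
    heights: dict[str, float]
    ms2: list[tuple[float, float]]
    cluster_key: str


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _clear_of_rules(mz: float, member_mzs: Sequence[float], deltas: Sequence[float]) -> bool:
    for other in member_mzs:
        diff = abs(mz - other)
        if diff < _MZ_GUARD:
            return False
        for d in deltas:
            if abs(diff - d) < _DELTA_GUARD:
                return False
    return True


def generate(cfg: SimConfig) -> tuple[PeakTable, GroundTruth]:
    """Generate a peak table and its ground truth from one seeded config."""
    rng = np.random.default_rng(cfg.seed)
    rules = default_positive_rules()
    deltas = [r.delta for r in rules]

    # sample design
    samples: list[SampleInfo] = []
    class_of: dict[str, int] = {}
    for i in range(cfg.n_samples):
        cls = i % cfg.n_classes
        sid = f"cls{cls + 1}_{i // cfg.n_classes + 1}"
        samples.append(SampleInfo(sid, SampleRole.BIOLOGICAL, f"cls{cls + 1}"))
        class_of[sid] = cls
    blanks = [f"Blank_{i + 1}" for i in range(cfg.n_blanks)]
    samples += [SampleInfo(b, SampleRole.BLANK, "blank") for b in blanks]
    qcs = [f"QC_{i + 1}" for i in range(cfg.n_qc)]
    samples += [SampleInfo(q, SampleRole.QC, "qc") for q in qcs]
    bio_ids = [s.sample_id for s in samples if s.role == SampleRole.BIOLOGICAL]

    rows: list[_Row] = []
    base = cfg.adduct_set[0]
    extras = cfg.adduct_set[1:]

    for k in range(cfg.n_compounds):
        comp_id = f"M{k + 1:04d}"
        mass = rng.uniform(*cfg.neutral_mass_range)
        rt = rng.uniform(*cfg.rt_range)
        mu = rng.uniform(math.log(1e4), math.log(1e6))
        class_eff = rng.normal(0.0, cfg.class_effect_sd, size=cfg.n_classes)
        abundance = {s: math.exp(mu + class_eff[class_of[s]]) for s in bio_ids}

        # which adduct forms exist
        drop = rng.random() < cfg.p_drop_quasimolecular
        chosen = [a for a in extras if rng.random() < cfg.p_extra_adduct]
        if drop and len(chosen) < 2:
            pool = [a for a in extras if a not in chosen]
            need = 2 - len(chosen)
            chosen += [pool[i] for i in rng.choice(len(pool), size=need, replace=False)]
        forms = ([] if drop else [base]) + chosen

        comp_rows: list[_Row] = []
        for j, adduct in enumerate(forms):
            true_mz = mass + adduct.mass_offset
            response = 1.0 if adduct is base else math.exp(rng.normal(-1.0, 0.7))
            noise = _lognormal_factor(rng, cfg.intensity_cv, size=len(bio_ids))
            heights = {
                s: abundance[s] * response * float(noise[i]) for i, s in enumerate(bio_ids)
            }
            for b in blanks:
                heights[b] = float(rng.uniform(0.0, 5.0))
            qc_base = float(np.mean(list(abundance.values()))) * response
            for q in qcs:
                heights[q] = qc_base * float(1.0 + rng.normal(0.0, 0.02))
            role = "parental" if adduct is base else "adduct"
            comp_rows.append(
                _Row(
                    mz=true_mz + rng.normal(0.0, cfg.mz_jitter_sd),
                    true_mz=true_mz,
                    rt=max(0.0, rt + rng.normal(0.0, cfg.rt_jitter_sd)),
                    role=role,
                    compound=comp_id,
                    adduct=adduct.name,
                    heights=heights,
                    ms2=[],
                    cluster_key=comp_id,
                )
            )

        # in-source fragments, written into the precursor's MS2
        if rng.random() < cfg.p_fragment and comp_rows:
            n_frag = int(rng.integers(1, cfg.max_fragments_per_parent + 1))
            precursor = comp_rows[0]  # quasi-molecular if present, else first adduct
            for _ in range(n_frag):
                frag_true = None
                for _attempt in range(200):
                    if rng.random() < 0.5:
                        loss = float(NEUTRAL_LOSSES[rng.integers(len(NEUTRAL_LOSSES))])
                    else:
                        loss = float(rng.uniform(20.0, 200.0))
                    cand = precursor.true_mz - loss
                    if cand <= 50.0:
                        continue
                    member_mzs = [r.true_mz for r in comp_rows]
                    if _clear_of_rules(cand, member_mzs, deltas):
                        frag_true = cand
                        break
                if frag_true is None:
                    continue  # geometry too crowded; skip this fragment
                response = math.exp(rng.normal(-1.5, 0.7))
                noise = _lognormal_factor(rng, cfg.intensity_cv, size=len(bio_ids))
                heights = {
                    s: abundance[s] * response * float(noise[i]) for i, s in enumerate(bio_ids)
                }
                for b in blanks:
                    heights[b] = float(rng.uniform(0.0, 5.0))
                qc_base = float(np.mean(list(abundance.values()))) * response
                for q in qcs:
                    heights[q] = qc_base * float(1.0 + rng.normal(0.0, 0.02))
                precursor.ms2.append((frag_true, float(rng.uniform(100.0, 999.0))))
                comp_rows.append(
                    _Row(
                        mz=frag_true + rng.normal(0.0, cfg.mz_jitter_sd),
                        true_mz=frag_true,
                        rt=max(0.0, rt + rng.normal(0.0, cfg.rt_jitter_sd)),
                        role="fragment",
                        compound=comp_id,
                        adduct=None,
                        heights=heights,
                        ms2=[],
                        cluster_key=comp_id,
                    )
                )

        # uninformative extra MS2 peaks on the precursor, kept clear of members
        if comp_rows:
            member_mzs = [r.true_mz for r in comp_rows]
            for _ in range(int(rng.integers(0, 4))):
                pmz = float(rng.uniform(60.0, comp_rows[0].true_mz))
                if all(abs(pmz - m) > 2 * _MZ_GUARD for m in member_mzs):
                    comp_rows[0].ms2.append((pmz, float(rng.uniform(10.0, 500.0))))
        rows.extend(comp_rows)

    # uncorrelated noise features (singleton clusters)
    n_blank_noise = int(round(cfg.n_noise_features * cfg.blank_noise_fraction))
    for i in range(cfg.n_noise_features):
        blank_dominated = i < n_blank_noise
        heights = {}
        for s in bio_ids:
            heights[s] = float(rng.uniform(0.0, 50.0)) if blank_dominated else float(
                rng.lognormal(math.log(1e4), 1.0)
            )
        for b in blanks:
            heights[b] = float(rng.uniform(5e4, 5e5)) if blank_dominated else float(
                rng.uniform(0.0, 5.0)
            )
        for q in qcs:
            heights[q] = float(np.mean([heights[s] for s in bio_ids]))
        rows.append(
            _Row(
                mz=float(rng.uniform(*cfg.neutral_mass_range)),
                true_mz=0.0,
                rt=float(rng.uniform(*cfg.rt_range)),
                role="noise",
                compound=None,
                adduct=None,
                heights=heights,
                ms2=[],
                cluster_key=f"N{i + 1:04d}",
            )
        )

    # stable ids in elution order
    rows.sort(key=lambda r: (r.rt, r.mz))
    features: list[Feature] = []
    truth = GroundTruth()
    cluster_members: dict[str, set[str]] = {}
    for i, row in enumerate(rows, start=1):
        fid = f"F{i:04d}"
        features.append(
            Feature(
                feature_id=fid,
                mz=row.mz,
                rt=row.rt,
                heights=row.heights,
                ms2=Spectrum.from_peaks(row.ms2),
                cluster_id=row.cluster_key,
            )
        )
        truth.roles[fid] = row.role
        if row.compound is not None:
            truth.parent_of[fid] = row.compound
        if row.adduct is not None:
            truth.adduct_of[fid] = row.adduct
        cluster_members.setdefault(row.cluster_key, set()).add(fid)
    truth.expected_clusters = [frozenset(m) for _, m in sorted(cluster_members.items())]

    table = PeakTable(features=features, samples=samples, polarity=cfg.adduct_set[0].polarity)
    table.log(
        f"simulated {len(features)} features: {cfg.n_compounds} compounds, "
        f"{cfg.n_noise_features} noise (seed {cfg.seed})"
    )
    return table, truth


@dataclass
class RecoveryMetrics:
    """Precision/recall of each rating stage against planted truth."""

    adduct_precision: float
    adduct_recall: float
    fragment_precision: float
    fragment_recall: float
    srf_precision: float
    srf_recall: float
    rand_index: float
    n_features: int


def _pr(predicted: set[str], expected: set[str]) -> tuple[float, float]:
    precision = len(predicted & expected) / len(predicted) if predicted else 1.0
    recall = len(predicted & expected) / len(expected) if expected else 1.0
    return precision, recall


def _rand_index(a: dict[str, int], b: dict[str, int]) -> float:
    """Rand index of two labelings over the same universe (pair-counting)."""
    ids = sorted(a)
    n = len(ids)
    if n < 2:
        return 1.0
    import itertools

    agree = 0
    total = 0
    la = [a[i] for i in ids]
    lb = [b[i] for i in ids]
    for i, j in itertools.combinations(range(n), 2):
        same_a = la[i] == la[j]
        same_b = lb[i] == lb[j]
        agree += same_a == same_b
        total += 1
    return agree / total


def score_against_truth(
    result: RatingResult,
    truth: GroundTruth,
    predicted_clusters: Optional[Sequence[frozenset[str]]] = None,
) -> RecoveryMetrics:
    """Score a rating result against planted truth.

    Adduct-flag recall is measured over the *flaggable* features (adduct
    forms of compounds with >= 2 such forms: an isolated quasi-molecular
    ion exhibits no correlation by construction).  SRF precision/recall is
    measured over non-noise features — retained uncorrelated noise
    singletons are structurally indistinguishable from SRFs.
    """
    universe = set(truth.roles)
    got = set(result.attributions)
    if got != universe:
        raise ValidationError(
            f"feature universe mismatch: {len(got ^ universe)} features differ"
        )
    trf_pred = {f for f, a in result.attributions.items() if a == Attribution.TRF}
    frag_pred = {f for f, a in result.attributions.items() if a == Attribution.FRAGMENT}
    noise = truth.noise()
    srf_pred = {f for f, a in result.attributions.items() if a == Attribution.SRF} - noise

    ap, ar = _pr(trf_pred, truth.expected_trfs())
    fp, fr = _pr(frag_pred, truth.fragments())
    sp, sr = _pr(srf_pred, truth.expected_srfs())

    if predicted_clusters is None:
        ri = 1.0  # clustering not under test
    else:
        la = {f: i for i, c in enumerate(truth.expected_clusters) for f in c}
        lb = {f: i for i, c in enumerate(predicted_clusters) for f in c}
        restricted = set(la) & set(lb)
        ri = _rand_index(
            {f: la[f] for f in restricted}, {f: lb[f] for f in restricted}
        )
    return RecoveryMetrics(
        adduct_precision=ap,
        adduct_recall=ar,
        fragment_precision=fp,
        fragment_recall=fr,
        srf_precision=sp,
        srf_recall=sr,
        rand_index=ri,
        n_features=len(universe),
    )
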