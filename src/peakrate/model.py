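"""In-memory model for aligned LC-MS peak tables.

A *feature* is one aligned LC-MS signal: an average m/z, an average
retention time, a per-sample intensity (peak height) vector, and — when
data-dependent acquisition picked it — an MS2 spectrum.  A *peak table*
collects the features of one study together with the sample design
(biological classes, blanks, pooled QCs).

As the rating pipeline runs, each feature acquires an *attribution*:

``TRF``
    top-rated feature — a parental ion evidenced by at least one adduct
    correlation inside its feature cluster;
``SRF``
    second-rated feature — a parental ion present only as an isolated
    quasi-molecular ion;
``fragment``
    an in-source fragment whose MS1 m/z reappears in a cluster-mate's MS2;
``interference``
    background removed by the generic filters (blank, RSD).

Attributions only ever move from ``unrated`` to one of the four final
states; nothing is re-attributed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .errors import ValidationError


class Attribution(str, enum.Enum):
    UNRATED = "unrated"
    TRF = "TRF"
    SRF = "SRF"
    FRAGMENT = "fragment"
    INTERFERENCE = "interference"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SampleRole(str, enum.Enum):
    BIOLOGICAL = "biological"
    BLANK = "blank"
    QC = "qc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Spectrum:
    """An MS2 spectrum: (m/z, intensity) peaks sorted ascending by m/z.

    Intensities are kept exactly as read — fragment screening is an m/z
    existence test and does not depend on normalisation.
    """

    peaks: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for mz, inten in self.peaks:
            if not (mz > 0) or math.isnan(mz) or math.isnan(inten) or inten < 0:
                raise ValidationError(f"invalid spectrum peak ({mz}, {inten})")
        if any(self.peaks[i][0] > self.peaks[i + 1][0] for i in range(len(self.peaks) - 1)):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.peaks)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @classmethod
    def from_peaks(cls, peaks: Iterable[tuple[float, float]]) -> "Spectrum":
        return cls(tuple(sorted((float(m), float(i)) for m, i in peaks)))


@dataclass
class Feature:
    """One aligned feature and its evolving annotation state."""

    feature_id: str
    mz: float
    rt: float
    heights: dict[str, float] = field(default_factory=dict)
    ms2: Spectrum = field(default_factory=Spectrum)
    cluster_id: Optional[str] = None
    upstream_adduct: Optional[str] = None
    attribution: Attribution = Attribution.UNRATED
    adduct_label: Optional[str] = None
    group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValidationError(f"feature {self.feature_id!r}: m/z must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValidationError(f"feature {self.feature_id!r}: rt must be >= 0, got {self.rt}")

    def set_attribution(self, value: Attribution) -> None:
        """Transition unrated -> final state; re-attribution is a bug."""
        if self.attribution not in (Attribution.UNRATED, value):
            raise ValidationError(
                f"feature {self.feature_id!r}: cannot re-attribute "
                f"{self.attribution.value} -> {value.value}"
            )
        self.attribution = value

    def copy(self) -> "Feature":
        return replace(self, heights=dict(self.heights))


@dataclass(frozen=True)
class FeatureCluster:
    """A group of co-eluting, intensity-correlated features (one putative compound)."""

    cluster_id: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValidationError(f"cluster {self.cluster_id!r} has no members")
        if not isinstance(self.member_ids, frozenset):
            object.__setattr__(self, "member_ids", frozenset(self.member_ids))

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class SampleInfo:
    """One injection: its id, role in the design, and biological class."""

    sample_id: str
    role: SampleRole = SampleRole.BIOLOGICAL
    class_label: str = ""


@dataclass
class PeakTable:
    """Ordered feature collection plus sample metadata.

    ``provenance`` is an audit log: each operation appends one line
    describing what it did and how many features it touched.
    """

    features: list[Feature] = field(default_factory=list)
    samples: list[SampleInfo] = field(default_factory=list)
    polarity: str = "positive"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- access helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def feature(self, feature_id: str) -> Feature:
        try:
            return self._index()[feature_id]
        except KeyError:
            raise KeyError(f"no feature with id {feature_id!r}") from None

    def _index(self) -> dict[str, Feature]:
        return {f.feature_id: f for f in self.features}

    def sample_ids(self, role: Optional[SampleRole] = None) -> list[str]:
        return [s.sample_id for s in self.samples if role is None or s.role == role]

    @property
    def biological_ids(self) -> list[str]:
        return self.sample_ids(SampleRole.BIOLOGICAL)

    @property
    def blank_ids(self) -> list[str]:
        return self.sample_ids(SampleRole.BLANK)

    @property
    def qc_ids(self) -> list[str]:
        return self.sample_ids(SampleRole.QC)

    def classes(self) -> dict[str, list[str]]:
        """Biological class label -> sample ids."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            if s.role == SampleRole.BIOLOGICAL:
                out.setdefault(s.class_label, []).append(s.sample_id)
        return out

    def clusters(self) -> dict[str, list[str]]:
        """cluster_id -> member feature ids, in table order (unclustered skipped)."""
        out: dict[str, list[str]] = {}
        for f in self.features:
            if f.cluster_id is not None:
                out.setdefault(f.cluster_id, []).append(f.feature_id)
        return out

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "PeakTable":
        return PeakTable(
            features=[f.copy() for f in self.features],
            samples=list(self.samples),
            polarity=self.polarity,
            provenance=list(self.provenance),
        )

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature ids: {dupes}")
        declared = {s.sample_id for s in self.samples}
        if len(declared) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        for f in self.features:
            unknown = set(f.heights) - declared
            if unknown:
                raise ValidationError(
                    f"feature {f.feature_id!r} has heights for undeclared samples {sorted(unknown)}"
                )
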