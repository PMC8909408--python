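"""Read and write aligned peak tables in the MS-DIAL / MS-CleanR export dialect.

MS-DIAL's alignment export (and the cleaned table MS-CleanR writes from it)
is a flat CSV/TSV: one row per aligned feature, columns for the feature id,
average m/z, average retention time, an MS2 spectrum serialised as
whitespace-separated ``mz:intensity`` pairs, and one column of peak heights
per sample.  The two tools use different header spellings, so every logical
column is resolved through an alias list (override via ``Dialect``).

Sample roles (biological / blank / QC) are inferred from the column name by
default (a name containing "blank" or "qc"), or supplied explicitly.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .model import Attribution, Feature, PeakTable, SampleInfo, SampleRole, Spectrum

logger = logging.getLogger(__name__)

#: Default header aliases, checked case-insensitively with spaces/dots collapsed.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("alignment id", "alignment.id", "feature id", "feature_id", "id"),
    "mz": ("average mz", "average.mz", "average_mz", "mz", "m/z"),
    "rt": ("average rt(min)", "average.rt.min.", "average rt", "rt", "rt(min)", "rt_min"),
    "ms2": ("ms/ms spectrum", "ms.ms.spectrum", "ms.ms. spectrum", "msms spectrum", "ms2", "msms"),
    "cluster": ("cluster id", "cluster.id", "cluster_id", "cluster"),
    "adduct": ("adduct type", "adduct ion name", "adduct.type", "adduct", "upstream_adduct"),
    "attribution": ("attribution",),
    "adduct_label": ("adduct_label", "flagged adduct"),
    "group_id": ("group_id", "trf group"),
}


def _canon(name: str) -> str:
    return " ".join(name.strip().lower().replace(".", " ").split())


@dataclass
class Dialect:
    """Column resolution and delimiter policy for one table format."""

    aliases: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_ALIASES))
    delimiter: Optional[str] = None  # None -> sniff from extension, then content
    #: explicit sample columns and roles; None -> every unresolved column is a sample
    samples: Optional[list[SampleInfo]] = None
    polarity: str = "positive"

    def resolve(self, columns: Sequence[str]) -> dict[str, str]:
        """Map logical field -> actual column name present in *columns*."""
        canon = {_canon(c): c for c in columns}
        out: dict[str, str] = {}
        for logical, names in self.aliases.items():
            for name in names:
                if _canon(name) in canon:
                    out[logical] = canon[_canon(name)]
                    break
        return out


def _sniff_delimiter(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tsv", ".txt"):
        return "\t"
    if ext == ".csv":
        return ","
    with open(path, newline="") as fh:
        head = fh.readline()
    has_tab, has_comma = "\t" in head, "," in head
    if has_tab == has_comma:
        raise FormatError(f"cannot determine delimiter of {path!r}; use .csv/.tsv or set Dialect.delimiter")
    return "\t" if has_tab else ","


def parse_spectrum_string(text: object) -> Spectrum:
    """Parse MS-DIAL's ``"mz:intensity mz:intensity ..."`` cell encoding.

    Total function: any input yields a Spectrum.  Malformed tokens are
    skipped with a warning; missing cells (NaN/empty) give an empty spectrum.
    """
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return Spectrum()
    peaks = []
    for token in str(text).split():
        part = token.split(":")
        ok = len(part) == 2
        if ok:
            try:
                mz, inten = float(part[0]), float(part[1])
                ok = mz > 0 and inten >= 0 and not (math.isnan(mz) or math.isnan(inten))
            except ValueError:
                ok = False
        if ok:
            peaks.append((mz, inten))
        elif token:
            logger.warning("skipping malformed MS2 token %r", token)
    return Spectrum.from_peaks(peaks)


def serialize_spectrum(spectrum: Spectrum) -> str:
    # repr() is the shortest exact decimal form, so serialization round-trips
    return " ".join(f"{mz!r}:{inten!r}" for mz, inten in spectrum)


def _role_from_name(name: str) -> SampleRole:
    low = name.lower()
    if "blank" in low:
        return SampleRole.BLANK
    if "qc" in low:
        return SampleRole.QC
    return SampleRole.BIOLOGICAL


def read_alignment_table(path: str, dialect: Optional[Dialect] = None) -> PeakTable:
    """Read an aligned peak table (MS-DIAL / MS-CleanR export) into a PeakTable.

    Required columns: id, m/z, RT, and at least the sample heights; the MS2,
    cluster and adduct columns are optional.  Unparseable MS2 cells become
    empty spectra with a logged warning.  Row order is preserved.
    """
    dialect = dialect or Dialect()
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path!r}")
    delim = dialect.delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, dtype={}, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path!r} is empty") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path!r} is empty")

    resolved = dialect.resolve(df.columns)
    for required in ("id", "mz", "rt"):
        if required not in resolved:
            raise FormatError(
                f"{path!r}: required column {required!r} not found "
                f"(accepted names: {list(dialect.aliases[required])})"
            )

    if dialect.samples is not None:
        samples = list(dialect.samples)
        missing = [s.sample_id for s in samples if s.sample_id not in df.columns]
        if missing:
            raise FormatError(f"{path!r}: declared sample columns missing: {missing}")
    else:
        known = set(resolved.values())
        samples = [
            SampleInfo(c, _role_from_name(c), class_label=_class_from_name(c))
            for c in df.columns
            if c not in known
        ]

    sample_cols = [s.sample_id for s in samples]
    features = []
    for _, row in df.iterrows():
        fid = str(row[resolved["id"]])
        heights = {c: float(row[c]) if pd.notna(row[c]) else 0.0 for c in sample_cols}
        ms2 = parse_spectrum_string(row[resolved["ms2"]]) if "ms2" in resolved else Spectrum()
        cluster = row.get(resolved["cluster"]) if "cluster" in resolved else None
        adduct = row.get(resolved["adduct"]) if "adduct" in resolved else None
        attribution = Attribution.UNRATED
        if "attribution" in resolved and pd.notna(row[resolved["attribution"]]):
            attribution = Attribution(str(row[resolved["attribution"]]))
        feat = Feature(
            feature_id=fid,
            mz=float(row[resolved["mz"]]),
            rt=float(row[resolved["rt"]]),
            heights=heights,
            ms2=ms2,
            cluster_id=str(cluster) if pd.notna(cluster) and str(cluster) != "" else None,
            upstream_adduct=str(adduct) if pd.notna(adduct) and str(adduct) != "" else None,
            attribution=attribution,
        )
        if "adduct_label" in resolved and pd.notna(row[resolved["adduct_label"]]):
            feat.adduct_label = str(row[resolved["adduct_label"]])
        if "group_id" in resolved and pd.notna(row[resolved["group_id"]]):
            feat.group_id = str(row[resolved["group_id"]])
        features.append(feat)

    ids = [f.feature_id for f in features]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{path!r}: duplicate feature ids")
    table = PeakTable(features=features, samples=samples, polarity=dialect.polarity)
    table.log(f"read {len(features)} features, {len(samples)} samples from {path}")
    return table


def _class_from_name(name: str) -> str:
    # "indA_1" -> class "indA"; single-token names are their own class
    return name.rsplit("_", 1)[0] if "_" in name else name


def _frame(table: PeakTable, features: Sequence[Feature], annotate: bool) -> pd.DataFrame:
    cols: dict[str, list] = {
        "feature_id": [f.feature_id for f in features],
        "mz": [f.mz for f in features],
        "rt": [f.rt for f in features],
        "cluster_id": [f.cluster_id or "" for f in features],
        "ms2": [serialize_spectrum(f.ms2) for f in features],
    }
    if annotate:
        cols["attribution"] = [f.attribution.value for f in features]
        cols["adduct_label"] = [f.adduct_label or "" for f in features]
        cols["group_id"] = [f.group_id or "" for f in features]
    for s in table.samples:
        cols[s.sample_id] = [f.heights.get(s.sample_id, 0.0) for f in features]
    return pd.DataFrame(cols)


def write_table(table: PeakTable, path: str, kind: str = "full") -> None:
    """Write a peak table as CSV/TSV (delimiter from extension; default comma).

    kind="full"   — every feature with attribution, adduct label and group id;
    kind="final"  — only group representatives and SRFs (the cleaned table);
    kind="report" — attribution counts per category.
    """
    delim = "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".txt") else ","
    if kind == "report":
        counts = {a.value: 0 for a in Attribution}
        for f in table.features:
            counts[f.attribution.value] += 1
        pd.DataFrame({"attribution": list(counts), "count": list(counts.values())}).to_csv(
            path, sep=delim, index=False
        )
        return
    if kind == "full":
        feats: Sequence[Feature] = table.features
    elif kind == "final":
        from .rater import select_representative  # local import avoids a cycle

        groups: dict[str, set[str]] = {}
        for f in table.features:
            if f.attribution == Attribution.TRF:
                groups.setdefault(f.group_id or f.feature_id, set()).add(f.feature_id)
        keep = {select_representative(members, table) for members in groups.values()}
        keep |= {f.feature_id for f in table.features if f.attribution == Attribution.SRF}
        feats = sorted(
            (f for f in table.features if f.feature_id in keep), key=lambda f: (f.rt, f.mz)
        )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    _frame(table, feats, annotate=True).to_csv(path, sep=delim, index=False)


def write_final_table(table: PeakTable, final_ids: Sequence[str], path: str) -> None:
    """Write exactly the features in *final_ids* (rater-selected), in order."""
    delim = "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".txt") else ","
    index = {f.feature_id: f for f in table.features}
    feats = [index[i] for i in final_ids]
    _frame(table, feats, annotate=True).to_csv(path, sep=delim, index=False)


def write_msp(table: PeakTable, path: str) -> None:
    """Export per-feature MS2 spectra as an MSP library (skips empty spectra)."""
    with open(path, "w") as fh:
        for f in table.features:
            if len(f.ms2) == 0:
                continue
            fh.write(f"NAME: {f.feature_id}\n")
            fh.write(f"PRECURSORMZ: {f.mz:.4f}\n")
            fh.write(f"RETENTIONTIME: {f.rt:.2f}\n")
            fh.write(f"Num Peaks: {len(f.ms2)}\n")
            for mz, inten in f.ms2:
                fh.write(f"{mz:g}\t{inten:g}\n")
            fh.write("\n")
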