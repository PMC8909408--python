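"""End-to-end run orchestration: read -> clean -> cluster -> rate -> write.

``run`` is the library entry point the CLI wraps.  Every stage logs a
feature-count transition into the run manifest so the evolution of the
peak table (input = interference + fragment + TRF + SRF at each boundary)
is auditable after the fact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .adducts import DEFAULT_ADDUCT_TOLERANCE, CorrelationRule, default_positive_rules
from .errors import ConfigError, PeakrateError
from .fragments import DEFAULT_FRAGMENT_TOLERANCE
from .io import Dialect, read_alignment_table, write_final_table, write_table
from .model import Attribution, PeakTable
from .prefilter import (
    FilterConfig,
    apply_clusters,
    blank_filter,
    cluster_features,
    normalize_internal_standard,
    rsd_filter,
)
from .rater import rate_table, summarize_attributions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    filters: FilterConfig = field(default_factory=FilterConfig)
    adduct_tol: float = DEFAULT_ADDUCT_TOLERANCE
    fragment_tol: float = DEFAULT_FRAGMENT_TOLERANCE
    intensity_metric: str = "mean_biological"
    internal_standard: Optional[str] = None
    apply_blank_filter: bool = True
    apply_rsd_filter: bool = True
    recluster: bool = False
    strict_mode: bool = False
    rules: Optional[list[CorrelationRule]] = None  # None -> built-in positive six
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adduct_tol <= 0 or self.fragment_tol <= 0:
            raise ConfigError("tolerances must be > 0")


def _counts(table: PeakTable) -> dict[str, int]:
    out = {a.value: 0 for a in Attribution}
    for f in table.features:
        out[f.attribution.value] += 1
    return out


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to disk).

    On any error, partial outputs in the output directory are removed and
    the exception propagates.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    out = lambda name: os.path.join(cfg.output_dir, name)  # noqa: E731
    artifacts = [
        out("table_full.csv"),
        out("table_final.csv"),
        out("fragment_calls.csv"),
        out("summary.json"),
        out("manifest.json"),
    ]
    try:
        manifest: dict = {
            "tool": "peakrate",
            "version": __version__,
            "config": _config_dict(cfg),
            "stages": [],
        }

        table = read_alignment_table(cfg.input_path)
        manifest["stages"].append({"stage": "read", "counts": _counts(table)})

        if cfg.internal_standard:
            table = normalize_internal_standard(table, cfg.internal_standard)
            manifest["stages"].append({"stage": "normalize", "counts": _counts(table)})
        if cfg.apply_blank_filter:
            table = blank_filter(table, cfg.filters)
            manifest["stages"].append({"stage": "blank_filter", "counts": _counts(table)})
        if cfg.apply_rsd_filter:
            table = rsd_filter(table, cfg.filters)
            manifest["stages"].append({"stage": "rsd_filter", "counts": _counts(table)})

        need_clusters = cfg.recluster or any(
            f.cluster_id is None
            for f in table.features
            if f.attribution != Attribution.INTERFERENCE
        )
        if need_clusters:
            clusters = cluster_features(table, cfg.filters)
            apply_clusters(table, clusters)
            manifest["stages"].append(
                {"stage": "cluster", "counts": _counts(table), "n_clusters": len(clusters)}
            )

        rules = cfg.rules if cfg.rules is not None else default_positive_rules(cfg.adduct_tol)
        if cfg.strict_mode:
            from .strict import strict_filter_clusters

            n_pruned = strict_filter_clusters(table, cfg.filters)
            manifest["stages"].append({"stage": "strict_prune", "edges_pruned": n_pruned})
        result = rate_table(
            table,
            rules,
            fragment_tolerance=cfg.fragment_tol,
            intensity_metric=cfg.intensity_metric,
        )
        summary = summarize_attributions(result)
        manifest["stages"].append({"stage": "rate", "counts": _counts(table)})
        manifest["summary"] = dataclasses.asdict(summary)
        manifest["provenance"] = table.provenance

        write_table(table, out("table_full.csv"), kind="full")
        write_final_table(table, result.final_ids, out("table_final.csv"))
        _write_fragment_audit(result, out("fragment_calls.csv"))
        with open(out("summary.json"), "w") as fh:
            json.dump(dataclasses.asdict(summary), fh, indent=2)
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except PeakrateError:
        for p in artifacts:
            if os.path.exists(p):
                os.remove(p)
        raise


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["rules"] = (
        None
        if cfg.rules is None
        else [
            {"low": r.low_adduct.name, "high": r.high_adduct.name, "delta": r.delta}
            for r in cfg.rules
        ]
    )
    return d


def _write_fragment_audit(result, path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fragment_id", "owner_id", "matched_ms2_mz", "error", "primary"])
        for c in result.fragment_calls:
            w.writerow([c.fragment_id, c.owner_id, f"{c.matched_ms2_mz:.4f}", f"{c.error:.5f}", c.primary])
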