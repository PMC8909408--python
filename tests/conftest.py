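"""Shared fixtures: tiny hand-built tables and seeded synthetic studies."""

from __future__ import annotations

import pytest

from peakrate.model import Feature, PeakTable, SampleInfo, SampleRole, Spectrum

#: electron-corrected cation offsets used to build exact fixtures
H, NH4, NA, K = 1.007276, 18.033823, 22.989218, 38.963158


def build_table(rows, samples=None, polarity="positive"):
    """Build a PeakTable from (fid, mz, rt, heights, ms2_peaks, cluster_id) rows.

    Trailing row elements may be omitted; sample infos default to biological
    samples named from the union of height keys.
    """
    feats = []
    for row in rows:
        fid, mz, rt = row[:3]
        heights = row[3] if len(row) > 3 else {}
        ms2 = row[4] if len(row) > 4 else []
        cluster = row[5] if len(row) > 5 else None
        feats.append(
            Feature(fid, mz, rt, dict(heights), Spectrum.from_peaks(ms2), cluster_id=cluster)
        )
    if samples is None:
        sids = sorted({s for f in feats for s in f.heights})
        samples = [SampleInfo(s) for s in sids]
    return PeakTable(features=feats, samples=samples, polarity=polarity)


@pytest.fixture
def design_samples():
    """Two classes x three replicates, one blank, one QC."""
    out = []
    for cls in ("A", "B"):
        for i in range(1, 4):
            out.append(SampleInfo(f"{cls}_{i}", SampleRole.BIOLOGICAL, cls))
    out.append(SampleInfo("Blank_1", SampleRole.BLANK, "blank"))
    out.append(SampleInfo("QC_1", SampleRole.QC, "qc"))
    return out


@pytest.fixture(scope="session")
def sim_exact():
    """Seeded synthetic study with exact m/z offsets (no jitter)."""
    from peakrate.simulate import SimConfig, generate

    return generate(SimConfig(n_compounds=60, n_noise_features=20, mz_jitter_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def sim_jittered():
    """Seeded synthetic study with 2 mDa m/z jitter."""
    from peakrate.simulate import SimConfig, generate

    return generate(SimConfig(n_compounds=60, n_noise_features=20, mz_jitter_sd=0.002, seed=11))
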