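"""The 16-feature candidate bank: EpEn and BM per region/band.

Seven epoch-based-entropy features (five bands on all electrodes, plus the
8-30 Hz range on the temporal and frontal+occipital regions) and nine
bump-model features (theta/alpha/beta on frontal, occipital and temporal
regions), 16 in total; squaring the standardized primaries later doubles
this to 32 candidates.
"""

from __future__ import annotations

import pandas as pd

from .bumps import MorletParams, bm_feature, channel_bump_models
from .epen import EpEnConfig, epen_feature
from .montage import REGIONS
from .recording import EEGRecording

__all__ = ["EPEN_BANK", "BM_BANK", "FEATURE_NAMES", "extract_features", "extract_cohort_features"]

#: (region, band) pairs of the EpEn features.
EPEN_BANK: list[tuple[str, str]] = [
    ("All", "1-4"),
    ("All", "4-8"),
    ("All", "8-12"),
    ("All", "12-30"),
    ("All", "8-30"),
    ("TemporalLR", "8-30"),
    ("FrontalOccipital", "8-30"),
]

#: (region, band) pairs of the bump-model features.
BM_BANK: list[tuple[str, str]] = [
    (region, band)
    for region in ("Frontal", "Occipital", "TemporalLR")
    for band in ("4-8", "8-12", "12-30")
]


def feature_name(kind: str, region: str, band: str) -> str:
    return f"{kind}_{region}_{band}"


#: Canonical order of the 16 primary feature names.
FEATURE_NAMES: list[str] = [feature_name("EpEn", r, b) for r, b in EPEN_BANK] + [
    feature_name("BM", r, b) for r, b in BM_BANK
]


def extract_features(
    rec: EEGRecording,
    epen_cfg: EpEnConfig | None = None,
    morlet: MorletParams | None = None,
    bm_agg: str = "rate",
    subset: list[str] | None = None,
) -> dict[str, float]:
    """All primary features for one (already 1-30 Hz prefiltered) recording.

    Bump models are extracted once per channel and shared across the three
    BM bands.  ``subset`` restricts computation to the named features (e.g.
    for quick runs); the full bank is the default.
    """
    epen_cfg = epen_cfg or EpEnConfig()
    wanted = set(FEATURE_NAMES if subset is None else subset)
    out: dict[str, float] = {}
    for region, band in EPEN_BANK:
        name = feature_name("EpEn", region, band)
        if name in wanted:
            out[name] = epen_feature(rec, region, band, epen_cfg)
    bm_regions = {
        r for r, b in BM_BANK if feature_name("BM", r, b) in wanted
    }
    if bm_regions:
        chans = sorted(
            {c for r in bm_regions for c in REGIONS[r]},
            key=rec.channel_labels.index,
        )
        models = channel_bump_models(rec, chans, morlet)
        for region, band in BM_BANK:
            name = feature_name("BM", region, band)
            if name in wanted:
                region_models = {c: models[c] for c in REGIONS[region]}
                out[name] = bm_feature(rec, region, band, morlet, agg=bm_agg, models=region_models)
    return out


def extract_cohort_features(
    cohort: list[EEGRecording],
    epen_cfg: EpEnConfig | None = None,
    morlet: MorletParams | None = None,
    bm_agg: str = "rate",
    subset: list[str] | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per subject plus a 'group' column."""
    rows = {}
    groups = {}
    for rec in cohort:
        rows[rec.subject_id] = extract_features(rec, epen_cfg, morlet, bm_agg, subset)
        groups[rec.subject_id] = rec.group
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.insert(0, "group", pd.Series(groups))
    df.index.name = "subject_id"
    return df
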