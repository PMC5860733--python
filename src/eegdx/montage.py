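"""Scalp montage and region definitions.

The reference montage is a 30-electrode modified international 10-20 layout
(common reference, 11 electrodes beyond the classic 19).  Region->electrode
groupings follow the standard lobe assignment of 10-20 labels; they can be
overridden from a YAML file so that a different clinical montage can be used
without code changes.
"""

from __future__ import annotations

from pathlib import Path

import yaml

#: The 30-channel modified 10-20 montage, in acquisition order.
STANDARD_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FC7", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

_FRONTAL = ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"]
_OCCIPITAL = ["O1", "Oz", "O2"]
_TEMPORAL_LR = ["FT7", "T3", "TP7", "T5", "FT8", "T4", "TP8", "T6"]

#: Region name -> ordered electrode labels (subset of STANDARD_MONTAGE).
REGIONS: dict[str, list[str]] = {
    "All": list(STANDARD_MONTAGE),
    "Frontal": list(_FRONTAL),
    "Occipital": list(_OCCIPITAL),
    "TemporalLR": list(_TEMPORAL_LR),
    "FrontalOccipital": list(_FRONTAL) + list(_OCCIPITAL),
}


def load_region_map(path: str | Path) -> dict[str, list[str]]:
    """Load a region->channels mapping from YAML, validating labels.

    The YAML file maps region names to lists of channel labels.  Labels must
    be unique within a region and belong to the standard montage.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("region map YAML must be a mapping of name -> [channels]")
    out: dict[str, list[str]] = {}
    for name, chans in raw.items():
        if not isinstance(chans, list) or not chans:
            raise ValueError(f"region {name!r}: channel list must be non-empty")
        if len(set(chans)) != len(chans):
            raise ValueError(f"region {name!r}: duplicate channel labels")
        unknown = [c for c in chans if c not in STANDARD_MONTAGE]
        if unknown:
            raise ValueError(f"region {name!r}: unknown channels {unknown}")
        out[str(name)] = [str(c) for c in chans]
    return out
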