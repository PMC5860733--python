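"""Band-pass filtering and montage-region selection.

The clinical protocol this package follows works on 20-s artifact-free
segments, band-pass filtered 1-30 Hz with a 3rd-order digital Butterworth
filter.  Filtering here is zero-phase (forward-backward second-order
sections) by default so that burst latencies are not shifted; a single-pass
causal mode is available via ``zero_phase=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .montage import REGIONS
from .recording import EEGRecording

__all__ = [
    "FrequencyBand",
    "BANDS",
    "TABLE_BANDS",
    "bandpass_1_30",
    "band_filter",
    "select_region",
    "flag_artifacts",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval in Hz with a conventional name."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name}: need 0 < low < high, got [{self.low}, {self.high}]")


#: Standard EEG bands plus the broad 8-30 Hz range used by the feature bank.
BANDS: dict[str, FrequencyBand] = {
    "delta": FrequencyBand("delta", 1.0, 4.0),
    "theta": FrequencyBand("theta", 4.0, 8.0),
    "alpha": FrequencyBand("alpha", 8.0, 12.0),
    "beta": FrequencyBand("beta", 12.0, 30.0),
    "broad": FrequencyBand("broad", 8.0, 30.0),
}

#: Band lookup by "low-high" string, as used in feature names ("8-12" etc.).
TABLE_BANDS: dict[str, FrequencyBand] = {
    "1-4": BANDS["delta"],
    "4-8": BANDS["theta"],
    "8-12": BANDS["alpha"],
    "12-30": BANDS["beta"],
    "8-30": BANDS["broad"],
}


def _butter_sos(low: float, high: float, fs: float, order: int = 3):
    if high >= fs / 2:
        raise ValueError(
            f"band upper edge {high} Hz not below Nyquist ({fs / 2} Hz); fs too low"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def band_filter(
    rec: EEGRecording, band: FrequencyBand, order: int = 3, zero_phase: bool = True
) -> EEGRecording:
    """Band-pass filter every channel with a Butterworth filter.

    ``order`` is the analog prototype order (3 poles per band edge, the
    conventional reading of "3rd-order Butterworth band-pass").
    """
    if rec.fs < 64:
        raise ValueError(f"sampling rate {rec.fs} Hz too low (need >= 64 Hz)")
    sos = _butter_sos(band.low, band.high, rec.fs, order)
    if zero_phase:
        out = sps.sosfiltfilt(sos, rec.data, axis=1)
    else:
        out = sps.sosfilt(sos, rec.data, axis=1)
    return rec.with_data(out)


def bandpass_1_30(rec: EEGRecording, order: int = 3, zero_phase: bool = True) -> EEGRecording:
    """The protocol's global 1-30 Hz pre-filter."""
    return band_filter(rec, FrequencyBand("preproc", 1.0, 30.0), order, zero_phase)


def select_region(rec: EEGRecording, region: str | list[str]) -> EEGRecording:
    """Sub-recording restricted to a named montage region (or channel list).

    Channels keep the order in which the region definition lists them.
    """
    channels = REGIONS[region] if isinstance(region, str) else list(region)
    idx = []
    for c in channels:
        if c not in rec.channel_labels:
            raise KeyError(f"channel {c!r} not present in recording {rec.subject_id}")
        idx.append(rec.channel_labels.index(c))
    return rec.with_data(rec.data[idx], channel_labels=channels)


def flag_artifacts(rec: EEGRecording, z_thresh: float = 5.0, win_s: float = 1.0) -> np.ndarray:
    """Crude amplitude-based artifact flag per window (for real EDF intake).

    Returns a boolean array (one entry per ``win_s`` window) marking windows
    whose peak absolute amplitude on any channel exceeds ``z_thresh`` robust
    SDs of that channel.  Not part of the validated synthetic pipeline.
    """
    win = int(round(win_s * rec.fs))
    n_win = rec.n_samples // win
    mad = np.median(np.abs(rec.data - np.median(rec.data, axis=1, keepdims=True)), axis=1)
    sd = 1.4826 * np.maximum(mad, 1e-12)
    flags = np.zeros(n_win, dtype=bool)
    for w in range(n_win):
        seg = np.abs(rec.data[:, w * win : (w + 1) * win])
        flags[w] = bool((seg.max(axis=1) / sd > z_thresh).any())
    if flags.all():
        warnings.warn("all windows flagged as artifactual; thresholds may be inappropriate")
    return flags
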