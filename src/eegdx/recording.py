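"""In-memory container for one subject's multichannel EEG segment."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Diagnostic group labels used throughout the package.
GROUPS = ("SCI", "AD", "MCI", "OtherPath")


@dataclass
class EEGRecording:
    """One subject's channels x samples EEG array.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Diagnostic group label, one of ``GROUPS`` (or any string for
        externally loaded data).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered electrode labels, one per data row.
    meta : dict
        Optional metadata (e.g. age); never used by the pipeline itself.
    """

    subject_id: str
    group: str
    data: np.ndarray
    fs: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, channel_labels: list[str] | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (and optionally labels)."""
        return replace(
            self,
            data=data,
            channel_labels=list(self.channel_labels if channel_labels is None else channel_labels),
        )
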