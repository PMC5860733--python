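"""Minimal European Data Format (EDF) I/O for continuous multichannel EEG.

Implements the plain EDF variant: ASCII fixed-width header (256 bytes plus
256 per signal) followed by little-endian 16-bit data records.  Physical
values are mapped linearly onto the full digital range per channel, so a
write/read round trip is exact to one quantization step of
``(phys_max - phys_min) / 65535``.

Only what the pipeline needs is supported: equal sampling rate across
channels, one continuous segment, no annotations (EDF+ TAL channels are
ignored on read).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EEGRecording

__all__ = ["EDFError", "write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFError(ValueError):
    """Malformed EDF file; ``offset`` is the byte position of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file.

    The subject id and group label are stored in the local-patient-id header
    field so :func:`read_edf` can restore them.  Uses 1-second data records
    when the sampling rate is integral, otherwise a single record spanning
    the segment.
    """
    n_ch, n_s = rec.data.shape
    fs = rec.fs
    if float(fs).is_integer() and n_s % int(fs) == 0:
        spr = int(fs)  # samples per record
        n_rec, rec_dur = n_s // spr, 1.0
    else:
        spr, n_rec, rec_dur = n_s, 1, n_s / fs

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    header = b"".join(
        [
            _field("0", 8),
            _field(f"{rec.subject_id} {rec.group}", 80),
            _field("eegdx synthetic cohort", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            # use the full 8 ASCII chars for the record duration: it encodes
            # the sampling rate, so every digit counts for non-integral rates
            _field(f"{rec_dur:.8f}"[:8] if rec_dur != int(rec_dur) else f"{rec_dur:g}", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(_field(lab, 16) for lab in rec.channel_labels)
    sig += b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch))
    sig += b"".join(_field("uV", 8) for _ in range(n_ch))
    sig += b"".join(_field(f"{v:.8g}"[:8], 8) for v in phys_min)
    sig += b"".join(_field(f"{v:.8g}"[:8], 8) for v in phys_max)
    sig += b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    sig += b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    sig += b"".join(_field("", 80) for _ in range(n_ch))
    sig += b"".join(_field(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_field("", 32) for _ in range(n_ch))

    # re-read the truncated ASCII physical range so the scaling is consistent
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - pmin[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def _parse_num(raw: bytes, offset: int, what: str, conv=float):
    try:
        return conv(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise EDFError(f"cannot parse {what} from {raw!r}", offset) from exc


def read_edf(path: str | Path) -> EEGRecording:
    """Read a plain EDF/EDF+C file into an :class:`EEGRecording`."""
    blob = Path(path).read_bytes()
    if len(blob) < 256:
        raise EDFError("file shorter than the 256-byte fixed header", len(blob))
    n_rec = _parse_num(blob[236:244], 236, "number of data records", int)
    rec_dur = _parse_num(blob[244:252], 244, "data record duration")
    n_ch = _parse_num(blob[252:256], 252, "signal count", int)
    hdr_len = 256 * (1 + n_ch)
    if len(blob) < hdr_len:
        raise EDFError("file truncated inside the signal header", len(blob))

    def sig_fields(base: int, width: int):
        start = 256 + base * n_ch
        return [
            (blob[start + i * width : start + (i + 1) * width], start + i * width)
            for i in range(n_ch)
        ]

    labels = [raw.decode("ascii", "replace").strip() for raw, _ in sig_fields(0, 16)]
    pmin = np.array([_parse_num(r, o, "physical minimum") for r, o in sig_fields(16 + 80 + 8, 8)])
    pmax = np.array([_parse_num(r, o, "physical maximum") for r, o in sig_fields(16 + 80 + 16, 8)])
    dmin = np.array([_parse_num(r, o, "digital minimum") for r, o in sig_fields(16 + 80 + 24, 8)])
    dmax = np.array([_parse_num(r, o, "digital maximum") for r, o in sig_fields(16 + 80 + 32, 8)])
    spr = [
        _parse_num(r, o, "samples per record", int)
        for r, o in sig_fields(16 + 80 + 40 + 80, 8)
    ]

    keep = [i for i, lab in enumerate(labels) if "EDF Annotations" not in lab]
    rates = {spr[i] for i in keep}
    if len(rates) != 1:
        raise EDFError(f"mixed samples-per-record {sorted(rates)} not supported", hdr_len)
    spr0 = rates.pop()
    if rec_dur <= 0:
        raise EDFError("non-positive data record duration", 244)
    fs = spr0 / rec_dur

    rec_size = 2 * sum(spr)
    expected = hdr_len + n_rec * rec_size
    if len(blob) < expected:
        raise EDFError(
            f"data truncated: expected {expected} bytes, found {len(blob)}", len(blob)
        )
    data = np.empty((len(keep), n_rec * spr0))
    offsets = np.concatenate([[0], np.cumsum(spr)])
    raw = np.frombuffer(blob[hdr_len : hdr_len + n_rec * rec_size], dtype="<i2")
    raw = raw.reshape(n_rec, sum(spr))
    for out_i, i in enumerate(keep):
        chunk = raw[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[out_i] = (chunk - dmin[i]) * scale + pmin[i]

    patient = blob[8:88].decode("ascii", "replace").strip()
    parts = patient.split()
    subject_id = parts[0] if parts else Path(path).stem
    group = parts[1] if len(parts) > 1 else "NA"
    return EEGRecording(
        subject_id=subject_id,
        group=group,
        data=data,
        fs=fs,
        channel_labels=[labels[i] for i in keep],
    )
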