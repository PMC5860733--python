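"""Sparse time-frequency bump modeling of oscillatory EEG events.

A complex Morlet wavelet transform (about 7 cycles per wavelet, the standard
EEG trade-off between time and frequency resolution) produces a magnitude
map |W(f, t)|, which is z-scored independently at each frequency so that
transient departures from that frequency's own baseline stand out.  The
z-map is then approximated by a sparse sum of half-ellipsoid atoms

    b(theta; f, t) = a * sqrt(max(0, 1 - ((t-t_c)/w_t)^2 - ((f-f_c)/w_f)^2))

each described by five parameters: time/frequency position, time/frequency
width, and amplitude.  Atoms are extracted greedily (matching pursuit):
locate the map maximum, fit one atom by bounded local least squares around
it, subtract, repeat until the fitted amplitude falls below a threshold (2
z-units by default) or a maximum atom count is reached.  The residual energy
is non-increasing along the extraction.

The scalar "bump model" (BM) feature for a montage region and frequency
band is, by default, the rate of extracted atoms whose center frequency
falls inside the band (bumps/s), averaged over the region's channels;
amplitude-based aggregations are available via ``agg``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from scipy.optimize import least_squares

from .preprocess import TABLE_BANDS, FrequencyBand, select_region
from .recording import EEGRecording

__all__ = [
    "MorletParams",
    "TFMap",
    "Bump",
    "BumpModel",
    "morlet_cwt",
    "zscore_map",
    "fit_bumps",
    "channel_bump_models",
    "bm_feature",
    "bumps_to_frame",
]


@dataclass
class MorletParams:
    """Morlet CWT settings.

    ``cycles`` controls the number of oscillations under the Gaussian
    envelope (2*pi*f0*sigma_t = cycles); 7 gives the classic EEG-suited
    resolution compromise.  The frequency grid defaults to 1-30 Hz in 0.5 Hz
    steps, matching the analysis band.
    """

    cycles: float = 7.0
    f_min: float = 1.0
    f_max: float = 30.0
    f_step: float = 0.5
    support_sigmas: float = 4.0

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.f_min, self.f_max + 1e-9, self.f_step)

    def sigma_t(self, f: float) -> float:
        return self.cycles / (2 * np.pi * f)


@dataclass
class TFMap:
    """Magnitude (and optionally z-scored) time-frequency map."""

    freqs: np.ndarray  # Hz, (F,)
    magnitude: np.ndarray  # (F, T)
    fs: float
    edge: np.ndarray  # (F,) samples flagged unreliable at each end, per frequency
    z: np.ndarray | None = None  # (F, T) after zscore_map
    mu_f: np.ndarray | None = None
    sigma_f: np.ndarray | None = None

    @property
    def n_times(self) -> int:
        return self.magnitude.shape[1]

    def valid_mask(self) -> np.ndarray:
        """(F, T) boolean mask of columns outside the per-frequency edges."""
        T = self.n_times
        idx = np.arange(T)[None, :]
        e = self.edge[:, None]
        return (idx >= e) & (idx < T - e)


@dataclass
class Bump:
    """One half-ellipsoid atom: 5 parameters."""

    t_center: float  # s
    f_center: float  # Hz
    t_width: float  # s
    f_width: float  # Hz
    amplitude: float  # z-units

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.t_center, self.f_center, self.t_width, self.f_width, self.amplitude)


@dataclass
class BumpModel:
    bumps: list[Bump] = field(default_factory=list)
    residual_energy: list[float] = field(default_factory=list)  # after each extraction
    initial_energy: float = 0.0
    duration: float = 0.0  # usable (non-edge) seconds at mid-band

    @property
    def n_bumps(self) -> int:
        return len(self.bumps)


def morlet_cwt(signal: np.ndarray, params: MorletParams, fs: float) -> TFMap:
    """Complex Morlet wavelet magnitude map of a 1-D signal.

    Wavelets are L1-normalized so that |W| estimates the instantaneous
    amplitude of a tone at the wavelet's frequency.  Samples within one
    wavelet support of either end are flagged per frequency.
    """
    x = np.asarray(signal, dtype=float).ravel()
    T = x.size
    if T < 2 * fs:
        raise ValueError("need at least 2 s of signal for the CWT")
    freqs = params.freqs
    if freqs[-1] >= fs / 2:
        raise ValueError(f"grid frequency {freqs[-1]} Hz >= Nyquist ({fs / 2} Hz)")
    half = np.array(
        [int(np.ceil(params.support_sigmas * params.sigma_t(f) * fs)) for f in freqs]
    )
    L = next_fast_len(T + 2 * int(half.max()))
    X = fft(x, L)
    mag = np.empty((freqs.size, T))
    for i, f in enumerate(freqs):
        h = half[i]
        t = np.arange(-h, h + 1) / fs
        env = np.exp(-(t**2) / (2 * params.sigma_t(f) ** 2))
        psi = env * np.exp(2j * np.pi * f * t)
        psi *= 2.0 / env.sum()  # unit tone at f -> |W| ~ 1
        W = ifft(X * fft(psi, L))[h : h + T]
        mag[i] = np.abs(W)
    return TFMap(freqs=freqs, magnitude=mag, fs=fs, edge=half)


def zscore_map(tf: TFMap) -> TFMap:
    """Frequency-wise z-scoring: each row gets mean 0, SD 1 over time.

    Statistics are computed over non-edge columns only; constant rows are
    set to zero with a warning.
    """
    valid = tf.valid_mask()
    mu = np.empty(tf.freqs.size)
    sd = np.empty(tf.freqs.size)
    z = np.zeros_like(tf.magnitude)
    flat = []
    for i in range(tf.freqs.size):
        row = tf.magnitude[i, valid[i]]
        if row.size < 2:  # signal shorter than this frequency's edge region
            mu[i], sd[i] = 0.0, 0.0
            flat.append(tf.freqs[i])
            continue
        mu[i] = row.mean()
        sd[i] = row.std()
        if sd[i] < 1e-12:
            flat.append(tf.freqs[i])
            continue
        z[i] = (tf.magnitude[i] - mu[i]) / sd[i]
    if flat:
        warnings.warn(f"constant rows at {len(flat)} frequencies set to zero")
    tf.z, tf.mu_f, tf.sigma_f = z, mu, sd
    return tf


def _atom(t: np.ndarray, f: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Half-ellipsoid atom on a (F, T) grid; theta = (a, tc, fc, wt, wf)."""
    a, tc, fc, wt, wf = theta
    u2 = ((t[None, :] - tc) / wt) ** 2 + ((f[:, None] - fc) / wf) ** 2
    return a * np.sqrt(np.clip(1.0 - u2, 0.0, None))


def _halfmax_extent(profile: np.ndarray, peak: int, step: float) -> float:
    """Distance from peak to half-maximum, averaged over both sides."""
    val = profile[peak]
    out = []
    for direction in (1, -1):
        i = peak
        while 0 <= i + direction < profile.size and profile[i + direction] > val / 2:
            i += direction
        out.append(abs(i - peak) + 1)
    return float(np.mean(out)) * step


def fit_bumps(
    tf: TFMap, max_bumps: int = 50, min_amplitude: float = 2.0
) -> BumpModel:
    """Greedy matching-pursuit extraction of half-ellipsoid atoms.

    Requires a z-scored map (run :func:`zscore_map` first).  Stops when the
    fitted amplitude drops below ``min_amplitude`` z-units or ``max_bumps``
    atoms have been extracted.
    """
    if tf.z is None:
        raise ValueError("map is not z-scored; call zscore_map first")
    valid = tf.valid_mask()
    res = np.where(valid, tf.z, 0.0)
    dt = 1.0 / tf.fs
    df = float(tf.freqs[1] - tf.freqs[0]) if tf.freqs.size > 1 else 1.0
    t_axis = np.arange(tf.n_times) * dt
    f_axis = tf.freqs
    model = BumpModel(
        initial_energy=float(np.sum(res**2)),
        duration=float(valid[len(valid) // 2].sum() * dt),
    )
    energy = model.initial_energy
    for _ in range(max_bumps):
        fi, ti = np.unravel_index(np.argmax(res), res.shape)
        peak = res[fi, ti]
        if peak < min_amplitude:
            break
        # initial widths from the half-max extent around the peak
        # (half-ellipsoid reaches half maximum at 0.866 of its width)
        wt0 = np.clip(_halfmax_extent(res[fi], ti, dt) / 0.866, 2 * dt, 1.5)
        wf0 = np.clip(_halfmax_extent(res[:, ti], fi, df) / 0.866, 2 * df, 10.0)
        # fit window: +/- 3 initial widths; parameter bounds keep the atom's
        # support inside the window so the global residual cannot grow
        t_lo = max(0, int((t_axis[ti] - 3 * wt0) / dt))
        t_hi = min(tf.n_times, int((t_axis[ti] + 3 * wt0) / dt) + 1)
        f_lo = max(0, int(np.searchsorted(f_axis, f_axis[fi] - 3 * wf0)))
        f_hi = min(f_axis.size, int(np.searchsorted(f_axis, f_axis[fi] + 3 * wf0)) + 1)
        tw, fw = t_axis[t_lo:t_hi], f_axis[f_lo:f_hi]
        zwin = res[f_lo:f_hi, t_lo:t_hi]
        # least-squares on a time-decimated grid (the atom is smooth, full
        # sampling buys nothing); subtraction below is full resolution
        stride = max(1, tw.size // 64)
        tw_fit, z_fit = tw[::stride], zwin[:, ::stride]
        x0 = np.array([peak, t_axis[ti], f_axis[fi], wt0, wf0])
        lb = [0.0, t_axis[ti] - wt0, f_axis[fi] - wf0, dt, df / 2]
        ub = [2 * peak, t_axis[ti] + wt0, f_axis[fi] + wf0, 2 * wt0, 2 * wf0]
        x0 = np.clip(x0, lb, ub)
        sol = least_squares(
            lambda th: (_atom(tw_fit, fw, th) - z_fit).ravel(),
            x0,
            bounds=(lb, ub),
            method="trf",
            ftol=1e-5,
            xtol=1e-5,
            max_nfev=40,
        )
        theta = sol.x
        if theta[0] < min_amplitude:
            break
        res[f_lo:f_hi, t_lo:t_hi] = zwin - _atom(tw, fw, theta)
        new_energy = float(np.sum(res**2))
        # bounded fit can only improve on the zero atom, but guard anyway
        if new_energy > energy + 1e-9:
            break
        energy = new_energy
        model.bumps.append(
            Bump(
                t_center=float(theta[1]),
                f_center=float(theta[2]),
                t_width=float(theta[3]),
                f_width=float(theta[4]),
                amplitude=float(theta[0]),
            )
        )
        model.residual_energy.append(energy)
    return model


def channel_bump_models(
    rec: EEGRecording,
    channels: list[str] | str,
    params: MorletParams | None = None,
    max_bumps: int = 50,
    min_amplitude: float = 2.0,
) -> dict[str, BumpModel]:
    """CWT -> z-score -> bump extraction for each listed channel.

    Bump models depend only on the channel signal (not on a band), so one
    pass serves every band's BM feature; cache the result when computing the
    full feature bank.
    """
    params = params or MorletParams()
    sub = select_region(rec, channels)
    out: dict[str, BumpModel] = {}
    for lab, row in zip(sub.channel_labels, sub.data):
        tf = zscore_map(morlet_cwt(row, params, rec.fs))
        out[lab] = fit_bumps(tf, max_bumps=max_bumps, min_amplitude=min_amplitude)
    return out


def bm_feature(
    rec: EEGRecording,
    region: str,
    band: FrequencyBand | str,
    params: MorletParams | None = None,
    agg: str = "rate",
    max_bumps: int = 50,
    min_amplitude: float = 2.0,
    models: dict[str, BumpModel] | None = None,
) -> float:
    """Scalar BM feature: band-restricted bump statistic averaged over a region.

    ``agg``: "rate" (bumps/s, default), "mean_amplitude" (z-units) or
    "total_amplitude" (z-units/s).  Precomputed ``models`` (from
    :func:`channel_bump_models`) are reused when given.
    """
    if isinstance(band, str):
        band = TABLE_BANDS[band]
    if models is None:
        models = channel_bump_models(
            rec, region, params, max_bumps=max_bumps, min_amplitude=min_amplitude
        )
    vals = []
    for model in models.values():
        in_band = [b for b in model.bumps if band.low <= b.f_center < band.high]
        dur = max(model.duration, 1e-9)
        if agg == "rate":
            vals.append(len(in_band) / dur)
        elif agg == "mean_amplitude":
            vals.append(float(np.mean([b.amplitude for b in in_band])) if in_band else 0.0)
        elif agg == "total_amplitude":
            vals.append(float(np.sum([b.amplitude for b in in_band])) / dur)
        else:
            raise ValueError(f"unknown aggregation {agg!r}")
    return float(np.mean(vals))


def bumps_to_frame(models: dict[str, BumpModel]) -> pd.DataFrame:
    """Flatten per-channel bump models to a tidy table (CSV-ready)."""
    rows = [
        {"channel": ch, "t_center": b.t_center, "f_center": b.f_center,
         "t_width": b.t_width, "f_width": b.f_width, "amplitude": b.amplitude}
        for ch, model in models.items()
        for b in model.bumps
    ]
    return pd.DataFrame(
        rows, columns=["channel", "t_center", "f_center", "t_width", "f_width", "amplitude"]
    )
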