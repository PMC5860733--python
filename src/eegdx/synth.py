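"""Synthetic resting-state EEG cohorts with group-structured biomarkers.

Emulates the statistical structure a differential-diagnosis analysis of
Alzheimer's disease assumes in a clinical EEG cohort:

* a 1/f-shaped background (white noise makes band-limited features
  degenerate, real EEG spectra are pink);
* a sustained, occipital-dominant alpha rhythm whose *regularity* increases
  with the Alzheimer-like effect size, lowering the sample-density entropy of
  the signal (the Alzheimer literature's "reduced EEG complexity");
* transient Gaussian-windowed oscillatory bursts planted as Poisson events,
  with more theta-band bursts on frontal channels and fewer beta-band bursts
  for Alzheimer-like subjects (the "increased theta / decreased beta
  synchrony" direction).

Group parameterization: the AD group receives the full effect sizes, MCI
half of them, OtherPath draws each effect per subject uniformly between the
SCI (zero) and AD (full) levels to mimic that group's clinical
heterogeneity, and SCI is the unaffected reference.

Every planted burst is recorded in a ground-truth event log so downstream
time-frequency detection can be scored against the generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .montage import REGIONS, STANDARD_MONTAGE
from .recording import GROUPS, EEGRecording

__all__ = ["CohortSpec", "generate_cohort", "event_log", "write_manifest"]

# Spontaneous (group-independent) burst rates per channel, bursts/s.
# Kept sparse (a few events per 20-s segment): transient oscillatory events
# are rare by definition, and the frequency-wise z-scoring of the detector
# self-normalizes dense activity, which would wash group differences out.
BASE_BURST_RATES = {"theta": 0.04, "alpha": 0.10, "beta": 0.10}
BURST_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}

# Relative alpha-rhythm gain by scalp area (occipital-dominant topography).
_ALPHA_GAIN_POSTERIOR = 0.5
_ALPHA_GAIN_OTHER = 0.25


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the clinical study design this generator emulates:
    group sizes 22 SCI / 49 AD / 58 MCI / 40 other pathologies, 30-channel
    modified 10-20 montage, 256 Hz sampling, 20-s artifact-free segments.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"SCI": 22, "AD": 49, "MCI": 58, "OtherPath": 40}
    )
    fs: float = 256.0
    duration: float = 20.0
    montage: tuple[str, ...] = STANDARD_MONTAGE
    #: dimensionless >= 0; strength of the entropy reduction in AD-like groups
    effect_entropy: float = 1.0
    #: bursts/s added to the theta-band rate of AD-like *frontal* channels
    effect_theta_bursts: float = 0.16
    #: bursts/s removed from the beta-band rate of AD-like channels
    effect_beta_bursts: float = 0.05
    #: broadband background standard deviation, microvolts
    noise_sd: float = 10.0
    #: amplitude ratio of the alpha rhythm to background at occipital channels
    alpha_snr: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.montage) != 30 or len(set(self.montage)) != 30:
            raise ValueError("montage: must contain exactly 30 unique labels")
        if self.fs <= 0:
            raise ValueError("fs: must be > 0")
        if self.duration <= 0:
            raise ValueError("duration: must be > 0")
        for name in ("effect_entropy", "effect_theta_bursts", "effect_beta_bursts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be > 0")
        if self.alpha_snr < 0:
            raise ValueError("alpha_snr: must be >= 0")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"n_per_group: unknown group labels {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("n_per_group: counts must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["montage"] = list(d["montage"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "montage" in d:
            d["montage"] = tuple(d["montage"])
        return cls(**d)


def _alpha_gains(montage: tuple[str, ...]) -> np.ndarray:
    gains = np.full(len(montage), _ALPHA_GAIN_OTHER)
    for i, lab in enumerate(montage):
        if lab in REGIONS["Occipital"]:
            gains[i] = 1.0
        elif lab[0] in ("P", "T") or lab.startswith("CP"):
            gains[i] = _ALPHA_GAIN_POSTERIOR
    return gains


def _pink_noise(rng: np.random.Generator, n_ch: int, n_s: int, fs: float) -> np.ndarray:
    """1/f-power background in 1-30 Hz, unit variance per channel."""
    white = rng.standard_normal((n_ch, n_s))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_s, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= 0.5) & (freqs <= 35.0)
    shape[band] = 1.0 / np.sqrt(np.maximum(freqs[band], 1.0))
    x = np.fft.irfft(spec * shape, n=n_s, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _alpha_rhythm(
    rng: np.random.Generator, n_s: int, fs: float, f_alpha: float, regularity: float
) -> np.ndarray:
    """Unit-variance alpha oscillation.

    ``regularity`` in [0, 1) mixes a narrowband Gaussian process (0: fully
    stochastic) toward a phase-stable sinusoid (1: fully deterministic);
    the mixture is variance preserving, so only the waveform's *shape* (and
    hence its density entropy) changes, not its power.
    """
    sos = sps.butter(2, [f_alpha - 1.0, f_alpha + 1.0], btype="bandpass", fs=fs, output="sos")
    nb = sps.sosfiltfilt(sos, rng.standard_normal(n_s))
    nb /= nb.std()
    t = np.arange(n_s) / fs
    tone = np.sqrt(2.0) * np.sin(2 * np.pi * f_alpha * t + rng.uniform(0, 2 * np.pi))
    return np.sqrt(1.0 - regularity) * nb + np.sqrt(regularity) * tone


def _burst_waveform(
    n_s: int, fs: float, t_c: float, f_c: float, amp: float, phase: float
) -> np.ndarray:
    """Gaussian-windowed oscillation lasting about 4 cycles of f_c."""
    sigma = 1.0 / f_c  # +/- 2 sigma support ~ 4 periods
    t = np.arange(n_s) / fs
    env = np.exp(-0.5 * ((t - t_c) / sigma) ** 2)
    return amp * env * np.cos(2 * np.pi * f_c * (t - t_c) + phase)


def _group_effects(group: str, spec: CohortSpec, rng: np.random.Generator) -> dict[str, float]:
    full = {
        "entropy": spec.effect_entropy,
        "theta": spec.effect_theta_bursts,
        "beta": spec.effect_beta_bursts,
    }
    if group == "SCI":
        return {k: 0.0 for k in full}
    if group == "AD":
        return full
    if group == "MCI":
        return {k: 0.5 * v for k, v in full.items()}
    # OtherPath: heterogeneous, each effect drawn uniformly in [0, full]
    return {k: rng.uniform(0.0, v) if v > 0 else 0.0 for k, v in full.items()}


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate a seeded synthetic cohort.

    Returns one :class:`EEGRecording` per subject, group order SCI, AD, MCI,
    OtherPath.  Each recording's ``meta`` carries the subject's realized
    effect sizes and the ground-truth list of planted bursts
    (``meta["burst_events"]``: channel, band, t_center s, f_center Hz,
    amplitude microvolts).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_s = int(round(spec.fs * spec.duration))
    montage = tuple(spec.montage)
    frontal = {c for c in REGIONS["Frontal"] if c in montage}
    gains = _alpha_gains(montage)
    recs: list[EEGRecording] = []
    for group in GROUPS:
        for k in range(spec.n_per_group.get(group, 0)):
            eff = _group_effects(group, spec, rng)
            # the entropy effect makes the alpha rhythm more regular (more
            # sinusoid-like) and weaker — the joint "reduced complexity +
            # reduced alpha power" signature of the Alzheimer literature
            regularity = 1.0 - np.exp(-1.5 * eff["entropy"])
            alpha_scale = np.exp(-0.25 * eff["entropy"])
            data = spec.noise_sd * _pink_noise(rng, len(montage), n_s, spec.fs)
            # occipital-dominant alpha rhythm, one generator per subject
            f_alpha = float(np.clip(rng.normal(10.0, 0.5), 8.5, 11.5))
            alpha = _alpha_rhythm(rng, n_s, spec.fs, f_alpha, regularity)
            data += (
                alpha_scale * spec.alpha_snr * spec.noise_sd * gains[:, None] * alpha[None, :]
            )
            # Poisson bursts per channel and band
            events: list[dict] = []
            for ci, chan in enumerate(montage):
                for band, (lo, hi) in BURST_BANDS.items():
                    rate = BASE_BURST_RATES[band]
                    if band == "theta" and chan in frontal:
                        rate += eff["theta"]
                    if band == "beta":
                        rate = max(rate - eff["beta"], 0.0)
                    n_ev = rng.poisson(rate * spec.duration)
                    for _ in range(n_ev):
                        t_c = rng.uniform(0.5, spec.duration - 0.5)
                        f_c = rng.uniform(lo + 0.5, hi - 0.5)
                        amp = spec.noise_sd * rng.uniform(2.5, 4.0)
                        phase = rng.uniform(0, 2 * np.pi)
                        data[ci] += _burst_waveform(n_s, spec.fs, t_c, f_c, amp, phase)
                        events.append(
                            {"channel": chan, "band": band, "t_center": t_c,
                             "f_center": f_c, "amplitude": amp}
                        )
            recs.append(
                EEGRecording(
                    subject_id=f"{group}-{k:03d}",
                    group=group,
                    data=data,
                    fs=spec.fs,
                    channel_labels=list(montage),
                    meta={"effects": eff, "burst_events": events, "f_alpha": f_alpha},
                )
            )
    return recs


def event_log(cohort: list[EEGRecording]) -> pd.DataFrame:
    """Ground-truth planted-burst table for a generated cohort."""
    rows = []
    for rec in cohort:
        for ev in rec.meta.get("burst_events", []):
            rows.append({"subject_id": rec.subject_id, "group": rec.group, **ev})
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "channel", "band", "t_center", "f_center", "amplitude"]
    )


def write_manifest(cohort: list[EEGRecording], paths: list[str], out_csv: str | Path) -> None:
    """Write the cohort manifest (subject_id, group, file path) as CSV."""
    if len(paths) != len(cohort):
        raise ValueError("one path per recording required")
    pd.DataFrame(
        {"subject_id": [r.subject_id for r in cohort],
         "group": [r.group for r in cohort],
         "path": paths}
    ).to_csv(out_csv, index=False)
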