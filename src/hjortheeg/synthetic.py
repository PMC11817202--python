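"""Synthetic EEG cohorts with controllable group differences.

The signal model is a sum of independent band-limited Gaussian
processes (one per canonical sub-band, each rescaled to unit variance
and multiplied by a per-band RMS amplitude) plus an optional 1/f
"pink" background. Hjorth activity of a band-filtered epoch is the
band variance, so a multiplicative amplitude factor f applied to the
patient group shows up downstream as a variance (activity) ratio of
f² — a known ground truth for classification, statistics and
attribution recovery.

Defaults emulate the shape of a two-group resting-state screening
study: 20 patients + 20 controls, 50 four-second epochs per subject at
250 Hz over the 19-channel 10–20 montage, with the patient group's
beta/gamma amplitude elevated ×1.5 in the frontal channels F3, F4, Fz
and Fp2.

Reproducibility: each subject's generator is seeded from
``SeedSequence([master_seed, subject_index])``, so a cohort is
byte-identical under a fixed config and stable under subject
subsetting.
"""

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .bands import Band, CANONICAL_BANDS
from .errors import ConfigurationError, InvalidBandError, SignalTooShortError
from .montage import CHANNELS_19
from .preprocess import FilterSpec, design_fir, zero_phase_filter
from .recording import EEGRecording

#: Per-band RMS amplitude defaults (µV), loosely shaped like a resting
#: eyes-closed spectrum (strong slow activity, weak gamma).
DEFAULT_BAND_SD: Dict[str, float] = {
    "delta": 20.0,
    "theta": 10.0,
    "alpha": 15.0,
    "beta": 5.0,
    "gamma": 2.0,
}

#: Seconds of padding generated on each side and trimmed after filtering.
EDGE_PAD_S = 2.0


@dataclass(frozen=True)
class EffectSpec:
    """Multiplicative amplitude factor applied to the patient group."""

    channels: Tuple[str, ...] = ("F3", "F4", "Fz", "Fp2")
    bands: Tuple[str, ...] = ("beta", "gamma")
    factor: float = 1.5

    def __post_init__(self):
        if self.factor <= 0:
            raise ConfigurationError("effect factor must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_per_group: int = 20
    epochs_per_subject: int = 50
    epoch_length: float = 4.0
    fs: float = 250.0
    montage: Tuple[str, ...] = CHANNELS_19
    band_sd: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_SD))
    effect: EffectSpec = field(default_factory=EffectSpec)
    pink_background_sd: float = 2.0
    bands: Tuple[Band, ...] = CANONICAL_BANDS
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.epochs_per_subject < 1:
            raise ConfigurationError("cohort counts must be positive")
        if any(sd < 0 for sd in self.band_sd.values()) or self.pink_background_sd < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        for b in self.bands:
            b.validate_for_fs(self.fs)
        unknown = [ch for ch in self.effect.channels if ch not in self.montage]
        if unknown:
            raise ConfigurationError(f"effect channels not in montage: {unknown}")

    def amplitude(self, group: str, channel: str, band_name: str) -> float:
        sd = self.band_sd.get(band_name, 0.0)
        if (
            group == "patient"
            and channel in self.effect.channels
            and band_name in self.effect.bands
        ):
            sd *= self.effect.factor
        return sd


def band_limited_noise(
    band: Band, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band``.

    White Gaussian noise is passed through the canonical zero-phase
    band-pass filter and rescaled to unit sample variance.
    """
    band.validate_for_fs(fs)
    min_n = int(np.ceil(8 * fs / band.low))
    if n_samples < min_n:
        raise SignalTooShortError(
            f"need >= {min_n} samples for stable variance in band {band.name!r}"
        )
    taps = design_fir(FilterSpec.for_band(band), fs)
    white = rng.standard_normal(n_samples)
    out = zero_phase_filter(white, taps)[0]
    sd = out.std()
    if sd == 0:
        raise InvalidBandError(f"band {band.name!r} produced a null signal")
    return out / sd


def pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude ∝ f^-1/2 ⇒ power ∝ 1/f
    shaped = np.fft.irfft(spec * scale, n=n_samples)
    return (shaped - shaped.mean()) / shaped.std()


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, subject_index]))


def generate_recording(
    config: SimulationConfig, subject_index: int, group: str, subject_id: str
) -> EEGRecording:
    """One subject's continuous recording (padding already trimmed)."""
    fs = config.fs
    n_keep = int(round(config.epochs_per_subject * config.epoch_length * fs))
    n_pad = int(round(EDGE_PAD_S * fs))
    n_total = n_keep + 2 * n_pad
    rng = _subject_rng(config.seed, subject_index)
    data = np.empty((len(config.montage), n_keep))
    for ci, ch in enumerate(config.montage):
        sig = np.zeros(n_total)
        for band in config.bands:
            amp = config.amplitude(group, ch, band.name)
            comp = band_limited_noise(band, n_total, fs, rng)
            if amp > 0:
                sig += amp * comp
        if config.pink_background_sd > 0:
            sig += config.pink_background_sd * pink_noise(n_total, rng)
        data[ci] = sig[n_pad : n_pad + n_keep]
    return EEGRecording(
        subject_id=subject_id, group=group, fs=fs, channels=config.montage, data=data
    )


def generate_cohort(config: SimulationConfig) -> list:
    """A balanced cohort: patients P01..Pn then controls C01..Cn.

    The subject index used for seeding runs over the full cohort
    (patients first), so any subject's signal is independent of cohort
    size changes that keep its index.
    """
    cohort = []
    idx = 0
    for group, prefix in (("patient", "P"), ("control", "C")):
        for k in range(config.n_per_group):
            sid = f"{prefix}{k + 1:02d}"
            cohort.append(generate_recording(config, idx, group, sid))
            idx += 1
    return cohort
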