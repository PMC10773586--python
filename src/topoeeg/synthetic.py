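"""Synthetic annotated EEG recordings and small geometric fixtures.

The generator emulates a scalp EEG montage (19 channels at 256 Hz by
default): a 1/f "pink" background shared-shape across channels, a 10 Hz
alpha component, broadband sensor noise, and -- inside annotated seizure
intervals -- a high-amplitude rhythmic spike-wave-like discharge (4 Hz by
default) applied to every channel with per-channel phase jitter.  The goal
is a controllable, seeded stand-in for clinical recordings whose ictal and
interictal windows are separable by design, not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud
from .recording import Annotation, EEGRecording, validate_annotations

__all__ = ["SynthesisConfig", "generate_recording", "five_point_cloud"]


@dataclass
class SynthesisConfig:
    """Parameters of the synthetic EEG generator.

    Amplitudes are microvolts (RMS for the stochastic components).  The
    seizure discharge amplitude is ``amplitude_multiplier`` times the total
    background RMS, so ictal windows dominate the rhythm band by
    construction.
    """

    n_channels: int = 19
    sampling_rate: float = 256.0
    duration: float = 60.0
    seizure_intervals: list[Annotation] = field(default_factory=list)
    pink_exponent: float = 1.0
    pink_rms: float = 20.0
    alpha_freq: float = 10.0
    alpha_rms: float = 10.0
    seizure_freq: float = 4.0
    amplitude_multiplier: float = 5.0
    phase_jitter_sd: float = 0.3
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.amplitude_multiplier <= 1:
            raise ValueError("amplitude_multiplier must exceed 1")
        self.seizure_intervals = validate_annotations(
            self.seizure_intervals, self.duration
        )


# 10-20 bipolar montage labels used for default synthetic recordings.
MONTAGE_19 = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1", "FP1-F3", "F3-C3", "C3-P3",
    "P3-O1", "FP2-F4", "F4-C4", "C4-P4", "P4-O2", "FP2-F8", "F8-T8",
    "P8-O2", "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8",
]


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    weights = np.ones_like(freqs)
    nz = freqs > 0
    weights[nz] = freqs[nz] ** (-exponent / 2.0)
    weights[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * weights, n=n)
    return x / (np.std(x) + 1e-12)


def _channel_labels(n: int) -> list[str]:
    if n <= len(MONTAGE_19):
        return MONTAGE_19[:n]
    return MONTAGE_19 + [f"EEG{i}" for i in range(len(MONTAGE_19), n)]


def generate_recording(config: SynthesisConfig) -> EEGRecording:
    """Generate a seeded annotated multichannel recording.

    Within each annotated interval every channel receives a rhythmic
    discharge (fundamental plus a half-amplitude second harmonic, giving the
    sharp/slow character of a spike-wave) whose amplitude is
    ``amplitude_multiplier`` x the background RMS.  Onset is instantaneous so
    that detection-latency measurements are unambiguous.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    bg_rms = np.sqrt(
        config.pink_rms**2 + config.alpha_rms**2 + config.noise_sd**2
    )
    seiz_amp = config.amplitude_multiplier * bg_rms

    ictal = np.zeros(n, dtype=bool)
    for onset, offset in config.seizure_intervals:
        i0 = int(round(onset * config.sampling_rate))
        i1 = int(round(offset * config.sampling_rate))
        ictal[i0:i1] = True

    samples = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        x = config.pink_rms * _pink_noise(rng, n, config.pink_exponent)
        alpha_phase = rng.uniform(0, 2 * np.pi)
        x += (
            np.sqrt(2.0)
            * config.alpha_rms
            * np.sin(2 * np.pi * config.alpha_freq * t + alpha_phase)
        )
        x += config.noise_sd * rng.standard_normal(n)
        phase = rng.normal(0.0, config.phase_jitter_sd)
        burst = np.sin(2 * np.pi * config.seizure_freq * t + phase)
        burst += 0.5 * np.sin(4 * np.pi * config.seizure_freq * t + 2 * phase)
        x[ictal] += seiz_amp * burst[ictal]
        samples[ch] = x

    return EEGRecording(
        channel_labels=_channel_labels(config.n_channels),
        rate=config.sampling_rate,
        samples=samples,
        annotations=list(config.seizure_intervals),
        subject_id=f"synth{config.seed:03d}",
    )


#: The five-point planar cloud used throughout as a worked example: its
#: Rips filtration connects the two bottom points at scale 1, the two upper
#: left points at sqrt(2), closes a pentagon loop at sqrt(5), and fills it
#: at scale 3.
_FIVE_POINTS = np.array(
    [[2.0, 2.0], [0.0, 3.0], [-1.0, 2.0], [0.0, 0.0], [1.0, 0.0]]
)


def five_point_cloud() -> PointCloud:
    """Return the packaged five-point planar fixture cloud."""
    return PointCloud(
        points=_FIVE_POINTS.copy(), n_channels=5, n_folds=0, source="fixture"
    )
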