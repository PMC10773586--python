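"""Noise reduction, resampling and balanced 2-s segmentation.

The standard conditioning chain for scalp-EEG seizure work: keep a
consistent channel montage, band-pass 0.5-40 Hz (where most seizure
activity lives), bring everything to 256 Hz, then tile the annotated
seizure intervals and the distant interictal background into fixed 2-s
windows with equal class counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .recording import EEGRecording, Segment

__all__ = [
    "PreprocessConfig",
    "ChannelError",
    "BalanceError",
    "select_channels",
    "bandpass",
    "resample",
    "cut_segments",
    "preprocess_recording",
]


class ChannelError(KeyError):
    """A requested channel label is absent from the recording."""


class BalanceError(ValueError):
    """Interictal pool too small to balance the seizure segment count."""


@dataclass
class PreprocessConfig:
    """Conditioning and segmentation parameters.

    ``interictal_buffer_s`` keeps interictal windows at least that far from
    every annotated interval, guarding against pre-/post-ictal
    contamination.  ``stride_seconds`` defaults to the window length
    (non-overlapping tiling).
    """

    band: tuple[float, float] = (0.5, 40.0)
    target_rate: float = 256.0
    window_seconds: float = 2.0
    stride_seconds: Optional[float] = None
    channel_whitelist: Optional[list[str]] = None
    interictal_buffer_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.target_rate / 2:
            raise ValueError(
                f"band {self.band} invalid for Nyquist {self.target_rate / 2}"
            )
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.stride_seconds is None:
            self.stride_seconds = self.window_seconds
        if self.stride_seconds <= 0:
            raise ValueError("stride_seconds must be positive")
        if self.interictal_buffer_s < 0:
            raise ValueError("interictal_buffer_s must be >= 0")


def select_channels(recording: EEGRecording, whitelist: Sequence[str]) -> EEGRecording:
    """Restrict and reorder channels to ``whitelist`` order."""
    index = {lab: i for i, lab in enumerate(recording.channel_labels)}
    missing = [lab for lab in whitelist if lab not in index]
    if missing:
        raise ChannelError(f"channel(s) not in recording: {', '.join(missing)}")
    rows = [index[lab] for lab in whitelist]
    return recording.copy_with(
        channel_labels=list(whitelist), samples=recording.samples[rows]
    )


def bandpass(recording: EEGRecording, low: float, high: float) -> EEGRecording:
    """Zero-phase 6th-order Butterworth band-pass; preserves shape and rate.

    Forward-backward filtering keeps event timing intact, which matters for
    latency measurement downstream; order 6 gives > 20 dB rejection one
    quarter-octave past the 40 Hz edge (e.g. mains-adjacent 50 Hz).
    """
    nyq = recording.rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) invalid for Nyquist {nyq}")
    sos = signal.butter(6, [low, high], btype="bandpass", fs=recording.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return recording.copy_with(samples=filtered)


def resample(recording: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase resampling with anti-alias filtering; annotations (in
    seconds) are untouched."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if abs(target_rate - recording.rate) < 1e-9:
        return recording
    frac = Fraction(target_rate / recording.rate).limit_denominator(1000)
    out = signal.resample_poly(recording.samples, frac.numerator, frac.denominator, axis=1)
    return recording.copy_with(samples=out, rate=target_rate)


def cut_segments(recording: EEGRecording, config: PreprocessConfig) -> list[Segment]:
    """Cut balanced seizure/interictal windows.

    A window ``[t, t+W)`` is *seizure* only when fully contained in an
    annotated interval (boundary-straddling windows are discarded) and
    carries the index of that event.  Interictal candidates tile the
    stride grid at least ``interictal_buffer_s`` away from every annotated
    interval; a seeded uniform subsample matches the seizure count.
    """
    rate = recording.rate
    w = config.window_seconds
    stride = float(config.stride_seconds)
    win_len = int(round(w * rate))
    duration = recording.duration

    seizure: list[Segment] = []
    for ev, (onset, offset) in enumerate(recording.annotations):
        t = onset
        while t + w <= offset + 1e-9:
            i0 = int(round(t * rate))
            seizure.append(
                Segment(
                    samples=recording.samples[:, i0 : i0 + win_len],
                    start_time=t,
                    label="seizure",
                    subject_id=recording.subject_id,
                    event_index=ev,
                )
            )
            t += stride

    buffer = config.interictal_buffer_s
    pool: list[float] = []
    t = 0.0
    while t + w <= duration + 1e-9:
        clear = all(
            t + w <= onset - buffer + 1e-9 or t >= offset + buffer - 1e-9
            for onset, offset in recording.annotations
        )
        if clear:
            pool.append(t)
        t += stride

    n_seiz = len(seizure)
    if n_seiz == 0:
        warnings.warn(
            "no annotated interval fits a full window; returning 0 segments",
            stacklevel=2,
        )
        return []
    if len(pool) < n_seiz:
        raise BalanceError(
            f"interictal pool ({len(pool)}) smaller than seizure count ({n_seiz})"
        )
    rng = np.random.default_rng(config.seed)
    chosen = sorted(rng.choice(len(pool), size=n_seiz, replace=False))
    interictal = []
    for idx in chosen:
        t0 = pool[idx]
        i0 = int(round(t0 * rate))
        interictal.append(
            Segment(
                samples=recording.samples[:, i0 : i0 + win_len],
                start_time=t0,
                label="interictal",
                subject_id=recording.subject_id,
                event_index=None,
            )
        )
    return seizure + interictal


def preprocess_recording(recording: EEGRecording, config: PreprocessConfig) -> EEGRecording:
    """Full conditioning chain: channel selection, band-pass, resampling."""
    rec = recording
    if config.channel_whitelist:
        rec = select_channels(rec, config.channel_whitelist)
    rec = bandpass(rec, *config.band)
    rec = resample(rec, config.target_rate)
    return rec
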