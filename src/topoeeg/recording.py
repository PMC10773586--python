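"""Core containers for annotated multichannel EEG and windowed segments.

Time is measured in seconds from recording start.  Seizure annotations are
half-open intervals ``[onset, offset)`` and must be sorted, non-overlapping
and contained in the record.  Signal amplitudes are microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "Annotation",
    "EEGRecording",
    "Segment",
    "AnnotationError",
]

Label = Literal["seizure", "interictal"]


class AnnotationError(ValueError):
    """Raised when seizure intervals are malformed."""


Annotation = tuple[float, float]


def validate_annotations(
    annotations: Sequence[Annotation], duration: Optional[float] = None
) -> list[Annotation]:
    """Check sortedness, non-overlap and containment of seizure intervals.

    Returns the annotations as a list of ``(onset, offset)`` float tuples.
    """
    out: list[Annotation] = []
    prev_off = -np.inf
    for onset, offset in annotations:
        onset, offset = float(onset), float(offset)
        if not onset < offset:
            raise AnnotationError(f"empty or inverted interval [{onset}, {offset})")
        if onset < 0:
            raise AnnotationError(f"interval [{onset}, {offset}) starts before 0")
        if onset < prev_off:
            raise AnnotationError(
                f"interval [{onset}, {offset}) overlaps or precedes a previous one"
            )
        if duration is not None and offset > duration + 1e-9:
            raise AnnotationError(
                f"interval [{onset}, {offset}) exceeds record duration {duration}"
            )
        out.append((onset, offset))
        prev_off = offset
    return out


@dataclass
class EEGRecording:
    """Annotated multichannel EEG signal.

    Parameters
    ----------
    channel_labels
        One label per row of ``samples``.
    rate
        Sampling rate in Hz.
    samples
        ``(n_channels, n_times)`` array in microvolts.
    annotations
        Seizure intervals ``[onset, offset)`` in seconds.
    subject_id
        Free-form identifier carried through segmentation and evaluation.
    """

    channel_labels: list[str]
    rate: float
    samples: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.annotations = validate_annotations(self.annotations, self.duration)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.shape[1] / self.rate

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


@dataclass
class Segment:
    """A fixed-length window cut from a recording.

    ``label`` is ``"seizure"`` when the window lies fully inside an annotated
    interval and ``"interictal"`` otherwise; ``event_index`` records which
    seizure event (annotation index) a seizure window belongs to.
    """

    samples: np.ndarray
    start_time: float
    label: Label
    subject_id: str = "synthetic"
    event_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("segment samples must be a (channels, window) matrix")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def window_samples(self) -> int:
        return self.samples.shape[1]
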