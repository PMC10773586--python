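"""EDF (European Data Format) round-trip for annotated recordings.

Writing produces plain EDF: a 256-byte global header, one 256-byte header
per signal, then 1-second data records of little-endian int16.  The
physical range is set symmetrically just above the recording's absolute
maximum, so quantization error is bounded by the physical span / 2^16.
Seizure intervals travel in a sidecar text file (same path with an
``.ann.tsv`` suffix, one ``onset<TAB>offset`` pair per line) and are picked
up again on read.  Reading the signal itself goes through MNE's EDF reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import Annotation, EEGRecording, validate_annotations

__all__ = ["write_edf", "read_edf", "annotation_sidecar_path"]

_LABEL_MAX = 16  # EDF signal-label field width


class EDFError(ValueError):
    pass


def annotation_sidecar_path(path) -> Path:
    return Path(path).with_suffix(".ann.tsv")


def _field(value: str, width: int) -> bytes:
    raw = value.encode("ascii")
    if len(raw) > width:
        raise EDFError(f"field {value!r} exceeds EDF width {width}")
    return raw.ljust(width)


def _num(value: float, width: int = 8) -> bytes:
    text = f"{value:.7g}"[:width]
    return _field(text, width)


def write_edf(recording: EEGRecording, path) -> Path:
    """Write a recording as EDF plus an annotation sidecar; returns the EDF path.

    The sample count must tile into whole 1-second records.  Channel labels
    must fit EDF's 16-character field.
    """
    path = Path(path)
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise EDFError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    n_ch, n_samp = recording.samples.shape
    if n_samp % rate != 0:
        raise EDFError(
            f"{n_samp} samples do not tile into whole 1-s records at {rate} Hz"
        )
    for lab in recording.channel_labels:
        if len(lab) > _LABEL_MAX:
            raise EDFError(f"channel label {lab!r} exceeds {_LABEL_MAX} characters")
    n_rec = n_samp // rate

    pmax = float(np.max(np.abs(recording.samples))) * 1.0001
    pmax = max(pmax, 1.0)
    pmin = -pmax
    dmin, dmax = -32768, 32767

    header = b"0".ljust(8)
    header += _field(recording.subject_id[:80], 80)
    header += _field("", 80)
    header += b"01.01.20" + b"00.00.00"
    header += _field(str(256 * (n_ch + 1)), 8)
    header += _field("", 44)
    header += _field(str(n_rec), 8)
    header += _field("1", 8)
    header += _field(str(n_ch), 4)
    header += b"".join(_field(lab, 16) for lab in recording.channel_labels)
    header += _field("", 80) * n_ch
    header += _field("uV", 8) * n_ch
    header += _num(pmin) * n_ch
    header += _num(pmax) * n_ch
    header += _field(str(dmin), 8) * n_ch
    header += _field(str(dmax), 8) * n_ch
    header += _field("", 80) * n_ch
    header += _field(str(rate), 8) * n_ch
    header += _field("", 32) * n_ch
    assert len(header) == 256 * (n_ch + 1)

    # _num truncates to 8 chars, so rescale with the values actually written
    pmin_w, pmax_w = float(_num(pmin)), float(_num(pmax))
    scale = (dmax - dmin) / (pmax_w - pmin_w)
    digital = np.clip(
        np.round((recording.samples - pmin_w) * scale + dmin), dmin, dmax
    ).astype("<i2")

    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())

    write_annotation_sidecar(recording.annotations, annotation_sidecar_path(path))
    return path


def write_annotation_sidecar(annotations: list[Annotation], path) -> None:
    with open(path, "w") as fh:
        for onset, offset in annotations:
            fh.write(f"{onset!r}\t{offset!r}\n")


def read_annotation_sidecar(path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            onset, offset = line.split("\t")
            out.append((float(onset), float(offset)))
    return validate_annotations(out)


def read_edf(path, subject_id: str | None = None) -> EEGRecording:
    """Read an EDF file (MNE backend) and its annotation sidecar if present."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # MNE converts microvolt channels to volts

    sidecar = annotation_sidecar_path(path)
    if sidecar.exists():
        annotations = read_annotation_sidecar(sidecar)
    else:
        annotations = validate_annotations(
            [
                (float(on), float(on) + float(du))
                for on, du in zip(raw.annotations.onset, raw.annotations.duration)
            ]
        )

    return EEGRecording(
        channel_labels=list(raw.ch_names),
        rate=float(raw.info["sfreq"]),
        samples=samples,
        annotations=annotations,
        subject_id=subject_id if subject_id is not None else path.stem,
    )
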