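"""Audio containers, WAV round-trip, framing and pre-processing filters.

The on-disk format is RIFF PCM WAV (16-bit mono by default), matching the
acquisition protocol the pipeline targets (44.1 kHz, 16-bit, uncompressed).
Recordings live in per-subject folders as ``<subject>/<content>_<k>.wav``
where ``content`` is one of the five sustained vowels or ``speech``; both
pieces of metadata are recovered on read when the path follows that layout.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError, SignalTooShortError, UnsupportedFormatError

VOWELS = ("a", "e", "i", "o", "u")
CONTENT_TAGS = VOWELS + ("speech",)

_FILENAME_RE = re.compile(r"^(?P<content>[aeiou]|speech)_(?P<k>\d+)$")


@dataclass
class Waveform:
    """A mono audio signal with subject/class/content metadata.

    ``class_label`` uses 0 = healthy, 1 = Parkinson's disease, 2 = multiple
    sclerosis; ``None`` means unknown.  ``ground_truth`` is populated by the
    synthetic generators only and carries the exact pulse times/amplitudes
    and the clean/noise components, so tests never need the pitch tracker
    to know what the generator did.
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    class_label: int | None = None
    content: str | None = None
    augmented: bool = False
    ground_truth: "object | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("waveform must be a non-empty 1-D sample series")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ParameterError("samples must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def replace(self, **kwargs) -> "Waveform":
        return replace(self, **kwargs)


@dataclass
class FrameSeries:
    """Fixed-length, windowed analysis frames of a signal."""

    frames: np.ndarray  # shape (n_frames, frame_length)
    frame_length: int
    hop: int
    window: str
    sample_rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a RIFF PCM WAV file into a :class:`Waveform`.

    Samples are scaled to [-1, 1]; stereo is downmixed by channel
    averaging.  Subject and content metadata are parsed from a
    ``<subject>/<content>_<k>.wav`` path when it matches the convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise UnsupportedFormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise UnsupportedFormatError(f"{path}: no audio payload")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    samples = np.clip(samples, -1.0, 1.0)

    subject_id, content = "", None
    m = _FILENAME_RE.match(path.stem)
    if m:
        content = m.group("content")
        subject_id = path.parent.name
    return Waveform(samples=samples, sample_rate=int(rate), subject_id=subject_id, content=content)


def write_wav(path: str | os.PathLike, waveform: Waveform) -> None:
    """Write a waveform as 16-bit PCM mono WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # same 2^15 scale as the reader, so a round trip only quantizes
    quantized = np.clip(
        np.round(waveform.samples * 32768.0), -32768, 32767
    ).astype(np.int16)
    wavfile.write(str(path), waveform.sample_rate, quantized)


def discover_recordings(root: str | os.PathLike) -> list[Path]:
    """List WAV files under ``<root>/<subject>/*.wav``, sorted for determinism."""
    root = Path(root)
    return sorted(p for p in root.glob("*/*.wav"))


def frame_signal(
    waveform: Waveform,
    frame_length: int,
    hop: int,
    window: str = "rectangular",
) -> FrameSeries:
    """Slice a signal into fixed-length frames with multiplicative windowing.

    The frame count is ``floor((N - frame_length)/hop) + 1``; trailing
    samples that do not fill a frame are dropped.
    """
    x = waveform.samples
    n = x.size
    if hop < 1:
        raise ParameterError("hop must be >= 1")
    if frame_length < 1:
        raise ParameterError("frame_length must be >= 1")
    if frame_length > n:
        raise SignalTooShortError(
            f"frame_length {frame_length} exceeds signal length {n}"
        )
    if window not in ("rectangular", "hanning"):
        raise ParameterError(f"unknown window {window!r}")
    n_frames = (n - frame_length) // hop + 1
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    if window == "hanning":
        frames = frames * np.hanning(frame_length)[None, :]
    return FrameSeries(
        frames=frames,
        frame_length=frame_length,
        hop=hop,
        window=window,
        sample_rate=waveform.sample_rate,
    )


def highpass(waveform: Waveform, cutoff_hz: float = 60.0) -> Waveform:
    """Zero-phase 4th-order Butterworth high-pass.

    Applied forward-backward so glottal-cycle landmarks are not shifted;
    used to suppress rumble/DC ahead of cepstral analysis.
    """
    if not 0 < cutoff_hz < waveform.sample_rate / 2:
        raise ParameterError("cutoff must lie in (0, Nyquist)")
    sos = butter(4, cutoff_hz, btype="highpass", fs=waveform.sample_rate, output="sos")
    y = sosfiltfilt(sos, waveform.samples)
    peak = np.max(np.abs(y))
    if peak > 1.0:  # filtering can overshoot slightly; keep the invariant
        y = y / peak
    return waveform.replace(samples=y, ground_truth=None)
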