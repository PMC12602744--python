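"""Cepstral-domain features: MFCC, CPP, zero-crossing rate, spectral centroid.

Each quantity is summarized by its mean and median over analysis frames
(for MFCC, over the flattened coefficient-by-frame matrix), yielding the
eight cepstral features of the biomarker set.

CPP (cepstral peak prominence) follows the classic recipe: high-pass the
signal, Hann-window each frame, take the real cepstrum of the dB
magnitude spectrum, locate the peak in the quefrency band of plausible
pitch periods, and report its height above a linear regression trend
fitted to the cepstrum over that band.  Strongly periodic voices show a
prominent pitch peak; breathy or noisy ones do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fftpack import dct

from .errors import ParameterError, SignalTooShortError, SilentInputError
from .signal_io import FrameSeries, Waveform, frame_signal, highpass

_SILENCE_RMS = 1e-6


@dataclass(frozen=True)
class CepstralConfig:
    """Framing and filterbank settings shared by the cepstral extractors."""

    frame_length: int = 2048
    hop: int = 512
    n_mfcc: int = 13
    n_mels: int = 26
    cpp_frame_length: int = 2048
    cpp_hop: int = 1024
    highpass_hz: float = 60.0
    f0_min: float = 60.0
    f0_max: float = 500.0


@dataclass(frozen=True)
class CepstralSet:
    mfcc_mean: float
    mfcc_median: float
    cpp_mean: float
    cpp_median: float
    zcr_mean: float
    zcr_median: float
    sc_mean: float
    sc_median: float


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, n_fft: int, sample_rate: float) -> np.ndarray:
    """Triangular filters equally spaced on the Mel scale over [0, Nyquist]."""
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(sample_rate / 2), n_mels + 2))
    bins = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    bank = np.zeros((n_mels, bins.size))
    for m in range(n_mels):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (bins - lo) / max(mid - lo, 1e-12)
        down = (hi - bins) / max(hi - mid, 1e-12)
        bank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def mfcc_matrix(waveform: Waveform, config: CepstralConfig = CepstralConfig()) -> np.ndarray:
    """MFCC coefficient-by-frame matrix, shape (n_frames, n_mfcc).

    Stages: framing (Hann), power spectrum, Mel filterbank, log, DCT-II.
    """
    frames = frame_signal(
        waveform, config.frame_length, config.hop, window="hanning"
    )
    power = np.abs(np.fft.rfft(frames.frames, axis=1)) ** 2
    bank = _mel_filterbank(config.n_mels, config.frame_length, waveform.sample_rate)
    mel_energy = power @ bank.T
    log_energy = np.log(np.maximum(mel_energy, 1e-12))
    coeffs = dct(log_energy, type=2, axis=1, norm="ortho")[:, : config.n_mfcc]
    return coeffs


def mfcc_stats(
    waveform: Waveform, config: CepstralConfig = CepstralConfig()
) -> tuple[float, float]:
    """Mean and median of the flattened MFCC matrix."""
    coeffs = mfcc_matrix(waveform, config).ravel()
    return float(np.mean(coeffs)), float(np.median(coeffs))


def cpp_frame_values(
    waveform: Waveform, config: CepstralConfig = CepstralConfig()
) -> np.ndarray:
    """Per-frame cepstral peak prominence in dB."""
    filtered = highpass(waveform, config.highpass_hz)
    frames = frame_signal(
        filtered, config.cpp_frame_length, config.cpp_hop, window="hanning"
    )
    if frames.n_frames < 3:
        raise SignalTooShortError(
            f"CPP needs >= 3 frames, got {frames.n_frames}"
        )
    fs = waveform.sample_rate
    spectrum_db = 20.0 * np.log10(np.abs(np.fft.rfft(frames.frames, axis=1)) + 1e-12)
    cepstrum = np.fft.irfft(spectrum_db, axis=1)
    q_lo = int(np.floor(fs / config.f0_max))
    q_hi = min(int(np.ceil(fs / config.f0_min)), cepstrum.shape[1] // 2 - 1)
    if q_hi <= q_lo + 2:
        raise ParameterError("quefrency band too narrow for CPP")
    quefrencies = np.arange(q_lo, q_hi + 1)
    band = cepstrum[:, q_lo : q_hi + 1]
    values = []
    for row in band:
        k = int(np.argmax(row))
        slope, intercept = np.polyfit(quefrencies, row, 1)
        trend = slope * quefrencies[k] + intercept
        values.append(float(row[k] - trend))
    return np.asarray(values)


def cpp_stats(
    waveform: Waveform, config: CepstralConfig = CepstralConfig()
) -> tuple[float, float]:
    """Mean and median CPP over frames, in dB."""
    values = cpp_frame_values(waveform, config)
    return float(np.mean(values)), float(np.median(values))


def zcr_stats(frames: FrameSeries) -> tuple[float, float]:
    """Mean and median per-frame zero-crossing rate (sign changes / length)."""
    if frames.n_frames < 1:
        raise ParameterError("need at least one frame")
    signs = np.where(frames.frames >= 0, 1, -1)
    crossings = np.sum(np.abs(np.diff(signs, axis=1)) > 0, axis=1)
    rates = crossings / frames.frame_length
    return float(np.mean(rates)), float(np.median(rates))


def centroid_stats(frames: FrameSeries) -> tuple[float, float]:
    """Mean and median spectral centroid (Hz) over non-silent frames."""
    if frames.n_frames < 1:
        raise ParameterError("need at least one frame")
    rms = np.sqrt(np.mean(frames.frames**2, axis=1))
    keep = rms >= _SILENCE_RMS
    if not np.any(keep):
        raise SilentInputError("all frames are silent")
    mags = np.abs(np.fft.rfft(frames.frames[keep], axis=1))
    freqs = np.fft.rfftfreq(frames.frame_length, 1.0 / frames.sample_rate)
    centroids = (mags @ freqs) / np.maximum(mags.sum(axis=1), 1e-300)
    return float(np.mean(centroids)), float(np.median(centroids))


def cepstral_features(
    waveform: Waveform, config: CepstralConfig = CepstralConfig()
) -> CepstralSet:
    """All eight cepstral-domain features of a recording."""
    mfcc_mean, mfcc_median = mfcc_stats(waveform, config)
    cpp_mean, cpp_median = cpp_stats(waveform, config)
    # ZCR counts raw sign changes; the centroid needs Hann frames so
    # spectral leakage does not drag the weighted mean upward
    frames = frame_signal(waveform, config.frame_length, config.hop)
    zcr_mean, zcr_median = zcr_stats(frames)
    sc_mean, sc_median = centroid_stats(
        frame_signal(waveform, config.frame_length, config.hop, window="hanning")
    )
    return CepstralSet(
        mfcc_mean=mfcc_mean,
        mfcc_median=mfcc_median,
        cpp_mean=cpp_mean,
        cpp_median=cpp_median,
        zcr_mean=zcr_mean,
        zcr_median=zcr_median,
        sc_mean=sc_mean,
        sc_median=sc_median,
    )
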