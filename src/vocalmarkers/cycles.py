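"""Glottal-cycle boundary, fundamental-frequency and formant estimation.

The cycle tracker is a two-stage procedure: a coarse F0 track from the
normalized autocorrelation of 40 ms frames (frames whose autocorrelation
peak falls below the voicing threshold are treated as unvoiced), then
waveform peak-picking constrained to +/-30% of the locally estimated
period, with parabolic interpolation for sub-sample peak instants.
Periods are the successive differences of the detected cycle instants;
per-cycle amplitudes are peak-to-peak values in a one-period window
centred on each cycle peak.

Formants are estimated by linear-predictive (all-pole) analysis on the
signal decimated to ~11 kHz with 0.97 pre-emphasis; resonance candidates
are complex LPC pole angles with bandwidth below 400 Hz, with broader
poles (up to 700 Hz) accepted only above the highest sharp resonance,
where source rolloff blurs the LPC bandwidth estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import decimate

from .errors import InsufficientVoicingError, ParameterError
from .signal_io import Waveform

#: Conventional pitch-search bounds (Hz) for adult phonation.
DEFAULT_F0_MIN = 60.0
DEFAULT_F0_MAX = 500.0
VOICING_THRESHOLD = 0.45  # autocorrelation peak below this => unvoiced
_FRAME_SEC = 0.040
_LPC_ORDER = 12
_LPC_TARGET_RATE = 11025.0
_MAX_FORMANT_BANDWIDTH = 400.0
_LOOSE_FORMANT_BANDWIDTH = 700.0


@dataclass
class CycleSeries:
    """Ordered glottal-cycle periods (s) and peak-to-peak amplitudes.

    ``onsets`` (optional) holds the detected cycle peak instants in
    seconds, one per cycle, for estimators that need to re-segment the
    waveform cycle-synchronously.
    """

    periods: np.ndarray
    amplitudes: np.ndarray
    onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.onsets is not None:
            self.onsets = np.asarray(self.onsets, dtype=float)
        if self.periods.size != self.amplitudes.size:
            raise ParameterError("periods and amplitudes must have equal length")
        if self.periods.size < 2:
            raise ParameterError("a cycle series needs at least 2 cycles")
        if np.any(self.periods <= 0):
            raise ParameterError("all periods must be positive")
        if np.any(self.amplitudes < 0):
            raise ParameterError("amplitudes must be non-negative")

    @property
    def n(self) -> int:
        return int(self.periods.size)

    @property
    def mean_f0(self) -> float:
        return float(np.mean(1.0 / self.periods))


@dataclass
class FormantSet:
    """First formant centers (Hz) plus the fundamental; NaN marks missing."""

    f0: float
    formants: np.ndarray  # F1..Fn, increasing, NaN-padded

    @property
    def f1(self) -> float:
        return float(self.formants[0]) if self.formants.size > 0 else float("nan")

    @property
    def f2(self) -> float:
        return float(self.formants[1]) if self.formants.size > 1 else float("nan")


def _voiced_frame_track(x, fs, f0_min, f0_max):
    """Per-frame (voiced?, period-in-samples) from normalized autocorrelation."""
    frame_len = int(round(_FRAME_SEC * fs))
    hop = frame_len // 2
    lag_min = max(2, int(np.floor(fs / f0_max)))
    lag_max = int(np.ceil(fs / f0_min))
    if lag_max >= frame_len:
        frame_len = lag_max + 1
        hop = frame_len // 2
    n_frames = max(0, (x.size - frame_len) // hop + 1)
    track = []
    for j in range(n_frames):
        frame = x[j * hop : j * hop + frame_len]
        frame = frame - frame.mean()
        e0 = float(np.dot(frame, frame))
        if e0 < 1e-12:
            track.append((False, 0.0))
            continue
        spec = np.fft.rfft(frame, n=2 * frame_len)
        ac = np.fft.irfft(spec * np.conj(spec))[:frame_len]
        lags = np.arange(frame_len)
        with np.errstate(divide="ignore"):
            norm = ac / ac[0] * frame_len / np.maximum(frame_len - lags, 1)
        band = norm[lag_min : lag_max + 1]
        best = float(np.max(band))
        if best < VOICING_THRESHOLD:
            track.append((False, 0.0))
            continue
        # octave guard: the unbiased normalization inflates long lags, so
        # take the SHORTEST lag whose peak is within 10% of the best one
        near = np.flatnonzero(band >= 0.9 * best)
        k = int(near[0]) + lag_min
        # step to the local maximum around that lag
        while k + 1 <= lag_max and norm[k + 1] > norm[k]:
            k += 1
        while k - 1 >= lag_min and norm[k - 1] > norm[k]:
            k -= 1
        peak = float(norm[k])
        # parabolic refinement of the lag
        if 1 <= k < frame_len - 1:
            y0, y1, y2 = norm[k - 1], norm[k], norm[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            k = k + float(np.clip(delta, -1, 1))
        track.append((True, float(k)))
    return track, frame_len, hop


def _refine_peak(x, idx):
    """Sub-sample peak instant by parabolic interpolation around idx."""
    if idx <= 0 or idx >= x.size - 1:
        return float(idx)
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-15:
        return float(idx)
    return idx + float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))


def _pick_peaks_in_region(x, start, stop, period):
    """Walk cycle peaks through x[start:stop] given a local period estimate."""
    p = period
    seg = x[start:stop]
    if seg.size < 2 * int(p):
        return []
    anchor = start + int(np.argmax(seg[: 2 * int(p)]))
    peaks = [anchor]
    ref = float(x[anchor])  # running reference peak height; gates out silence
    # forward pass
    t = anchor
    while True:
        lo = t + int(round(0.7 * p))
        hi = t + int(round(1.3 * p))
        if hi >= stop:
            break
        k = lo + int(np.argmax(x[lo : hi + 1]))
        if x[k] < 0.2 * ref:
            break
        peaks.append(k)
        ref = 0.8 * ref + 0.2 * float(x[k])
        p = 0.8 * p + 0.2 * (k - t)  # slow adaptation of the local period
        t = k
    # backward pass from the anchor
    p = period
    ref = float(x[anchor])
    t = anchor
    while True:
        hi = t - int(round(0.7 * p))
        lo = t - int(round(1.3 * p))
        if lo < start:
            break
        k = lo + int(np.argmax(x[lo : hi + 1]))
        if x[k] < 0.2 * ref:
            break
        peaks.insert(0, k)
        ref = 0.8 * ref + 0.2 * float(x[k])
        p = 0.8 * p + 0.2 * (t - k)
        t = k
    return [_refine_peak(x, k) for k in peaks]


def estimate_cycles(
    waveform: Waveform,
    f0_min: float = DEFAULT_F0_MIN,
    f0_max: float = DEFAULT_F0_MAX,
) -> CycleSeries:
    """Detect glottal cycles and return their periods and amplitudes.

    Raises :class:`InsufficientVoicingError` when fewer than 5 cycles are
    found or the resulting mean F0 escapes ``[f0_min, f0_max]`` (silence,
    noise-only, or out-of-range phonation).
    """
    if not 0 < f0_min < f0_max < waveform.sample_rate / 2:
        raise ParameterError("need 0 < f0_min < f0_max < Nyquist")
    x = waveform.samples - np.mean(waveform.samples)
    fs = waveform.sample_rate
    track, frame_len, hop = _voiced_frame_track(x, fs, f0_min, f0_max)

    all_periods: list[float] = []
    all_amplitudes: list[float] = []
    all_onsets: list[float] = []
    j = 0
    while j < len(track):
        if not track[j][0]:
            j += 1
            continue
        j0 = j
        while j < len(track) and track[j][0]:
            j += 1
        region_periods = [track[i][1] for i in range(j0, j)]
        period = float(np.median(region_periods))
        start = j0 * hop
        stop = min((j - 1) * hop + frame_len, x.size)
        peaks = _pick_peaks_in_region(x, start, stop, period)
        if len(peaks) < 2:
            continue
        peaks_arr = np.asarray(peaks)
        periods = np.diff(peaks_arr) / fs
        half = int(round(0.45 * period))
        amps = []
        for pk in peaks_arr[:-1]:
            c = int(round(pk))
            lo, hi = max(0, c - half), min(x.size, c + half + 1)
            amps.append(float(np.ptp(x[lo:hi])))
        all_periods.extend(periods.tolist())
        all_amplitudes.extend(amps)
        all_onsets.extend((peaks_arr[:-1] / fs).tolist())

    if len(all_periods) < 5:
        raise InsufficientVoicingError(
            f"only {len(all_periods)} cycles detected (need >= 5)"
        )
    series = CycleSeries(
        np.asarray(all_periods), np.asarray(all_amplitudes), np.asarray(all_onsets)
    )
    if not f0_min <= series.mean_f0 <= f0_max:
        raise InsufficientVoicingError(
            f"mean F0 {series.mean_f0:.1f} Hz outside [{f0_min}, {f0_max}]"
        )
    return series


def _lpc_coefficients(x: np.ndarray, order: int) -> np.ndarray:
    r = np.correlate(x, x, mode="full")[x.size - 1 : x.size + order]
    r[0] *= 1.0 + 1e-9  # slight diagonal loading for numerical safety
    a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    return np.concatenate([[1.0], a])


def estimate_formants(
    waveform: Waveform,
    n_formants: int = 4,
    f0_min: float = DEFAULT_F0_MIN,
    f0_max: float = DEFAULT_F0_MAX,
    cycles: CycleSeries | None = None,
) -> FormantSet:
    """Estimate the first ``n_formants`` vocal-tract resonances plus F0.

    Fewer resolvable resonances than requested yield NaN-padded entries
    rather than an error.  A precomputed ``cycles`` series skips the
    internal pitch pass.
    """
    if not 1 <= n_formants <= 5:
        raise ParameterError("n_formants must lie in [1, 5]")
    if cycles is None:
        cycles = estimate_cycles(waveform, f0_min, f0_max)
    f0 = cycles.mean_f0

    x = waveform.samples - np.mean(waveform.samples)
    fs = float(waveform.sample_rate)
    q = max(1, int(round(fs / _LPC_TARGET_RATE)))
    if q > 1:
        x = decimate(x, q, ftype="fir", zero_phase=True)
        fs = fs / q
    x = np.append(x[0], x[1:] - 0.97 * x[:-1])  # pre-emphasis
    x = x * np.hamming(x.size)

    a = _lpc_coefficients(x, _LPC_ORDER)
    poles = np.roots(a)
    poles = poles[np.imag(poles) > 1e-6]
    freqs = np.angle(poles) * fs / (2 * np.pi)
    bws = -np.log(np.maximum(np.abs(poles), 1e-12)) * fs / np.pi
    in_range = (freqs > max(90.0, 1.2 * f0)) & (freqs < fs / 2 - 50.0)
    # sharp poles are trusted anywhere; broader ones (source rolloff blurs
    # the top formants) are accepted only above the highest sharp formant
    strict = np.sort(freqs[in_range & (bws < _MAX_FORMANT_BANDWIDTH)])
    loose = np.sort(freqs[in_range & (bws >= _MAX_FORMANT_BANDWIDTH)
                          & (bws < _LOOSE_FORMANT_BANDWIDTH)])
    candidates = list(strict)
    if candidates:
        candidates += [f for f in loose if f > candidates[-1]]
    candidates = sorted(candidates)
    formants = np.full(n_formants, np.nan)
    k = min(n_formants, len(candidates))
    formants[:k] = candidates[:k]
    return FormantSet(f0=f0, formants=formants)
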