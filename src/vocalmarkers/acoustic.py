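"""Jitter, shimmer and harmonic-to-noise features of a glottal-cycle series.

The perturbation formulas are implemented exactly as the study prints
them, with their idiosyncratic normalizations kept intact:

* absolute jitter Ja uses a ``1/N`` prefactor over the ``N-1`` consecutive
  period differences;
* the relative-jitter family (Jr, RAP, PPQ5) divides by
  ``(1/N) * sum of the first N-1 periods``;
* DDP is the same consecutive-difference sum as Ja but with a ``1/(N-1)``
  prefactor (so DDP = Ja * N/(N-1));
* shimmer-in-dB is a signed mean of ``20*log10(A_{i+1}/A_i)`` terms (it
  telescopes and may be negative);
* APQn compares each amplitude with the mean of its ``n-1`` neighbours
  (``k`` from ``-n//2`` to ``n//2`` excluding 0, edge cycles skipped),
  with a ``1/N`` outer prefactor, divided by the mean amplitude.

``classical=True`` switches every metric to the textbook MDVP-style
definition (proper means, absolute dB differences, centered neighbourhood
including the cycle itself) for cross-checking against other toolchains.

HNR is reported in the standard orientation, harmonic power over noise
power in dB, estimated by cycle-synchronous averaging: the mean cycle is
the harmonic template and per-cycle residuals are the noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cycles import CycleSeries, estimate_cycles
from .errors import InsufficientCyclesError, InsufficientVoicingError
from .signal_io import Waveform

HNR_FLOOR_DB = -20.0
HNR_CEIL_DB = 40.0


@dataclass(frozen=True)
class JitterSet:
    """Five period-perturbation metrics (Ja, DDP in seconds; rest ratios)."""

    ja: float
    jr: float
    rap: float
    ppq5: float
    ddp: float


@dataclass(frozen=True)
class ShimmerSet:
    """Six amplitude-perturbation metrics; NaN marks an APQ with too few cycles."""

    sr: float
    sdb: float
    apq3: float
    apq5: float
    apq11: float
    dda: float


def jitter_metrics(cycles: CycleSeries, classical: bool = False) -> JitterSet:
    """Compute the five jitter metrics from a cycle series.

    Needs at least 5 cycles (PPQ5 references i-2..i+2 neighbours).
    """
    t = cycles.periods
    n = t.size
    if n < 3:
        raise InsufficientCyclesError(f"RAP needs >= 3 cycles, got {n}")
    if n < 5:
        raise InsufficientCyclesError(f"PPQ5 needs >= 5 cycles, got {n}")

    diffs = np.abs(np.diff(t))  # N-1 consecutive differences
    rap_terms = np.abs((t[:-2] + t[1:-1] + t[2:]) / 3.0 - t[1:-1])
    ppq5_terms = np.abs(
        (t[:-4] + t[1:-3] + t[2:-2] + t[3:-1] + t[4:]) / 5.0 - t[2:-2]
    )

    if classical:
        denom = float(np.mean(t))
        ja = float(np.mean(diffs))
        ddp = float(np.mean(np.abs(np.diff(t, n=2))))
        rap = float(np.mean(rap_terms)) / denom
        ppq5 = float(np.mean(ppq5_terms)) / denom
        return JitterSet(ja=ja, jr=ja / denom, rap=rap, ppq5=ppq5, ddp=ddp)

    denom = float(np.sum(t[: n - 1])) / n
    ja = float(np.sum(diffs)) / n
    return JitterSet(
        ja=ja,
        jr=ja / denom,
        rap=float(np.sum(rap_terms)) / (n - 2) / denom,
        ppq5=float(np.sum(ppq5_terms)) / (n - 4) / denom,
        ddp=float(np.sum(diffs)) / (n - 1),
    )


def _apq(a: np.ndarray, n_pts: int, classical: bool) -> float:
    n = a.size
    half = n_pts // 2
    if n - 2 * half < 2:
        return float("nan")
    terms = []
    for i in range(half, n - half):
        if classical:
            nb = a[i - half : i + half + 1]  # includes the cycle itself
        else:
            nb = np.concatenate([a[i - half : i], a[i + 1 : i + half + 1]])
        terms.append(abs(a[i] - float(np.mean(nb))))
    mean_amp = float(np.mean(a))
    prefactor = len(terms) if classical else n
    return float(np.sum(terms)) / prefactor / mean_amp


def shimmer_metrics(cycles: CycleSeries, classical: bool = False) -> ShimmerSet:
    """Compute the six shimmer metrics from a cycle series.

    APQ3/APQ5/APQ11 need 4/6/12 cycles respectively; those that cannot be
    computed come back as NaN so the pipeline can impute them.
    """
    a = cycles.amplitudes
    n = a.size
    if n < 2:
        raise InsufficientCyclesError(f"shimmer needs >= 2 cycles, got {n}")

    diffs = np.abs(np.diff(a))
    positive = np.all(a > 0)
    if classical:
        denom = float(np.mean(a))
        sr = float(np.mean(diffs)) / denom
        sdb = (
            float(np.mean(np.abs(20.0 * np.log10(a[1:] / a[:-1]))))
            if positive
            else float("nan")
        )
        dda = float(np.mean(np.abs(np.diff(np.diff(a))))) if n >= 3 else float("nan")
    else:
        denom = float(np.sum(a[: n - 1])) / n
        sr = float(np.mean(diffs)) / denom
        sdb = (
            float(np.mean(20.0 * np.log10(a[1:] / a[:-1]))) if positive else float("nan")
        )
        dda = float(np.mean(diffs))

    return ShimmerSet(
        sr=sr,
        sdb=sdb,
        apq3=_apq(a, 3, classical),
        apq5=_apq(a, 5, classical),
        apq11=_apq(a, 11, classical),
        dda=dda,
    )


def harmonic_noise_ratio(
    waveform: Waveform,
    cycles: CycleSeries | None = None,
    f0_min: float = 60.0,
    f0_max: float = 500.0,
) -> float:
    """Harmonic-to-noise ratio in dB, clipped to [-20, 40].

    The waveform is cut into one-period segments centred on each detected
    cycle peak; the across-cycle mean segment is the harmonic estimate and
    the per-cycle residuals are the noise estimate.
    """
    if cycles is None:
        cycles = estimate_cycles(waveform, f0_min, f0_max)
    if cycles.n < 5:
        raise InsufficientCyclesError(f"HNR needs >= 5 cycles, got {cycles.n}")
    if cycles.onsets is None:
        raise InsufficientVoicingError("cycle series lacks onset instants")

    x = waveform.samples - np.mean(waveform.samples)
    fs = waveform.sample_rate
    seg_len = int(round(float(np.median(cycles.periods)) * fs))
    half = seg_len // 2
    max_shift = 8
    centers = []
    for onset in cycles.onsets:
        c = int(round(onset * fs))
        if c - half - max_shift < 0 or c + half + max_shift + 1 > x.size:
            continue
        centers.append(c)
    if len(centers) < 5:
        raise InsufficientCyclesError("fewer than 5 complete cycles for HNR")

    def extract(shifts):
        return np.asarray(
            [x[c + s - half : c + s + half + 1] for c, s in zip(centers, shifts)]
        )

    # detected peak instants carry +/- a sample of timing noise, which
    # would leak harmonic energy into the residual; realign each cycle to
    # the running template by an integer shift before averaging
    shifts = np.zeros(len(centers), dtype=int)
    segs = extract(shifts)
    for _ in range(3):
        template = segs.mean(axis=0)
        for i in range(len(centers)):
            c = centers[i]
            best, best_err = shifts[i], np.inf
            for s in range(-max_shift, max_shift + 1):
                seg = x[c + s - half : c + s + half + 1]
                err = float(np.sum((seg - template) ** 2))
                if err < best_err:
                    best, best_err = s, err
            shifts[i] = best
        segs = extract(shifts)
    template = segs.mean(axis=0)
    residual = segs - template
    p_harm = float(np.mean(template**2))
    p_noise = float(np.mean(residual**2))
    if p_noise <= 0 or p_harm / p_noise > 10 ** (HNR_CEIL_DB / 10):
        return HNR_CEIL_DB
    hnr = 10.0 * math.log10(p_harm / p_noise)
    return float(np.clip(hnr, HNR_FLOOR_DB, HNR_CEIL_DB))
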