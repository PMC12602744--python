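"""Synthetic voice signals with analytically known perturbation properties.

Clinical recordings of Parkinson's/multiple-sclerosis voices cannot be
redistributed, so every downstream stage is exercised against synthetic
material with exact ground truth instead.  The signal model is a
quasi-periodic train of smooth unipolar glottal pulses:

* cycle periods ``T_i = T0 * (1 + eps_i)`` with ``eps_i`` i.i.d. zero-mean
  Gaussian truncated at three standard deviations (jitter),
* per-cycle peak amplitudes ``A_i = A0 * (1 + eta_i)`` perturbed the same
  way (shimmer),
* band-limited Gaussian noise mixed in at an exact harmonic-to-noise
  power ratio (HNR), and
* optional cascaded second-order resonators imposing vowel formants.

``jitter_rel`` and ``shimmer_rel`` are calibrated to the quantity the
perturbation extractors estimate: the expected mean absolute consecutive
relative difference.  For i.i.d. Gaussian ``eps`` that expectation is
``2*sigma/sqrt(pi)``, hence ``sigma = target * sqrt(pi)/2``.

Every generator is a pure function of its spec (including the seed) and
returns, alongside the mixed waveform, a :class:`GroundTruth` sidecar with
the exact pulse times/amplitudes and the separate clean and noise
components — so oracles never depend on the pitch tracker under test.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfilt

from .errors import ParameterError, SignalTooShortError
from .signal_io import VOWELS, Waveform, write_wav

#: Preset (F1, F2, F3, F4) centers in Hz for the five sustained vowels,
#: conventional adult values; bandwidths grow with formant number.
VOWEL_FORMANTS: dict[str, tuple[float, float, float, float]] = {
    "a": (730.0, 1090.0, 2440.0, 3400.0),
    "e": (530.0, 1840.0, 2480.0, 3500.0),
    "i": (270.0, 2290.0, 3010.0, 3700.0),
    "o": (570.0, 840.0, 2410.0, 3400.0),
    "u": (300.0, 870.0, 2240.0, 3400.0),
}
FORMANT_BANDWIDTHS = (80.0, 100.0, 140.0, 180.0)

# Rosenberg-style glottal pulse: raised-cosine opening phase and a short
# cosine closing phase, as fractions of the nominal period.  The abrupt
# (but continuous) closure supplies the high-frequency source energy a
# real glottal flow has; a symmetric smooth burst would leave the upper
# formants unexcited.
_OPEN_FRACTION = 0.40
_CLOSE_FRACTION = 0.05
_BASE_AMPLITUDE = 0.8


@dataclass(frozen=True)
class PulseTrainSpec:
    """Parameters of one synthetic phonation."""

    f0: float = 120.0
    duration: float = 2.0
    sample_rate: int = 44100
    jitter_rel: float = 0.0
    shimmer_rel: float = 0.0
    hnr_db: float | None = None  # None => noiseless
    formants: tuple[tuple[float, float], ...] | None = None
    vowel_label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.sample_rate / 2:
            raise ParameterError("f0 must lie in (0, Nyquist)")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if not 0 <= self.jitter_rel <= 0.2:
            raise ParameterError("jitter_rel must lie in [0, 0.2]")
        if not 0 <= self.shimmer_rel <= 0.2:
            raise ParameterError("shimmer_rel must lie in [0, 0.2]")
        if self.formants is not None:
            centers = [f for f, _ in self.formants]
            if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
                raise ParameterError("formant centers must be strictly increasing")
            if any(not 0 < c < self.sample_rate / 2 for c in centers):
                raise ParameterError("formant centers must lie below Nyquist")
        if self.vowel_label is not None and self.vowel_label not in VOWELS:
            raise ParameterError(f"unknown vowel label {self.vowel_label!r}")

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "duration": self.duration,
            "sample_rate": self.sample_rate,
            "jitter_rel": self.jitter_rel,
            "shimmer_rel": self.shimmer_rel,
            "hnr_db": self.hnr_db,
            "formants": self.formants,
            "vowel_label": self.vowel_label,
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """Exact generator state attached to a synthetic waveform."""

    pulse_times: np.ndarray  # onset instant of each glottal cycle (s)
    pulse_amplitudes: np.ndarray  # peak amplitude of each cycle
    clean: np.ndarray  # harmonic component, same scale as the mix
    noise: np.ndarray  # additive noise component
    spec: PulseTrainSpec

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.pulse_times)

    def realized_jitter(self) -> float:
        """Mean absolute consecutive relative period difference."""
        t = self.periods
        return float(np.mean(np.abs(np.diff(t))) / np.mean(t))

    def realized_shimmer(self) -> float:
        a = self.pulse_amplitudes
        return float(np.mean(np.abs(np.diff(a))) / np.mean(a))

    def realized_hnr_db(self) -> float:
        """AC-power ratio of the stored clean and noise components, in dB."""
        if not np.any(self.noise):
            return math.inf
        p_h = float(np.var(self.clean))
        p_n = float(np.mean(self.noise**2))
        return 10.0 * math.log10(p_h / p_n)


def _truncated_gaussian(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    if sigma == 0:
        return np.zeros(size)
    eps = rng.normal(0.0, sigma, size)
    return np.clip(eps, -3 * sigma, 3 * sigma)


def _perturbation_sigma(target: float) -> float:
    # E|eps_{i+1} - eps_i| = 2*sigma/sqrt(pi) for i.i.d. Gaussian eps
    return target * math.sqrt(math.pi) / 2.0


def _resonator_cascade(x: np.ndarray, formants, sample_rate: int) -> np.ndarray:
    """All-pole second-order resonators applied in cascade."""
    y = x
    for center, bandwidth in formants:
        r = math.exp(-math.pi * bandwidth / sample_rate)
        theta = 2 * math.pi * center / sample_rate
        a = [1.0, -2 * r * math.cos(theta), r * r]
        # unity gain at the resonance center
        w = np.exp(1j * theta)
        gain = abs(1.0 / np.polyval(a[::-1], 1.0 / w))
        y = lfilter([1.0 / gain], a, y)
    return y


def _band_limited_noise(rng: np.random.Generator, n: int, sample_rate: int) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    sos = butter(4, 0.9 * sample_rate / 2, btype="lowpass", fs=sample_rate, output="sos")
    return sosfilt(sos, white)


def _synthesize(spec: PulseTrainSpec, formants=None) -> Waveform:
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    t0 = 1.0 / spec.f0
    t_open = _OPEN_FRACTION * t0
    t_close = _CLOSE_FRACTION * t0
    width = t_open + t_close

    n_cycles = int(math.floor((spec.duration - width) / t0))
    if n_cycles < 5:
        raise SignalTooShortError(
            f"duration {spec.duration}s holds fewer than 5 cycles at f0={spec.f0} Hz"
        )

    eps = _truncated_gaussian(rng, _perturbation_sigma(spec.jitter_rel), n_cycles)
    eta = _truncated_gaussian(rng, _perturbation_sigma(spec.shimmer_rel), n_cycles)
    periods = t0 * (1.0 + eps)
    onsets = np.concatenate([[0.0], np.cumsum(periods)])[:-1]
    keep = onsets + width < spec.duration
    onsets, eta = onsets[keep], eta[: keep.sum()]
    amplitudes = _BASE_AMPLITUDE * (1.0 + eta)

    n_samples = int(round(spec.duration * fs))
    clean = np.zeros(n_samples)
    w_samples = max(int(round(width * fs)), 8)
    pulse_support = np.arange(w_samples + 1)
    for onset, amp in zip(onsets, amplitudes):
        start = int(round(onset * fs))
        tt = (pulse_support + start) / fs - onset
        shape = np.where(
            tt < t_open,
            0.5 * (1.0 - np.cos(math.pi * np.clip(tt, 0.0, t_open) / t_open)),
            np.cos(math.pi * np.clip(tt - t_open, 0.0, t_close) / (2.0 * t_close)),
        )
        stop = min(start + w_samples + 1, n_samples)
        clean[start:stop] += amp * np.clip(shape[: stop - start], 0.0, None)

    if formants is not None:
        clean = _resonator_cascade(clean, formants, fs)

    if spec.hnr_db is None or math.isinf(spec.hnr_db):
        noise = np.zeros(n_samples)
    else:
        noise = _band_limited_noise(rng, n_samples, fs)
        if formants is not None:
            noise = _resonator_cascade(noise, formants, fs)
        # harmonic power is AC power: the DC offset of the unipolar pulse
        # train carries no voice energy and is removed by every analyzer
        p_clean = float(np.var(clean))
        p_noise = float(np.mean(noise**2))
        noise *= math.sqrt(p_clean / p_noise * 10.0 ** (-spec.hnr_db / 10.0))

    mix = clean + noise
    scale = 0.9 / np.max(np.abs(mix))
    mix, clean, noise = mix * scale, clean * scale, noise * scale
    amplitudes = amplitudes * scale

    gt = GroundTruth(
        pulse_times=onsets,
        pulse_amplitudes=amplitudes,
        clean=clean,
        noise=noise,
        spec=spec,
    )
    return Waveform(
        samples=mix,
        sample_rate=fs,
        content=spec.vowel_label,
        ground_truth=gt,
    )


def generate_pulse_train(spec: PulseTrainSpec) -> Waveform:
    """Generate a quasi-periodic glottal pulse train (no vocal-tract filter)."""
    return _synthesize(spec, formants=None)


def generate_vowel(spec: PulseTrainSpec) -> Waveform:
    """Generate a sustained vowel: pulse train through formant resonators.

    Formants come from ``spec.formants`` when given, otherwise from the
    built-in preset for ``spec.vowel_label``.
    """
    if spec.formants is not None:
        formants = spec.formants
    else:
        if spec.vowel_label is None:
            raise ParameterError("generate_vowel needs vowel_label or explicit formants")
        centers = VOWEL_FORMANTS[spec.vowel_label]
        formants = tuple(zip(centers, FORMANT_BANDWIDTHS))
    wave = _synthesize(spec, formants=formants)
    return wave.replace(content=spec.vowel_label)


def generate_session(
    subject_id: str,
    class_label: int,
    base_spec: PulseTrainSpec,
    seed: int,
) -> list[Waveform]:
    """Generate one subject's recording session.

    Mirrors the acquisition protocol: two phonations of each of the five
    vowels plus one speech-like item (three short vowel segments separated
    by 100 ms silences).  Each recording gets an independent child seed.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=16)
    recordings: list[Waveform] = []
    i = 0
    for vowel in VOWELS:
        for _ in range(2):
            spec = replace(base_spec, vowel_label=vowel, formants=None,
                           seed=int(child_seeds[i]))
            i += 1
            wave = generate_vowel(spec)
            recordings.append(
                wave.replace(subject_id=subject_id, class_label=class_label)
            )

    # speech-like item: concatenated vowel segments with 100 ms pauses
    fs = base_spec.sample_rate
    silence = np.zeros(int(round(0.1 * fs)))
    segments: list[np.ndarray] = []
    seg_duration = max(0.5, 6.0 / base_spec.f0)
    for vowel in ("a", "i", "u"):
        spec = replace(base_spec, vowel_label=vowel, formants=None,
                       duration=seg_duration, seed=int(child_seeds[i]))
        i += 1
        segments.append(generate_vowel(spec).samples)
        segments.append(silence)
    speech = np.concatenate(segments[:-1])
    recordings.append(
        Waveform(
            samples=speech,
            sample_rate=fs,
            subject_id=subject_id,
            class_label=class_label,
            content="speech",
        )
    )
    return recordings


def write_session(recordings: list[Waveform], root: str | os.PathLike) -> list[Path]:
    """Write a session as ``<root>/<subject>/<content>_<k>.wav`` plus JSON sidecars.

    The sidecar carries the generator spec and the exact pulse
    times/amplitudes so downstream analyses can be validated against
    ground truth after a disk round-trip.
    """
    root = Path(root)
    counters: dict[tuple[str, str], int] = {}
    paths = []
    for wave in recordings:
        key = (wave.subject_id, wave.content or "unknown")
        counters[key] = counters.get(key, 0) + 1
        path = root / wave.subject_id / f"{wave.content}_{counters[key]}.wav"
        write_wav(path, wave)
        sidecar = {
            "subject_id": wave.subject_id,
            "class_label": wave.class_label,
            "content": wave.content,
        }
        if wave.ground_truth is not None:
            gt = wave.ground_truth
            sidecar["spec"] = gt.spec.to_dict()
            sidecar["pulse_times"] = gt.pulse_times.tolist()
            sidecar["pulse_amplitudes"] = gt.pulse_amplitudes.tolist()
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Class-conditional Gaussian feature tables


@dataclass(frozen=True)
class FeatureTableSpec:
    """Spec for a class-conditional Gaussian stand-in feature table."""

    n_per_class: dict[int, int] = field(default_factory=lambda: {0: 100, 1: 100})
    class_means: dict[int, np.ndarray] | None = None
    class_sds: dict[int, np.ndarray] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_class:
            raise ParameterError("n_per_class must not be empty")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ParameterError("per-class counts must be positive")
        if not 0 <= self.missing_rate < 0.5:
            raise ParameterError("missing_rate must lie in [0, 0.5)")
        if self.class_sds is not None:
            for sds in self.class_sds.values():
                if np.any(np.asarray(sds) <= 0):
                    raise ParameterError("all class sds must be positive")


def generate_feature_table(spec: FeatureTableSpec) -> pd.DataFrame:
    """Draw a feature table shaped like the consolidated study CSV.

    Rows are drawn class-conditionally Gaussian over the 28 named
    biomarkers; a ``missing_rate`` fraction of feature cells is blanked.
    """
    from .features import FEATURE_NAMES  # local import to avoid a cycle

    n_feat = len(FEATURE_NAMES)
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for label in sorted(spec.n_per_class):
        n = spec.n_per_class[label]
        mean = (
            np.zeros(n_feat)
            if spec.class_means is None
            else np.asarray(spec.class_means[label], dtype=float)
        )
        sd = (
            np.ones(n_feat)
            if spec.class_sds is None
            else np.asarray(spec.class_sds[label], dtype=float)
        )
        values = rng.normal(mean, sd, size=(n, n_feat))
        block = pd.DataFrame(values, columns=FEATURE_NAMES)
        block.insert(0, "subject_id", [f"C{label}S{i:04d}" for i in range(n)])
        block.insert(1, "class_label", label)
        blocks.append(block)
    table = pd.concat(blocks, ignore_index=True)

    if spec.missing_rate > 0:
        mask = rng.random((len(table), n_feat)) < spec.missing_rate
        values = table[list(FEATURE_NAMES)].to_numpy()
        values[mask] = np.nan
        table[list(FEATURE_NAMES)] = values
    return table


def separated_feature_table(
    n_per_class: dict[int, int],
    separation_sd: float = 3.0,
    n_informative: int = 5,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Feature table whose classes are separated on a few designated features.

    Class ``c`` has mean ``c * separation_sd`` (in units of the unit class
    sd) on the first ``n_informative`` features and 0 elsewhere — the
    margin construction used for classifier sanity checks.
    """
    from .features import FEATURE_NAMES

    n_feat = len(FEATURE_NAMES)
    means = {}
    for label in n_per_class:
        mu = np.zeros(n_feat)
        mu[:n_informative] = label * separation_sd
        means[label] = mu
    spec = FeatureTableSpec(
        n_per_class=dict(n_per_class),
        class_means=means,
        missing_rate=missing_rate,
        seed=seed,
    )
    return generate_feature_table(spec)
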