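"""The 28-biomarker feature vector of a single recording.

17 acoustic features (F0, F1-F4, five jitter, six shimmer, HNR), three
articulation features (TVSA, QVSA, FCR — per subject, broadcast onto each
of the subject's records) and eight cepstral features (mean/median of
MFCC, CPP, ZCR, spectral centroid).  Individual extractor failures — too
little voicing, too few cycles, a too-short signal — yield NaN for the
affected features rather than aborting the record; the pipeline's
imputation step fills them later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acoustic import harmonic_noise_ratio, jitter_metrics, shimmer_metrics
from .articulation import ArticulationSet, FormantInventory, articulation_features
from .cepstral import (
    CepstralConfig,
    centroid_stats,
    cpp_stats,
    mfcc_stats,
    zcr_stats,
)
from .cycles import estimate_cycles, estimate_formants
from .errors import (
    InsufficientCyclesError,
    InsufficientVoicingError,
    ParameterError,
    SignalTooShortError,
    SilentInputError,
)
from .signal_io import VOWELS, Waveform, frame_signal

#: Canonical feature order of the consolidated table.
FEATURE_NAMES: tuple[str, ...] = (
    "F0", "F1", "F2", "F3", "F4",
    "Jitter_abs", "Jitter_rel", "Jitter_RAP", "Jitter_PPQ5", "Jitter_DDP",
    "Shim_rel", "Shim_dB", "Shim_APQ3", "Shim_APQ5", "Shim_APQ11", "Shim_DDA",
    "HNR",
    "TVSA", "QVSA", "FCR",
    "MFCC_mean", "MFCC_median", "CPP_mean", "CPP_median",
    "ZCR_mean", "ZCR_median", "SC_mean", "SC_median",
)

_RECOVERABLE = (
    InsufficientVoicingError,
    InsufficientCyclesError,
    SignalTooShortError,
    SilentInputError,
    ParameterError,
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the per-record extraction chain."""

    f0_min: float = 60.0
    f0_max: float = 500.0
    classical_definitions: bool = False
    cepstral: CepstralConfig = CepstralConfig()


def build_formant_inventory(
    recordings: list[Waveform], config: ExtractionConfig = ExtractionConfig()
) -> FormantInventory:
    """Per-subject formant inventory: mean (F1, F2) over each vowel's phonations."""
    sums: dict[str, list[tuple[float, float]]] = {}
    for wave in recordings:
        if wave.content not in VOWELS:
            continue
        try:
            fset = estimate_formants(
                wave, n_formants=2, f0_min=config.f0_min, f0_max=config.f0_max
            )
        except _RECOVERABLE:
            continue
        if math.isnan(fset.f1) or math.isnan(fset.f2):
            continue
        sums.setdefault(wave.content, []).append((fset.f1, fset.f2))
    entries = {}
    for vowel, pairs in sums.items():
        f1 = float(np.mean([p[0] for p in pairs]))
        f2 = float(np.mean([p[1] for p in pairs]))
        if 0 < f1 < f2:
            entries[vowel] = (f1, f2)
    return FormantInventory(entries=entries)


def extract_record_features(
    waveform: Waveform,
    inventory: FormantInventory | None = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> dict[str, float]:
    """All 28 features of one recording; NaN marks an extractor that failed."""
    out: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}

    cycles = None
    try:
        cycles = estimate_cycles(waveform, config.f0_min, config.f0_max)
    except _RECOVERABLE:
        pass

    if cycles is not None:
        out["F0"] = cycles.mean_f0
        try:
            j = jitter_metrics(cycles, classical=config.classical_definitions)
            out.update(
                Jitter_abs=j.ja, Jitter_rel=j.jr, Jitter_RAP=j.rap,
                Jitter_PPQ5=j.ppq5, Jitter_DDP=j.ddp,
            )
        except _RECOVERABLE:
            pass
        try:
            s = shimmer_metrics(cycles, classical=config.classical_definitions)
            out.update(
                Shim_rel=s.sr, Shim_dB=s.sdb, Shim_APQ3=s.apq3,
                Shim_APQ5=s.apq5, Shim_APQ11=s.apq11, Shim_DDA=s.dda,
            )
        except _RECOVERABLE:
            pass
        try:
            out["HNR"] = harmonic_noise_ratio(waveform, cycles)
        except _RECOVERABLE:
            pass
        try:
            fset = estimate_formants(
                waveform, n_formants=4,
                f0_min=config.f0_min, f0_max=config.f0_max, cycles=cycles,
            )
            for i in range(4):
                out[f"F{i + 1}"] = float(fset.formants[i])
        except _RECOVERABLE:
            pass

    art: ArticulationSet | None = None
    if inventory is not None and inventory.entries:
        try:
            art = articulation_features(inventory)
        except _RECOVERABLE:
            pass
    if art is not None:
        out.update(TVSA=art.tvsa, QVSA=art.qvsa, FCR=art.fcr)

    cep = config.cepstral
    try:
        out["MFCC_mean"], out["MFCC_median"] = mfcc_stats(waveform, cep)
    except _RECOVERABLE:
        pass
    try:
        out["CPP_mean"], out["CPP_median"] = cpp_stats(waveform, cep)
    except _RECOVERABLE:
        pass
    try:
        frames = frame_signal(waveform, cep.frame_length, cep.hop)
        out["ZCR_mean"], out["ZCR_median"] = zcr_stats(frames)
        out["SC_mean"], out["SC_median"] = centroid_stats(
            frame_signal(waveform, cep.frame_length, cep.hop, window="hanning")
        )
    except _RECOVERABLE:
        pass
    return out
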