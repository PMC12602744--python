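"""Shared fixtures: a small synthetic cohort on disk and feature tables.

Everything is generated at test time from seeds; nothing is stored in the
repository.  The cohort emulates the acquisition protocol (two phonations
of each of the five vowels plus a speech item per subject) with a healthy
class at low perturbation and a pathological class at elevated jitter,
shimmer and noise.
"""

from __future__ import annotations

import numpy as np
import pytest

from vocalmarkers.dataset import consolidate
from vocalmarkers.synth import (
    PulseTrainSpec,
    generate_session,
    separated_feature_table,
    write_session,
)

# (jitter_rel, shimmer_rel, hnr_db) per class: healthy vs pathological
COHORT_CLASSES = {0: (0.003, 0.008, 25.0), 1: (0.02, 0.05, 12.0)}
SUBJECTS_PER_CLASS = 2


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("cohort")
    rng = np.random.default_rng(20240)
    for label, (jit, shim, hnr) in COHORT_CLASSES.items():
        for s in range(SUBJECTS_PER_CLASS):
            base = PulseTrainSpec(
                f0=115.0 + 10.0 * s,
                duration=1.0,
                jitter_rel=jit,
                shimmer_rel=shim,
                hnr_db=hnr,
            )
            session = generate_session(
                f"c{label}s{s:02d}", label, base, seed=int(rng.integers(0, 2**31 - 1))
            )
            write_session(session, root)
    return root


@pytest.fixture(scope="session")
def cohort_table(cohort_dir):
    return consolidate(cohort_dir)


@pytest.fixture(scope="session")
def separated_table():
    """200-row binary table with class means 3 sd apart on 5 features."""
    return separated_feature_table({0: 100, 1: 100}, separation_sd=3.0, seed=7)
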