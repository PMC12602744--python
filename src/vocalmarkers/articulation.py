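"""Vowel-space features from corner-vowel formants.

The vowel space is the polygon spanned by a speaker's vowels in the
(F1, F2) plane; neurological dysarthria centralizes vowels and shrinks
it.  Three per-subject features are derived from the corner vowels:

* tVSA — area of the /i/-/a/-/u/ triangle,
* qVSA — area of the /i/-/e/-/a/-/u/ quadrilateral,
* FCR  — formant centralization ratio
  ``(F2u + F2a + F1i + F1u) / (F2i + F1a)``, which moves toward 2 as the
  corner vowels collapse onto a common centre.

The two area formulas are signed (shoelace) expressions; areas are
reported as absolute values since vertex orientation is not meaningful
here.  Formants are averaged over a subject's available phonations of
each vowel before the features are computed, and the resulting values
are broadcast onto every record of that subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError
from .signal_io import VOWELS


@dataclass
class FormantInventory:
    """Per-subject map vowel -> mean (F1, F2) over that subject's phonations."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for vowel, (f1, f2) in self.entries.items():
            if vowel not in VOWELS:
                raise ParameterError(f"unknown vowel {vowel!r}")
            if not (0 < f1 < f2):
                raise ParameterError(
                    f"/{vowel}/: need 0 < F1 < F2, got ({f1}, {f2})"
                )

    def has(self, *vowels: str) -> bool:
        return all(v in self.entries for v in vowels)

    def f1(self, vowel: str) -> float:
        return self.entries[vowel][0]

    def f2(self, vowel: str) -> float:
        return self.entries[vowel][1]


@dataclass(frozen=True)
class ArticulationSet:
    """tVSA and qVSA in Hz^2, FCR dimensionless; NaN marks missing."""

    tvsa: float
    qvsa: float
    fcr: float


def articulation_features(inv: FormantInventory) -> ArticulationSet:
    """Compute tVSA, qVSA and FCR from a formant inventory.

    Missing prerequisite vowels yield NaN fields rather than errors:
    tVSA and FCR need /i/,/a/,/u/; qVSA additionally needs /e/.
    An entirely empty inventory is a parameter error.
    """
    if not inv.entries:
        raise ParameterError("empty formant inventory")

    tvsa = qvsa = fcr = float("nan")
    if inv.has("i", "a", "u"):
        f1i, f2i = inv.entries["i"]
        f1a, f2a = inv.entries["a"]
        f1u, f2u = inv.entries["u"]
        tvsa = abs(
            0.5 * (f1i * (f2a - f2u) + f1a * (f2u - f2i) + f1u * (f2i - f2a))
        )
        fcr = (f2u + f2a + f1i + f1u) / (f2i + f1a)
        if inv.has("e"):
            f1e, f2e = inv.entries["e"]
            qvsa = abs(
                0.5
                * (
                    (f1e * f2i + f1a * f2e + f1u * f2a + f1i * f2u)
                    - (f1i * f2e + f1e * f2a + f1a * f2u + f1u * f2i)
                )
            )
    # partial inventories without the /i/,/a/,/u/ corners still return,
    # with every field missing, for the pipeline's imputation step
    return ArticulationSet(tvsa=tvsa, qvsa=qvsa, fcr=fcr)
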