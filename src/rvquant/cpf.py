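"""Cone-pyramid formula (CPF) RV quantification.

Volumes from two four-chamber linear measurements:

    EDV = 1.21 * Dd**2 * Ld        ESV = 1.21 * Ds**2 * Ls      (mL, cm)
    EF  = (EDV - ESV) * 100 / EDV  (%)

plus body-surface-area indexing (mL/m^2) and sex-specific reference
classification: RV enlargement if the EDV index exceeds 123 (men) / 104
(women) mL/m^2 or the ESV index exceeds 59 / 48 mL/m^2; reduced RV function
if EF falls below 42% (men) / 46% (women).  All thresholds are strict
inequalities.  The coefficient ``k`` is a named parameter (default 1.21) so
it can be swapped for a geometrically calibrated value in sensitivity
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .geometry import CPF_K

__all__ = [
    "MethodResult",
    "ReferenceThresholds",
    "RVClassification",
    "DEFAULT_THRESHOLDS",
    "cpf_volume",
    "ejection_fraction",
    "index_to_bsa",
    "classify_rv",
]


@dataclass(frozen=True)
class ReferenceThresholds:
    """Sex-specific CMR reference limits (volumes in mL/m^2, EF in %)."""

    edvi_male: float = 123.0
    edvi_female: float = 104.0
    esvi_male: float = 59.0
    esvi_female: float = 48.0
    ef_male: float = 42.0
    ef_female: float = 46.0

    def __post_init__(self) -> None:
        for f in ("edvi_male", "edvi_female", "esvi_male", "esvi_female",
                  "ef_male", "ef_female"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


DEFAULT_THRESHOLDS = ReferenceThresholds()


@dataclass(frozen=True)
class RVClassification:
    """Reference-limit flags for one subject and one method."""

    enlarged_edv: bool
    enlarged_esv: bool
    reduced_ef: bool


@dataclass(frozen=True)
class MethodResult:
    """EDV/ESV/EF (+BSA-indexed) for one subject under one method."""

    subject: str
    method: str  # "standard" | "cpf"
    edv: float  # mL
    esv: float  # mL
    ef: float  # %
    edvi: float  # mL/m^2
    esvi: float  # mL/m^2
    classification: Optional[RVClassification] = None


def cpf_volume(diameter: float, length: float, k: float = CPF_K) -> float:
    """``k * diameter**2 * length`` in mL (inputs in cm)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    return k * diameter**2 * length


def ejection_fraction(edv: float, esv: float) -> float:
    """(EDV - ESV) * 100 / EDV in percent.

    A negative value (ESV > EDV, possible with noisy measurements) is
    returned as-is with a warning — clamping would bias downstream
    agreement statistics.
    """
    if edv <= 0:
        raise ValueError(f"EDV must be > 0 for an ejection fraction, got {edv}")
    ef = (edv - esv) * 100.0 / edv
    if ef < 0:
        warnings.warn(f"negative ejection fraction ({ef:.1f}%): ESV > EDV",
                      stacklevel=2)
    return ef


def index_to_bsa(volume: float, bsa: float) -> float:
    """Volume (mL) divided by body surface area (m^2) -> mL/m^2."""
    if bsa <= 0:
        raise ValueError(f"BSA must be > 0, got {bsa}")
    return volume / bsa


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("male", "m"):
        return "male"
    if s in ("female", "f"):
        return "female"
    raise ValueError(f"unknown sex label: {sex!r}")


def classify_rv(
    sex: str,
    edvi: float,
    esvi: float,
    ef: float,
    thresholds: ReferenceThresholds = DEFAULT_THRESHOLDS,
) -> RVClassification:
    """Strict-inequality reference classification (enlargement / dysfunction)."""
    male = _norm_sex(sex) == "male"
    return RVClassification(
        enlarged_edv=edvi > (thresholds.edvi_male if male else thresholds.edvi_female),
        enlarged_esv=esvi > (thresholds.esvi_male if male else thresholds.esvi_female),
        reduced_ef=ef < (thresholds.ef_male if male else thresholds.ef_female),
    )
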