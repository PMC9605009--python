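"""Perimetric photometry: decibels, apostilbs and cd/m².

Perimetric sensitivity is expressed as attenuation of a 0-dB reference
luminance (10,000 asb, the Humphrey convention): ``L(dB) = L0 · 10^(-dB/10)``.
Higher dB means a dimmer stimulus was still seen, i.e. better sensitivity.
One apostilb equals 1/π cd/m².

The simulated display ceiling of 125.73 cd/m² (≈ 395 asb) sets the device
floor near 14 dB; 40 dB (1 asb ≈ 0.318 cd/m²) is the conventional test
ceiling.  The bisection strategy operates on the nominal integer interval
[14, 40]; :func:`clamp_to_device` enforces what is physically displayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LuminanceSpec",
    "DEFAULT_SPEC",
    "db_to_asb",
    "asb_to_cdm2",
    "cdm2_to_asb",
    "luminance_to_db",
    "device_floor_db",
    "clamp_to_device",
    "DB_TEST_FLOOR",
    "DB_TEST_CEILING",
]

#: Nominal test-range endpoints used by the thresholding strategy (dB).
DB_TEST_FLOOR = 14.0
DB_TEST_CEILING = 40.0


@dataclass(frozen=True)
class LuminanceSpec:
    """Photometric configuration of the simulated display.

    Attributes
    ----------
    reference_asb : float
        Luminance of a 0-dB stimulus in apostilbs (Humphrey convention:
        10,000 asb).
    max_device_cdm2 : float
        Maximum display luminance in cd/m²; determines the dB floor.
    background_cdm2 : float
        Adaptation background in cd/m².
    """

    reference_asb: float = 10_000.0
    max_device_cdm2: float = 125.73
    background_cdm2: float = 10.0

    def __post_init__(self) -> None:
        if min(self.reference_asb, self.max_device_cdm2, self.background_cdm2) <= 0:
            raise ValueError("all luminances must be strictly positive")
        if self.max_device_cdm2 <= self.background_cdm2:
            raise ValueError("display ceiling must exceed the background luminance")


DEFAULT_SPEC = LuminanceSpec()


def db_to_asb(db: float, spec: LuminanceSpec = DEFAULT_SPEC) -> float:
    """Stimulus luminance in apostilbs for an attenuation of ``db`` decibels."""
    if not math.isfinite(db):
        raise ValueError("dB value must be finite")
    return spec.reference_asb * 10.0 ** (-db / 10.0)


def asb_to_cdm2(asb: float) -> float:
    """Convert apostilbs to cd/m² (divide by π)."""
    if asb < 0:
        raise ValueError("luminance cannot be negative")
    return asb / math.pi


def cdm2_to_asb(cdm2: float) -> float:
    """Convert cd/m² to apostilbs (multiply by π)."""
    if cdm2 < 0:
        raise ValueError("luminance cannot be negative")
    return cdm2 * math.pi


def luminance_to_db(asb: float, spec: LuminanceSpec = DEFAULT_SPEC) -> float:
    """Attenuation in dB of a stimulus of the given luminance (asb)."""
    if asb <= 0:
        raise ValueError("luminance must be strictly positive to express in dB")
    return 10.0 * math.log10(spec.reference_asb / asb)


def device_floor_db(spec: LuminanceSpec = DEFAULT_SPEC) -> float:
    """Dimmest *attenuation* the display can realise: the dB of its maximum luminance.

    For the default spec this is 10·log10(10000 / (125.73·π)) ≈ 14.03 dB —
    the reason sensitivities below 14 dB are undetectable on this device.
    """
    return luminance_to_db(cdm2_to_asb(spec.max_device_cdm2), spec)


def clamp_to_device(db: float, spec: LuminanceSpec = DEFAULT_SPEC) -> tuple[float, bool]:
    """Clamp a requested intensity into the displayable/testable gamut.

    Returns ``(displayable_db, clamped)``.  Values below the device floor
    (brighter than the display can show) are raised to the floor; values
    above the 40 dB test ceiling are lowered to it.
    """
    if not math.isfinite(db):
        raise ValueError("dB value must be finite")
    floor = device_floor_db(spec)
    if db < floor:
        return floor, True
    if db > DB_TEST_CEILING:
        return DB_TEST_CEILING, True
    return db, False
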