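"""Chronic feeding-exposure dose arithmetic.

ppb is interpreted as ng of active ingredient per mL of feeding solution
(mass per volume of the sucrose solution; the solution's density is ignored,
consistent with the standard reporting convention for spiked sucrose).
Conversions to molarity use ppb * 1000 / MW (ng/mL -> nmol/L).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ExposureSpec",
    "ppb_to_nanomolar",
    "nanomolar_to_ppb",
    "daily_dose",
    "IMIDACLOPRID_MW",
    "SULFOXAFLOR_MW",
]

IMIDACLOPRID_MW = 255.66  # g/mol
SULFOXAFLOR_MW = 277.27  # g/mol


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


def ppb_to_nanomolar(concentration_ppb: float, molecular_weight: float) -> float:
    """ng/mL -> nmol/L: concentration * 1000 / MW.

    e.g. 50 ppb imidacloprid (MW 255.66) -> 195.57 nM (reported as 195 nM).
    """
    _require_positive(concentration_ppb=concentration_ppb, molecular_weight=molecular_weight)
    return concentration_ppb * 1000.0 / molecular_weight


def nanomolar_to_ppb(concentration_nm: float, molecular_weight: float) -> float:
    """Inverse of :func:`ppb_to_nanomolar`."""
    _require_positive(concentration_nm=concentration_nm, molecular_weight=molecular_weight)
    return concentration_nm * molecular_weight / 1000.0


def daily_dose(daily_volume_ul: float, concentration_ppb: float) -> float:
    """Daily active-ingredient dose (ng/day) from consumption.

    volume (uL/day) * concentration (ng/mL) / 1000; zero volume gives zero.
    """
    if daily_volume_ul < 0:
        raise ValueError(f"daily_volume_ul must be >= 0, got {daily_volume_ul}")
    _require_positive(concentration_ppb=concentration_ppb)
    return daily_volume_ul * concentration_ppb / 1000.0


@dataclass(frozen=True)
class ExposureSpec:
    """A chronic feeding exposure: solution concentration, compound molecular
    weight, and measured daily consumption per animal."""

    concentration_ppb: float
    molecular_weight: float
    daily_volume_ul: float

    def __post_init__(self) -> None:
        _require_positive(
            concentration_ppb=self.concentration_ppb,
            molecular_weight=self.molecular_weight,
            daily_volume_ul=self.daily_volume_ul,
        )

    @property
    def nanomolar(self) -> float:
        return ppb_to_nanomolar(self.concentration_ppb, self.molecular_weight)

    @property
    def dose_ng_per_day(self) -> float:
        return daily_dose(self.daily_volume_ul, self.concentration_ppb)
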