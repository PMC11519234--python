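"""Gas-exchange computation from ventilation and gas fractions.

V̇o₂ and V̇co₂ are obtained from inspired ventilation and the inspired /
expired O₂ and CO₂ fractions via the Haldane transformation: nitrogen is
neither consumed nor produced, so the expired ventilation can be
reconstructed from the nitrogen balance

    V̇_E = V̇_I · F_IN2 / F_EN2,   F_N2 = 1 − F_O2 − F_CO2,

which gives

    V̇o₂  = V̇_I · (F_IO2 − F_IN2/F_EN2 · F_EO2)
    V̇co₂ = V̇_I · (F_IN2/F_EN2 · F_ECO2 − F_ICO2).

For ambient air F_IO2 = 0.2093 and F_ICO2 = 0.0003, so the inspired
nitrogen fraction is exactly 0.7904.  Volumes are assumed already
standardised (STPD); no analyzer drift correction is attempted here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import DomainError

__all__ = ["GasSample", "GasDerived", "compute_vo2", "compute_vco2", "derive_all",
           "FIO2_AMBIENT", "FICO2_AMBIENT"]

FIO2_AMBIENT = 0.2093
FICO2_AMBIENT = 0.0003

#: Negative computed uptakes larger than this are an input error; smaller
#: ones (measurement noise around zero) are clamped to 0 with a warning.
_NEGATIVE_TOL = 1e-3


@dataclass(frozen=True)
class GasSample:
    """Inspired ventilation plus inspired/expired gas fractions for one stage."""

    vi: float  # inspired ventilation, L·min⁻¹
    feo2: float  # expired O2 fraction (0-1)
    feco2: float  # expired CO2 fraction (0-1)
    fio2: float = FIO2_AMBIENT
    fico2: float = FICO2_AMBIENT

    def __post_init__(self) -> None:
        if not self.vi > 0:
            raise DomainError(f"vi must be > 0, got {self.vi}")
        for name in ("feo2", "feco2", "fio2", "fico2"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise DomainError(f"{name} must be in [0, 1), got {v}")
        if not 0 < self.feo2 + self.feco2 < 1:
            raise DomainError(
                f"feo2 + feco2 must be in (0, 1), got {self.feo2 + self.feco2}"
            )

    @property
    def fin2(self) -> float:
        """Inspired nitrogen fraction, 1 − F_IO2 − F_ICO2 (0.7904 for air)."""
        return 1.0 - self.fio2 - self.fico2

    @property
    def fen2(self) -> float:
        return 1.0 - self.feo2 - self.feco2


@dataclass(frozen=True)
class GasDerived:
    """Derived gas-exchange values; None marks an undefined ratio (vo2 = 0)."""

    vo2: float
    vco2: float
    rer: float | None
    ve_vo2: float | None
    ve_vco2: float | None


def _clamp_negative(value: float, what: str) -> float:
    if value < 0:
        if value < -_NEGATIVE_TOL:
            raise DomainError(f"{what} = {value:.4g} L/min is negative beyond tolerance")
        warnings.warn(f"{what} slightly negative ({value:.2e}); clamped to 0",
                      stacklevel=3)
        return 0.0
    return value


def compute_vo2(sample: GasSample) -> float:
    """Oxygen uptake (L·min⁻¹) by the Haldane transformation."""
    haldane = sample.fin2 / sample.fen2
    vo2 = sample.vi * (sample.fio2 - haldane * sample.feo2)
    return _clamp_negative(vo2, "vo2")


def compute_vco2(sample: GasSample) -> float:
    """Carbon-dioxide output (L·min⁻¹) by the Haldane transformation."""
    haldane = sample.fin2 / sample.fen2
    vco2 = sample.vi * (haldane * sample.feco2 - sample.fico2)
    return _clamp_negative(vco2, "vco2")


def derive_all(sample: GasSample, ve: float) -> GasDerived:
    """Bundle V̇o₂, V̇co₂, RER and the ventilatory equivalents.

    ``ve`` is the measured expired minute ventilation (L·min⁻¹).  When the
    computed V̇o₂ is zero (expired air identical to inspired air) the ratios
    RER and V̇_E/V̇o₂ are undefined and reported as None rather than
    infinity; likewise V̇_E/V̇co₂ for zero V̇co₂.
    """
    if not ve > 0:
        raise DomainError(f"ve must be > 0, got {ve}")
    vo2 = compute_vo2(sample)
    vco2 = compute_vco2(sample)
    rer = vco2 / vo2 if vo2 > 0 else None
    ve_vo2 = ve / vo2 if vo2 > 0 else None
    ve_vco2 = ve / vco2 if vco2 > 0 else None
    return GasDerived(vo2=vo2, vco2=vco2, rer=rer, ve_vo2=ve_vo2, ve_vco2=ve_vco2)
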