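"""Threshold result container shared by the f_R and V-slope detectors."""

from __future__ import annotations

from dataclasses import dataclass, field

from .regression import RegressionLine

__all__ = ["ThresholdResult", "DETERMINED", "UNDETERMINED"]

DETERMINED = "determined"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ThresholdResult:
    """A detected (or failed) exercise threshold.

    ``name`` is one of ``fRT1``/``fRT2`` (respiratory-frequency thresholds)
    or ``GET1``/``GET2`` (gas-exchange thresholds).  Coordinate fields are
    populated iff ``status == "determined"``; otherwise ``reason`` carries a
    machine-readable code such as ``no-provisional-T1``, ``slope-change``,
    ``insufficient-points`` or ``near-parallel``.

    ``lines`` holds the regression segments that produced the threshold and
    ``provenance`` the stage indices / intermediate values used, so a result
    can be audited without re-running the detector.
    """

    name: str
    status: str
    reason: str = ""
    fr: float | None = None  # breaths·min⁻¹
    hr: float | None = None  # beats·min⁻¹
    vo2: float | None = None  # L·min⁻¹
    po: float | None = None  # W
    hr_pct_max: float | None = None
    vo2_pct_peak: float | None = None
    lines: tuple[RegressionLine, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (DETERMINED, UNDETERMINED):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == DETERMINED and self.hr is None and self.vo2 is None:
            raise ValueError("a determined threshold needs at least one coordinate")

    @property
    def determined(self) -> bool:
        return self.status == DETERMINED

    def __str__(self) -> str:
        if not self.determined:
            return f"{self.name}: undetermined ({self.reason})"
        parts = []
        if self.fr is not None:
            parts.append(f"f_R = {self.fr:.1f} breaths/min")
        if self.hr is not None:
            parts.append(f"HR = {self.hr:.0f} beats/min")
        if self.vo2 is not None:
            parts.append(f"VO2 = {self.vo2:.3f} L/min")
        if self.po is not None:
            parts.append(f"PO = {self.po:.0f} W")
        return f"{self.name}: " + ", ".join(parts)
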