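"""Seedable synthetic incremental-test generator with known ground truth.

The generator emulates a 1-min, +20 W stage cycling protocol in middle-aged
men: heart rate rises linearly with power output; respiratory frequency is
piecewise-linear in the noiseless heart rate with two breakpoints (the
embedded f_R thresholds); V̇o₂ is linear in power output; V̇co₂ is
piecewise-linear in V̇o₂ with its slope break co-located with the first
f_R breakpoint (the embedded GET1); V̇_E is piecewise-linear in V̇co₂ with
its break co-located with the second f_R breakpoint (the embedded GET2).
I.i.d. Gaussian noise is added per channel per stage.

Default parameters are calibrated to a middle-aged cohort: HR_max ≈ 176
beats·min⁻¹, W_max 240 W (13-min test), V̇o₂peak ≈ 3.0 L·min⁻¹ (≈ 38
mL·kg⁻¹·min⁻¹ at 78 kg), breakpoints at ≈ 75% and ≈ 86% HR_max, RER rising
from ≈ 0.9 to ≈ 1.1.  The f_R slope structure keeps the pre-threshold
segment nearly flat relative to the f_R noise so that the 2·SD scan's
break-stage increments ((s₂−s₁)·ΔHR and (s₃−s₂)·ΔHR per stage) are at
least three noise SDs — the regime in which breakpoint detection is
physiologically meaningful.

Every series is returned together with a :class:`GroundTruth` carrying the
embedded threshold coordinates; accuracy is always judged against these,
never against published cohort values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import StageProtocol, StageRecord, StageSeries

__all__ = ["NoiseSD", "SubjectParams", "GroundTruth", "generate_series",
           "generate_cohort", "CohortRanges"]


@dataclass(frozen=True)
class NoiseSD:
    """Per-channel i.i.d. Gaussian noise SDs (per stage)."""

    hr: float = 2.0  # beats·min⁻¹
    fr: float = 1.0  # breaths·min⁻¹
    vo2: float = 0.03  # L·min⁻¹
    vco2: float = 0.015  # L·min⁻¹
    ve: float = 0.6  # L·min⁻¹

    def scaled(self, factor: float) -> "NoiseSD":
        return NoiseSD(*(factor * v for v in (self.hr, self.fr, self.vo2,
                                              self.vco2, self.ve)))


_ZERO_NOISE = NoiseSD(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters for one synthetic subject."""

    w_max: float = 240.0  # W, power of the last completed stage
    hr0: float = 80.0  # beats·min⁻¹ at unloaded cycling
    hr_slope: float = 0.40  # beats·min⁻¹ per W
    fr0: float = 14.0  # breaths·min⁻¹ at unloaded cycling
    fr_slopes: tuple[float, float, float] = (0.02, 0.45, 2.3)  # per beat·min⁻¹
    break_hr: tuple[float, float] = (132.0, 152.0)  # beats·min⁻¹
    vo2_0: float = 0.45  # L·min⁻¹ at unloaded cycling
    vo2_slope: float = 0.0105  # L·min⁻¹ per W
    vco2_slopes: tuple[float, float] = (0.95, 1.25)  # per L·min⁻¹ V̇o₂
    rer_0: float = 0.90  # V̇co₂/V̇o₂ at the first stage
    ve_slopes: tuple[float, float] = (23.0, 33.0)  # per L·min⁻¹ V̇co₂
    ve_0: float = 10.0  # L·min⁻¹ at the first stage
    noise_sd: NoiseSD = field(default_factory=NoiseSD)
    seed: int = 0
    increment_w: float = 20.0

    def __post_init__(self) -> None:
        s1, s2, s3 = self.fr_slopes
        if not (s1 < s2 < s3):
            raise ValueError(f"fr_slopes must be strictly increasing, got {self.fr_slopes}")
        b1, b2 = self.break_hr
        hr_max = self.hr0 + self.hr_slope * self.w_max
        if not (self.hr0 < b1 < b2 < hr_max):
            raise ValueError(
                f"break_hr {self.break_hr} must be strictly increasing inside "
                f"the HR range ({self.hr0}, {hr_max})")
        if self.vco2_slopes[1] <= self.vco2_slopes[0]:
            raise ValueError("vco2_slopes must increase at the break")
        if self.ve_slopes[1] <= self.ve_slopes[0]:
            raise ValueError("ve_slopes must increase at the break")


@dataclass(frozen=True)
class GroundTruth:
    """Embedded threshold coordinates of a generated series."""

    frt1_hr: float
    frt2_hr: float
    frt1_fr: float
    frt2_fr: float
    get1_vo2: float
    get2_vo2: float
    get2_vco2: float
    frt1_po: float
    frt2_po: float


def _piecewise_fr(params: SubjectParams, hr: np.ndarray) -> np.ndarray:
    s1, s2, s3 = params.fr_slopes
    b1, b2 = params.break_hr
    return (params.fr0
            + s1 * (np.minimum(hr, b1) - params.hr0)
            + s2 * np.clip(hr - b1, 0.0, b2 - b1)
            + s3 * np.maximum(hr - b2, 0.0))


def generate_series(params: SubjectParams,
                    subject_id: str = "synthetic"
                    ) -> tuple[StageSeries, GroundTruth]:
    """Generate one incremental test plus its embedded ground truth.

    Deterministic for a given ``params`` (the seed lives in the params);
    repeated calls return identical series.
    """
    rng = np.random.default_rng(params.seed)
    po = np.arange(0.0, params.w_max + params.increment_w / 2, params.increment_w)
    hr_clean = params.hr0 + params.hr_slope * po
    fr_clean = _piecewise_fr(params, hr_clean)
    vo2_clean = params.vo2_0 + params.vo2_slope * po

    b1, b2 = params.break_hr
    po_b1 = (b1 - params.hr0) / params.hr_slope
    po_b2 = (b2 - params.hr0) / params.hr_slope
    vo2_b1 = params.vo2_0 + params.vo2_slope * po_b1  # GET1 truth
    vo2_b2 = params.vo2_0 + params.vo2_slope * po_b2  # GET2 truth

    c1, c2 = params.vco2_slopes
    vco2_0 = params.rer_0 * params.vo2_0

    def vco2_of(v):
        v = np.asarray(v, dtype=float)
        return (vco2_0 + c1 * (np.minimum(v, vo2_b1) - params.vo2_0)
                + c2 * np.maximum(v - vo2_b1, 0.0))

    vco2_clean = vco2_of(vo2_clean)
    vco2_b2 = float(vco2_of(vo2_b2))  # GET2 truth on the V̇co₂ axis

    e1, e2 = params.ve_slopes
    ve_clean = (params.ve_0 + e1 * (np.minimum(vco2_clean, vco2_b2) - vco2_0)
                + e2 * np.maximum(vco2_clean - vco2_b2, 0.0))

    ns = params.noise_sd
    hr = hr_clean + rng.normal(0.0, ns.hr, po.size) if ns.hr else hr_clean.copy()
    fr = fr_clean + rng.normal(0.0, ns.fr, po.size) if ns.fr else fr_clean.copy()
    vo2 = vo2_clean + rng.normal(0.0, ns.vo2, po.size) if ns.vo2 else vo2_clean.copy()
    vco2 = vco2_clean + rng.normal(0.0, ns.vco2, po.size) if ns.vco2 else vco2_clean.copy()
    ve = ve_clean + rng.normal(0.0, ns.ve, po.size) if ns.ve else ve_clean.copy()
    # physical floors: channels must stay positive
    hr = np.maximum(hr, 30.0)
    fr = np.maximum(fr, 5.0)
    vo2 = np.maximum(vo2, 0.05)
    vco2 = np.maximum(vco2, 0.05)
    ve = np.maximum(ve, 2.0)

    stages = tuple(
        StageRecord(stage_index=i, po=float(po[i]), hr=float(hr[i]),
                    fr=float(fr[i]), vo2=float(vo2[i]), vco2=float(vco2[i]),
                    ve=float(ve[i]), vt=float(ve[i] / fr[i]))
        for i in range(po.size)
    )
    series = StageSeries(stages=stages,
                         protocol=StageProtocol(increment_w=params.increment_w),
                         subject_id=subject_id)
    truth = GroundTruth(
        frt1_hr=b1, frt2_hr=b2,
        frt1_fr=float(_piecewise_fr(params, np.array([b1]))[0]),
        frt2_fr=float(_piecewise_fr(params, np.array([b2]))[0]),
        get1_vo2=float(vo2_b1), get2_vo2=float(vo2_b2), get2_vco2=vco2_b2,
        frt1_po=float(po_b1), frt2_po=float(po_b2),
    )
    return series, truth


@dataclass(frozen=True)
class CohortRanges:
    """Population distributions for cohort sampling.

    Uniform ranges unless noted; breakpoints are drawn as fractions of the
    subject's noiseless HR_max and kept at least two stages apart.
    """

    w_max_choices: tuple[float, ...] = (200.0, 220.0, 240.0, 260.0)
    hr0: tuple[float, float] = (72.0, 88.0)
    hr_slope: tuple[float, float] = (0.36, 0.44)
    fr0: tuple[float, float] = (12.0, 16.0)
    fr_slope1: tuple[float, float] = (0.01, 0.05)
    fr_slope2: tuple[float, float] = (0.35, 0.55)
    fr_slope3: tuple[float, float] = (2.0, 2.6)
    break1_frac_hrmax: tuple[float, float] = (0.72, 0.78)
    break2_frac_hrmax: tuple[float, float] = (0.84, 0.90)
    vo2_0: tuple[float, float] = (0.40, 0.50)
    vo2_slope: tuple[float, float] = (0.0100, 0.0115)


def generate_cohort(n: int, ranges: CohortRanges | None = None,
                    seed: int = 0, noise_sd: NoiseSD | None = None
                    ) -> list[tuple[StageSeries, GroundTruth]]:
    """Draw ``n`` subjects from the population ranges (reproducible by seed)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    cohort = []
    for k in range(n):
        hr0 = rng.uniform(*ranges.hr0)
        hr_slope = rng.uniform(*ranges.hr_slope)
        w_max = float(rng.choice(ranges.w_max_choices))
        hr_max = hr0 + hr_slope * w_max
        b1 = rng.uniform(*ranges.break1_frac_hrmax) * hr_max
        b2 = rng.uniform(*ranges.break2_frac_hrmax) * hr_max
        min_gap = 2.0 * hr_slope * 20.0  # two stages of HR rise
        b2 = max(b2, b1 + min_gap)
        params = SubjectParams(
            w_max=w_max, hr0=hr0, hr_slope=hr_slope,
            fr0=rng.uniform(*ranges.fr0),
            fr_slopes=(rng.uniform(*ranges.fr_slope1),
                       rng.uniform(*ranges.fr_slope2),
                       rng.uniform(*ranges.fr_slope3)),
            break_hr=(b1, b2),
            vo2_0=rng.uniform(*ranges.vo2_0),
            vo2_slope=rng.uniform(*ranges.vo2_slope),
            noise_sd=noise_sd if noise_sd is not None else NoiseSD(),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(generate_series(params, subject_id=f"synthetic-{k:03d}"))
    return cohort


def noiseless(params: SubjectParams) -> SubjectParams:
    """Copy of ``params`` with all noise switched off."""
    return replace(params, noise_sd=_ZERO_NOISE)
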