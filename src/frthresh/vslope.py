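"""Gas-exchange threshold detection by the V-slope procedure.

GET2 (respiratory-compensation point) is found on the V̇_E vs V̇co₂
relation, GET1 (classic anaerobic threshold) afterwards on the V̇co₂ vs
V̇o₂ relation.  Both use the same two-segment machinery: every admissible
breakpoint splits the points into a lower and an upper least-squares line
(the boundary point belongs to both) and the chosen split maximises

    criterion = d(intersection, single line) / MSE(single line)

where the distance is perpendicular in raw axis units and the single line
is fitted to all points.  Acceptance rules: GET2 requires a slope increase
strictly greater than 15% of the lower slope; GET1 a slope increase
strictly greater than 0.1 (absolute).  Failing either leaves the threshold
``undetermined``.

Point-exclusion filters before the search:

* both relations drop the first two stages (0 and 20 W of a +20 W/min
  protocol);
* GET2 additionally drops trailing stages whose stage-to-stage V̇o₂
  increase is below 120 mL·min⁻¹ (scanning from the end, stopping at the
  first compliant increment);
* GET1 additionally drops leading points while the first
  ``min_segment``-point window has a V̇co₂-on-V̇o₂ slope below 0.6, and
  every point whose V̇o₂ exceeds the determined GET2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import StageSeries, summarize
from .exceptions import DegenerateFitError, NoIntersectionError
from .regression import RegressionLine, fit_line, intersect
from .thresholds import DETERMINED, UNDETERMINED, ThresholdResult

__all__ = [
    "TwoSegmentFit",
    "two_segment_best_fit",
    "filter_for_get2",
    "detect_get2",
    "detect_get1",
    "VSlopeModel",
    "VSlopeResults",
]

DEFAULT_MIN_SEGMENT = 3
#: Minimum stage-to-stage V̇o₂ increment (L·min⁻¹) for a trailing stage to
#: be kept in the GET2 filter.
MIN_VO2_INCREMENT = 0.120
#: GET2 acceptance: slope increase must strictly exceed this % of the lower slope.
GET2_SLOPE_CHANGE_PCT = 15.0
#: GET1 acceptance: slope increase must strictly exceed this (absolute).
GET1_SLOPE_CHANGE_ABS = 0.1
#: GET1 leading-segment exclusion: drop points while the initial window
#: slope is below this.
GET1_MIN_INITIAL_SLOPE = 0.6
#: Absolute tie tolerance on the strict acceptance inequalities, so that
#: data engineered exactly at a boundary resolve to "undetermined" rather
#: than flipping on the last floating-point bit.
_BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class TwoSegmentFit:
    """Best two-segment least-squares fit of a point set.

    ``breakpoint_index`` indexes the boundary point (shared by both limbs)
    within the fitted point arrays; ``break_x``/``break_y`` are the
    intersection of the two limbs, which need not coincide with a data
    point.  ``criterion`` is the distance-to-MSE ratio that was maximised.
    """

    breakpoint_index: int
    break_x: float
    break_y: float
    lower: RegressionLine
    upper: RegressionLine
    single: RegressionLine
    criterion: float

    @property
    def slope_change(self) -> float:
        """Upper-minus-lower slope (absolute units)."""
        return self.upper.slope - self.lower.slope

    @property
    def slope_change_pct(self) -> float:
        """Slope change as % of the lower slope (NaN for a non-positive lower slope)."""
        if self.lower.slope <= 0:
            return math.nan
        return 100.0 * self.slope_change / self.lower.slope


def _perp_distance(px: float, py: float, line: RegressionLine) -> float:
    return abs(line.slope * px - py + line.intercept) / math.hypot(line.slope, 1.0)


def two_segment_best_fit(x, y, min_segment: int = DEFAULT_MIN_SEGMENT) -> TwoSegmentFit:
    """Exhaustive search for the best two-segment split of ``(x, y)``.

    Every admissible boundary index ``b`` (both limbs keep at least
    ``min_segment`` points; the boundary point belongs to both) is scored by
    the distance-to-MSE criterion; ties keep the earliest split.  For
    exactly collinear data the criterion is 0 at every split.  Raises
    :class:`DegenerateFitError` when no admissible split yields two
    intersecting lines.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2 * min_segment:
        raise DegenerateFitError(
            f"need >= {2 * min_segment} points for two {min_segment}-point limbs, got {n}"
        )
    single = fit_line(x, y, segment="single")
    mse = single.sse / (n - 2)
    best: TwoSegmentFit | None = None
    for b in range(min_segment - 1, n - min_segment + 1):
        try:
            lower = fit_line(x[: b + 1], y[: b + 1], segment="lower")
            upper = fit_line(x[b:], y[b:], segment="upper")
        except DegenerateFitError:
            continue
        try:
            bx, by = intersect(lower, upper)
        except NoIntersectionError:
            # parallel limbs (e.g. exactly collinear data): the limbs agree
            # at the shared boundary point, which serves as the break
            bx, by = float(x[b]), float(lower.predict(x[b]))
        if not (x.min() <= bx <= x.max()):
            # near-parallel limbs extrapolate their crossing far outside the
            # measured range; such a split is not a physiological breakpoint
            continue
        dist = _perp_distance(bx, by, single)
        if mse > 0:
            crit = dist / mse
        else:
            crit = 0.0 if dist == 0 else math.inf
        if best is None or crit > best.criterion:
            best = TwoSegmentFit(breakpoint_index=b, break_x=float(bx),
                                 break_y=float(by), lower=lower, upper=upper,
                                 single=single, criterion=float(crit))
    if best is None:
        raise DegenerateFitError("no admissible split produced two intersecting lines")
    return best


def filter_for_get2(series: StageSeries) -> np.ndarray:
    """Positional stage indices surviving the GET2 exclusion filters.

    Drops the first two stages, then trailing stages whose stage-to-stage
    V̇o₂ increase is below 120 mL·min⁻¹; the trailing scan stops at the
    first compliant increment.
    """
    vo2 = series.vo2
    end = len(series) - 1
    while end >= 1 and (vo2[end] - vo2[end - 1]) < MIN_VO2_INCREMENT:
        end -= 1
    return np.arange(2, end + 1)


def _interpolate_stage_values(series: StageSeries, channel: str,
                              value: float) -> dict[str, float | None]:
    """Linear interpolation of fr/hr/po/vo2 at ``channel == value``.

    Uses the first pair of consecutive stages bracketing ``value``; outside
    the observed range, clamps to the nearest endpoint stage.
    """
    cx = series.column(channel)
    n = len(series)
    lo, t = None, 0.0
    for i in range(n - 1):
        a, b = cx[i], cx[i + 1]
        if (a <= value <= b) or (b <= value <= a):
            lo = i
            t = 0.0 if b == a else (value - a) / (b - a)
            break
    if lo is None:  # outside range: clamp
        lo, t = (0, 0.0) if value < cx[0] else (n - 2, 1.0)
    out: dict[str, float | None] = {}
    for name in ("fr", "hr", "po", "vo2"):
        col = series.column(name)
        a, b = col[lo], col[lo + 1]
        out[name] = float(a + t * (b - a)) if math.isfinite(a) and math.isfinite(b) else None
    return out


def _threshold_from_break(series: StageSeries, name: str, fit: TwoSegmentFit,
                          channel: str, note: str = "") -> ThresholdResult:
    coords = _interpolate_stage_values(series, channel, fit.break_x)
    summ = summarize(series)
    vo2 = coords["vo2"]
    if channel == "vo2":
        vo2 = fit.break_x  # GET1 is defined directly on the V̇o₂ axis
    return ThresholdResult(
        name=name, status=DETERMINED,
        fr=coords["fr"], hr=coords["hr"], vo2=vo2, po=coords["po"],
        hr_pct_max=(100.0 * coords["hr"] / summ.hr_max
                    if coords["hr"] is not None else None),
        vo2_pct_peak=(100.0 * vo2 / summ.vo2_peak
                      if vo2 is not None and summ.vo2_peak else None),
        lines=(fit.lower, fit.upper),
        provenance={"break_x": fit.break_x, "break_y": fit.break_y,
                    "channel": channel, "criterion": fit.criterion,
                    "note": note},
    )


def _undet(name: str, reason: str, **prov) -> ThresholdResult:
    return ThresholdResult(name=name, status=UNDETERMINED, reason=reason,
                           provenance=prov)


def detect_get2(series: StageSeries, min_segment: int = DEFAULT_MIN_SEGMENT
                ) -> tuple[ThresholdResult, TwoSegmentFit | None]:
    """Second gas-exchange threshold from the V̇_E vs V̇co₂ relation."""
    if not series.has_gas_exchange:
        return _undet("GET2", "missing-gas-channels"), None
    kept = filter_for_get2(series)
    if kept.size < 2 * min_segment:
        return _undet("GET2", "insufficient-points", n_points=int(kept.size)), None
    x = series.column("vco2")[kept]
    y = series.column("ve")[kept]
    try:
        fit = two_segment_best_fit(x, y, min_segment=min_segment)
    except DegenerateFitError as exc:
        return _undet("GET2", "degenerate-fit", detail=str(exc)), None
    if not fit.lower.slope > 0:
        return _undet("GET2", "nonpositive-lower-slope"), fit
    if not fit.slope_change_pct > GET2_SLOPE_CHANGE_PCT + _BOUNDARY_EPS:
        return _undet("GET2", "slope-change",
                      slope_change_pct=fit.slope_change_pct), fit
    return _threshold_from_break(series, "GET2", fit, channel="vco2"), fit


def detect_get1(series: StageSeries, get2: ThresholdResult | None = None,
                min_segment: int = DEFAULT_MIN_SEGMENT
                ) -> tuple[ThresholdResult, TwoSegmentFit | None]:
    """First gas-exchange threshold from the V̇co₂ vs V̇o₂ relation.

    When ``get2`` is determined its V̇o₂ caps the search domain (GET1 must
    not exceed GET2); when it is not, the search proceeds on the uncapped
    data and the result carries a ``no-get2-cap`` provenance note.
    """
    if not (series.has_channel("vo2") and series.has_channel("vco2")):
        return _undet("GET1", "missing-gas-channels"), None
    vo2 = series.vo2
    vco2 = series.column("vco2")
    kept = list(range(2, len(series)))
    note = ""
    if get2 is not None and get2.determined and get2.vo2 is not None:
        kept = [i for i in kept if vo2[i] <= get2.vo2]
    else:
        note = "no-get2-cap"
    # leading-segment exclusion: drop points while the initial window is shallow
    while len(kept) >= min_segment:
        w = kept[:min_segment]
        try:
            lead = fit_line(vo2[w], vco2[w])
        except DegenerateFitError:
            break
        if lead.slope < GET1_MIN_INITIAL_SLOPE:
            kept = kept[1:]
        else:
            break
    if len(kept) < 2 * min_segment:
        return _undet("GET1", "insufficient-points", n_points=len(kept),
                      note=note), None
    try:
        fit = two_segment_best_fit(vo2[kept], vco2[kept], min_segment=min_segment)
    except DegenerateFitError as exc:
        return _undet("GET1", "degenerate-fit", detail=str(exc), note=note), None
    if not fit.slope_change > GET1_SLOPE_CHANGE_ABS + _BOUNDARY_EPS:
        return _undet("GET1", "slope-change", slope_change=fit.slope_change,
                      note=note), fit
    return _threshold_from_break(series, "GET1", fit, channel="vo2", note=note), fit


class VSlopeModel:
    """V-slope gas-exchange threshold model for one incremental test.

    ``fit()`` runs GET2 first (V̇_E vs V̇co₂) and then GET1 (V̇co₂ vs V̇o₂,
    capped at the determined GET2) and returns a :class:`VSlopeResults`.
    """

    def __init__(self, series: StageSeries,
                 min_segment: int = DEFAULT_MIN_SEGMENT) -> None:
        self.series = series
        self.min_segment = int(min_segment)

    def fit(self) -> "VSlopeResults":
        get2, fit2 = detect_get2(self.series, self.min_segment)
        get1, fit1 = detect_get1(self.series, get2, self.min_segment)
        return VSlopeResults(model=self, get1=get1, get2=get2,
                             get1_fit=fit1, get2_fit=fit2)


@dataclass(frozen=True)
class VSlopeResults:
    """Fitted output of :class:`VSlopeModel`."""

    model: VSlopeModel
    get1: ThresholdResult
    get2: ThresholdResult
    get1_fit: TwoSegmentFit | None
    get2_fit: TwoSegmentFit | None

    @property
    def thresholds(self) -> tuple[ThresholdResult, ThresholdResult]:
        return self.get1, self.get2

    def summary(self) -> str:
        s = self.model.series
        out = [f"V-slope gas-exchange thresholds — subject {s.subject_id or '<unnamed>'}"]
        for t, fit in ((self.get2, self.get2_fit), (self.get1, self.get1_fit)):
            out.append(str(t))
            if fit is not None:
                out.append(
                    f"  lower slope {fit.lower.slope:.4f}, upper slope "
                    f"{fit.upper.slope:.4f}, criterion {fit.criterion:.3g}")
        return "\n".join(out)


def detect_vslope(series: StageSeries,
                  min_segment: int = DEFAULT_MIN_SEGMENT) -> VSlopeResults:
    """Convenience wrapper: build the model and fit in one call."""
    return VSlopeModel(series, min_segment=min_segment).fit()
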