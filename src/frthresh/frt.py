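"""Respiratory-frequency threshold (f_RT1 / f_RT2) detection.

The detector finds two breakpoints in the respiratory frequency (f_R) vs
heart rate (HR) relation of an incremental test, in two steps:

1. **Provisional scan.**  For each stage ``i`` the running baseline is the
   mean and sample SD of f_R over *all* previous stages (the 0 W stage
   included).  The first stage whose excess ``f_Ri − mean`` strictly
   exceeds twice the running SD — provided its power output strictly
   exceeds ``min_po`` (default 60 W, i.e. the first four stages of a
   +20 W/min protocol can feed the baseline but never trigger) — is the
   provisional first threshold; the first later stage triggering again is
   the provisional second threshold.  The baseline is never reset.

2. **Segmented regression.**  Three least-squares lines of f_R on HR are
   fitted: RL1 from the first stage through the provisional first
   threshold, RL2 between the two provisional thresholds, RL3 from the
   provisional second threshold to the last completed stage (boundary
   stages belong to both adjacent lines).  The final thresholds are the
   RL1×RL2 and RL2×RL3 intersections, reported in (HR, f_R) and mapped to
   V̇o₂ and power output through the V̇o₂-vs-HR and V̇o₂-vs-PO regressions
   over all completed stages when the V̇o₂ channel is available.

All failure modes (no trigger, too few stages per segment, near-parallel
lines) become ``undetermined`` statuses with reason codes, never
exceptions, so cohorts can be processed in batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import StageSeries, SeriesSummary, summarize
from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    NoIntersectionError,
)
from .regression import PARALLEL_TOL, RegressionLine, fit_line, intersect
from .thresholds import DETERMINED, UNDETERMINED, ThresholdResult

__all__ = [
    "running_baseline",
    "scan_provisional",
    "map_threshold",
    "RespiratoryThresholdModel",
    "RespiratoryThresholdResults",
    "detect_frt",
]

#: Default power-output gate: a stage can trigger only if its PO strictly
#: exceeds this (60 W excludes the first four stages of a +20 W protocol).
DEFAULT_MIN_PO = 60.0

#: Minimum number of stages for the full two-threshold procedure
#: (baseline, at least one eligible stage, and headroom for RL3).
MIN_STAGES_FOR_DETECTION = 6


def running_baseline(fr_values) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator) of the prior-f_R baseline.

    ``fr_values`` are the f_R of all stages before the stage under test,
    in order; at least two are required for the SD to exist.
    """
    v = np.asarray(fr_values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"baseline needs >= 2 values, got {v.size}")
    return float(v.mean()), float(v.std(ddof=1))


def scan_provisional(series: StageSeries, min_po: float = DEFAULT_MIN_PO
                     ) -> tuple[pd.DataFrame, int | None, int | None]:
    """Run the 2·SD provisional-threshold scan over a series.

    Returns ``(table, pt1, pt2)`` where ``table`` has one row per stage with
    columns ``stage, po_watts, hr_bpm, fr_brpm, avg_prev, sd_prev, excess,
    gate, eligible, triggered`` (baseline columns NaN where fewer than the
    required prior stages exist) and ``pt1``/``pt2`` are the positional
    indices of the provisional thresholds, or None when no stage triggers.
    Comparisons use unrounded values and strict inequalities throughout.
    """
    fr = series.fr
    po = series.po
    n = len(series)
    rows = []
    pt1: int | None = None
    pt2: int | None = None
    for i in range(n):
        avg = sd = excess = gate = math.nan
        eligible = bool(po[i] > min_po)
        triggered = False
        if i >= 1:
            avg = float(fr[:i].mean())
            excess = float(fr[i] - avg)
        if i >= 2:
            sd = float(fr[:i].std(ddof=1))
            gate = 2.0 * sd
            triggered = eligible and excess > gate
        if triggered:
            if pt1 is None:
                pt1 = i
            elif pt2 is None:
                pt2 = i
        rows.append({
            "stage": series.stages[i].stage_index,
            "po_watts": float(po[i]),
            "hr_bpm": float(series.hr[i]),
            "fr_brpm": float(fr[i]),
            "avg_prev": avg,
            "sd_prev": sd,
            "excess": excess,
            "gate": gate,
            "eligible": eligible,
            "triggered": triggered,
        })
    return pd.DataFrame(rows), pt1, pt2


def map_threshold(series: StageSeries, hr_t: float) -> tuple[float, float]:
    """Map a threshold HR to (V̇o₂, PO) via linear regressions.

    Fits V̇o₂ = a + b·HR and V̇o₂ = c + d·PO over all stages with a V̇o₂
    value (at least three required), evaluates the first at ``hr_t`` and
    inverts the second.  Raises :class:`InsufficientDataError` when the
    V̇o₂ channel is too sparse and :class:`DegenerateFitError` when the
    V̇o₂-on-PO slope is not positive.
    """
    vo2 = series.vo2
    ok = np.isfinite(vo2)
    if ok.sum() < 3:
        raise InsufficientDataError("need vo2 on >= 3 stages to map thresholds")
    hr_line = fit_line(series.hr[ok], vo2[ok], segment="vo2~hr")
    po_line = fit_line(series.po[ok], vo2[ok], segment="vo2~po")
    if po_line.slope <= 0:
        raise DegenerateFitError("vo2-on-po slope must be positive to invert")
    vo2_t = float(hr_line.predict(hr_t))
    po_t = (vo2_t - po_line.intercept) / po_line.slope
    return vo2_t, float(po_t)


def _undetermined(name: str, reason: str, **prov) -> ThresholdResult:
    return ThresholdResult(name=name, status=UNDETERMINED, reason=reason,
                           provenance=prov)


class RespiratoryThresholdModel:
    """Two-breakpoint model of f_R vs HR for one incremental test.

    Parameters
    ----------
    series : StageSeries
        Completed stages of the test; only PO, HR and f_R are required.
    min_po : float
        Eligibility gate in watts; a stage can be a provisional threshold
        only if its PO strictly exceeds this.  For protocols other than
        +20 W/min set it to the PO of the fourth loaded stage.
    parallel_tol : float
        Minimum slope difference for two segments to intersect.

    ``fit()`` returns a :class:`RespiratoryThresholdResults`.
    """

    def __init__(self, series: StageSeries, min_po: float = DEFAULT_MIN_PO,
                 parallel_tol: float = PARALLEL_TOL) -> None:
        self.series = series
        self.min_po = float(min_po)
        self.parallel_tol = float(parallel_tol)

    def fit(self) -> "RespiratoryThresholdResults":
        series = self.series
        scan, pt1, pt2 = scan_provisional(series, self.min_po)
        summary = summarize(series)
        lines: dict[str, RegressionLine] = {}

        if len(series) < MIN_STAGES_FOR_DETECTION:
            reason = "insufficient-stages"
            return RespiratoryThresholdResults(
                self, scan, pt1, pt2, lines,
                _undetermined("fRT1", reason), _undetermined("fRT2", reason),
                summary)
        if pt1 is None:
            return RespiratoryThresholdResults(
                self, scan, pt1, pt2, lines,
                _undetermined("fRT1", "no-provisional-T1"),
                _undetermined("fRT2", "no-provisional-T1"), summary)
        if pt2 is None:
            # RL2 needs both boundaries; without pT2 neither final
            # intersection is defined.
            return RespiratoryThresholdResults(
                self, scan, pt1, pt2, lines,
                _undetermined("fRT1", "no-provisional-T2", pt1=pt1),
                _undetermined("fRT2", "no-provisional-T2", pt1=pt1), summary)

        hr, fr = series.hr, series.fr
        windows = {"RL1": (0, pt1), "RL2": (pt1, pt2), "RL3": (pt2, len(series) - 1)}
        try:
            for seg, (lo, hi) in windows.items():
                lines[seg] = fit_line(hr[lo:hi + 1], fr[lo:hi + 1], segment=seg)
        except DegenerateFitError as exc:
            reason = f"degenerate-fit:{seg}"
            return RespiratoryThresholdResults(
                self, scan, pt1, pt2, lines,
                _undetermined("fRT1", reason, detail=str(exc)),
                _undetermined("fRT2", reason, detail=str(exc)), summary)

        frt1 = self._intersection_result("fRT1", lines["RL1"], lines["RL2"],
                                         pt1, pt2, summary)
        frt2 = self._intersection_result("fRT2", lines["RL2"], lines["RL3"],
                                         pt1, pt2, summary)
        if frt1.determined and frt2.determined and frt1.hr > frt2.hr:
            prov = {"pt1": pt1, "pt2": pt2, "hr1": frt1.hr, "hr2": frt2.hr}
            frt1 = _undetermined("fRT1", "inverted-thresholds", **prov)
            frt2 = _undetermined("fRT2", "inverted-thresholds", **prov)
        return RespiratoryThresholdResults(self, scan, pt1, pt2, lines,
                                           frt1, frt2, summary)

    def _intersection_result(self, name: str, a: RegressionLine,
                             b: RegressionLine, pt1: int, pt2: int,
                             summary: SeriesSummary) -> ThresholdResult:
        try:
            hr_t, fr_t = intersect(a, b, tol=self.parallel_tol)
        except NoIntersectionError as exc:
            return _undetermined(name, "near-parallel", detail=str(exc),
                                 pt1=pt1, pt2=pt2)
        vo2_t = po_t = vo2_pct = None
        mapping_note = ""
        try:
            vo2_t, po_t = map_threshold(self.series, hr_t)
            if summary.vo2_peak:
                vo2_pct = 100.0 * vo2_t / summary.vo2_peak
        except InsufficientDataError:
            mapping_note = "vo2-mapping-skipped:no-vo2-channel"
        except DegenerateFitError as exc:
            mapping_note = f"vo2-mapping-skipped:{exc}"
        return ThresholdResult(
            name=name, status=DETERMINED,
            fr=float(fr_t), hr=float(hr_t), vo2=vo2_t, po=po_t,
            hr_pct_max=100.0 * hr_t / summary.hr_max,
            vo2_pct_peak=vo2_pct,
            lines=(a, b),
            provenance={"pt1": pt1, "pt2": pt2, "note": mapping_note},
        )


@dataclass(frozen=True)
class RespiratoryThresholdResults:
    """Fitted output of :class:`RespiratoryThresholdModel`.

    Attributes
    ----------
    scan : pandas.DataFrame
        The provisional-scan table (one row per stage).
    pt1, pt2 : int or None
        Positional indices of the provisional thresholds.
    lines : dict
        The fitted segments keyed ``"RL1"``/``"RL2"``/``"RL3"`` (empty when
        detection stopped before the regression step).
    frt1, frt2 : ThresholdResult
        Final thresholds from the segment intersections.
    series_summary : SeriesSummary
        W_max / HR_max / peaks of the underlying test.
    """

    model: RespiratoryThresholdModel
    scan: pd.DataFrame
    pt1: int | None
    pt2: int | None
    lines: dict
    frt1: ThresholdResult
    frt2: ThresholdResult
    series_summary: SeriesSummary

    @property
    def thresholds(self) -> tuple[ThresholdResult, ThresholdResult]:
        return self.frt1, self.frt2

    def summary(self) -> str:
        """Human-readable report at the conventional display precisions
        (f_R one decimal, HR nearest integer, coefficients four decimals)."""
        s = self.model.series
        out = [f"Respiratory-frequency threshold detection — subject "
               f"{s.subject_id or '<unnamed>'}",
               f"stages: {len(s)}  W_max: {self.series_summary.w_max:.0f} W  "
               f"HR_max: {self.series_summary.hr_max:.0f} beats/min",
               ""]
        tbl = self.scan.copy()
        for col in ("fr_brpm", "avg_prev", "excess", "gate"):
            tbl[col] = tbl[col].round(1)
        tbl["sd_prev"] = tbl["sd_prev"].round(2)
        out.append(tbl.to_string(index=False))
        out.append("")
        for seg in ("RL1", "RL2", "RL3"):
            if seg in self.lines:
                ln = self.lines[seg]
                out.append(f"{seg}: f_R = {ln.slope:.4f}*HR + {ln.intercept:.4f}"
                           f"  (n = {ln.n})")
        out.append(str(self.frt1))
        out.append(str(self.frt2))
        return "\n".join(out)

    def plot(self, ax=None):
        """Plot f_R vs HR with the fitted segments and final thresholds.

        Requires matplotlib (optional dependency); returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.plot(s.hr, s.fr, "o", color="k", label="stages")
        for seg, ln in self.lines.items():
            lo, hi = {"RL1": (0, self.pt1), "RL2": (self.pt1, self.pt2),
                      "RL3": (self.pt2, len(s) - 1)}[seg]
            xs = np.linspace(s.hr[lo], s.hr[hi], 20)
            ax.plot(xs, ln.predict(xs), "--", label=seg)
        for t in self.thresholds:
            if t.determined:
                ax.axvline(t.hr, color="grey", lw=0.8)
                ax.annotate(t.name, (t.hr, t.fr))
        ax.set_xlabel("HR (beats/min)")
        ax.set_ylabel("f_R (breaths/min)")
        ax.legend()
        return ax


def detect_frt(series: StageSeries, min_po: float = DEFAULT_MIN_PO,
               parallel_tol: float = PARALLEL_TOL) -> RespiratoryThresholdResults:
    """Convenience wrapper: build the model and fit in one call."""
    return RespiratoryThresholdModel(series, min_po=min_po,
                                     parallel_tol=parallel_tol).fit()
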