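"""Ordinary least-squares line fitting and line intersection.

These are the numeric primitives shared by the respiratory-frequency
detector (three-segment regression of f_R on HR) and the V-slope detector
(two-segment regression on the gas-exchange axes).  All arithmetic is at
full double precision; rounding happens only in displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateFitError, NoIntersectionError

__all__ = ["RegressionLine", "fit_line", "intersect", "PARALLEL_TOL"]

#: Slopes closer than this are treated as parallel (no usable intersection).
PARALLEL_TOL = 1e-6


@dataclass(frozen=True)
class RegressionLine:
    """A fitted line ``y = slope * x + intercept`` with residual statistics.

    ``segment`` tags the line's role (``"RL1"``/``"RL2"``/``"RL3"`` for the
    f_R-on-HR segments, ``"lower"``/``"upper"``/``"single"`` for V-slope).
    """

    slope: float
    intercept: float
    n: int
    sse: float
    segment: str = ""

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    @property
    def mse(self) -> float:
        """Residual mean square, SSE/(n-2); NaN for a 2-point fit."""
        return self.sse / (self.n - 2) if self.n > 2 else float("nan")

    def __str__(self) -> str:  # matches the reporting precision convention
        return f"{self.segment or 'line'}: y = {self.slope:.4f}*x + {self.intercept:.4f} (n={self.n})"


def fit_line(x, y, segment: str = "") -> RegressionLine:
    """Least-squares fit of ``y`` on ``x``.

    Requires at least two points and non-identical predictor values;
    otherwise raises :class:`DegenerateFitError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateFitError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 2:
        raise DegenerateFitError(f"need >= 2 points to fit a line, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all predictor values identical; slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    return RegressionLine(slope=slope, intercept=intercept, n=n,
                          sse=float(np.sum(resid ** 2)), segment=segment)


def intersect(a: RegressionLine, b: RegressionLine,
              tol: float = PARALLEL_TOL) -> tuple[float, float]:
    """Intersection ``(x, y)`` of two fitted lines.

    Raises :class:`NoIntersectionError` when the slopes differ by less than
    ``tol`` (near-parallel lines give numerically meaningless crossings).
    """
    dslope = b.slope - a.slope
    if abs(dslope) < tol:
        raise NoIntersectionError(
            f"lines nearly parallel (|slope diff| = {abs(dslope):.2e} < {tol})"
        )
    x = (a.intercept - b.intercept) / dslope
    return x, a.slope * x + a.intercept
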