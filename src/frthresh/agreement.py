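"""Method-comparison statistics for paired threshold estimates.

Implements the validation toolkit used to compare two threshold detectors
on the same subjects: Bland–Altman bias and limits of agreement, Pearson
correlation with magnitude labels, regression standard error of the
estimate (SEE) with precision labels, Hedges' g effect size with magnitude
labels, and the paired t-test.

Classification bands (half-open, lower edge inclusive so every value maps
to exactly one class):

* correlation |r|: small < 0.3 ≤ moderate < 0.5 ≤ large < 0.7 ≤
  very large < 0.9 ≤ extremely large
* relative SEE (% of response mean): excellent < 2 ≤ good < 5 ≤
  acceptable < 10 ≤ moderate < 15 ≤ poor < 20 ≤ very poor
* |g|: small < 0.6 ≤ moderate < 1.2 ≤ large < 2.0 ≤ very large
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .regression import fit_line

__all__ = [
    "AgreementReport",
    "bland_altman",
    "pearson_with_class",
    "see_with_class",
    "hedges_g",
    "paired_t",
    "classify_r",
    "classify_see_pct",
    "classify_g",
    "agreement_report",
]

#: Limits-of-agreement multiplier (the ±1.96·SD convention of agreement plots).
LOA_MULTIPLIER = 1.96

_R_BANDS = ((0.3, "small"), (0.5, "moderate"), (0.7, "large"),
            (0.9, "very large"), (math.inf, "extremely large"))
_SEE_BANDS = ((2.0, "excellent"), (5.0, "good"), (10.0, "acceptable"),
              (15.0, "moderate"), (20.0, "poor"), (math.inf, "very poor"))
_G_BANDS = ((0.6, "small"), (1.2, "moderate"), (2.0, "large"),
            (math.inf, "very large"))


def _classify(value: float, bands) -> str:
    for edge, label in bands:
        if value < edge:
            return label
    raise AssertionError("unreachable")  # last edge is +inf


def classify_r(r: float) -> str:
    """Magnitude label for a correlation coefficient (|r| is used)."""
    return _classify(abs(r), _R_BANDS)


def classify_see_pct(see_pct: float) -> str:
    """Precision label for a relative SEE in percent."""
    if see_pct < 0:
        raise DomainError(f"see_pct must be >= 0, got {see_pct}")
    return _classify(see_pct, _SEE_BANDS)


def classify_g(g: float) -> str:
    """Magnitude label for a Hedges' g effect size (|g| is used)."""
    return _classify(abs(g), _G_BANDS)


def _paired_arrays(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D arrays")
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} pairs, got {x.size}")
    return x, y


def bland_altman(x, y) -> tuple[float, float, float, float]:
    """Bland–Altman agreement of two paired measurement sets.

    Returns ``(bias, loa_low, loa_high, proportional_bias_p)`` where the
    differences are ``x − y``, the limits of agreement are
    bias ± 1.96·SD(d) with the sample SD, and the proportional-bias p-value
    comes from regressing the differences on the pair means (NaN when the
    differences are constant, where the slope test is vacuous).
    """
    x, y = _paired_arrays(x, y)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mean = (x + y) / 2.0
    if sd == 0 or np.ptp(mean) == 0:
        p = math.nan
    else:
        p = float(stats.linregress(mean, d).pvalue)
    return bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd, p


def pearson_with_class(x, y) -> tuple[float, str]:
    """Pearson product-moment correlation with its magnitude label."""
    x, y = _paired_arrays(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, classify_r(r)


def see_with_class(x, y) -> tuple[float, float, str]:
    """Standard error of the estimate of the regression of ``y`` on ``x``.

    Returns ``(see, see_pct, label)`` with see = sqrt(SSE/(n−2)) and the
    relative SEE expressed as a percentage of the response mean.
    """
    x, y = _paired_arrays(x, y)
    line = fit_line(x, y)
    see = math.sqrt(line.sse / (line.n - 2))
    ym = float(np.mean(y))
    if ym == 0:
        raise DomainError("relative SEE undefined for zero response mean")
    see_pct = 100.0 * see / abs(ym)
    return see, see_pct, classify_see_pct(see_pct)


def hedges_g(a, b, paired: bool = False) -> tuple[float, str]:
    """Hedges' g standardised mean difference with its magnitude label.

    g = (mean(a) − mean(b)) / s_pooled × J with the pooled sample SD and
    the small-sample correction J = 1 − 3/(4·df − 1), df = n_a + n_b − 2.
    The ``paired`` flag is reporting metadata (the same pooled-SD formula is
    conventionally applied to paired comparisons); it does not alter the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 observations per sample")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df)
    if pooled == 0:
        raise DomainError("effect size undefined for zero pooled SD")
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = float((a.mean() - b.mean()) / pooled * correction)
    return g, classify_g(g)


def paired_t(a, b) -> float:
    """Two-sided p-value of Student's paired t-test of ``a`` vs ``b``.

    With zero-variance differences the statistic is degenerate: p = 1 for a
    zero mean difference and p = 0 otherwise.
    """
    a, b = _paired_arrays(a, b)
    d = a - b
    if d.std(ddof=1) == 0:
        return 1.0 if d.mean() == 0 else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass(frozen=True)
class AgreementReport:
    """Full method-comparison report for one variable across subjects."""

    variable: str
    n: int
    bias: float
    bias_pct_mean: float
    loa_low: float
    loa_high: float
    proportional_bias_p: float
    r: float
    r_class: str
    see: float
    see_pct: float
    see_class: str
    g: float
    g_class: str
    paired_p: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def __str__(self) -> str:
        return (
            f"{self.variable} (n = {self.n}): bias {self.bias:.3g} "
            f"[LOA {self.loa_low:.3g}, {self.loa_high:.3g}], "
            f"r = {self.r:.2f} ({self.r_class}), "
            f"SEE = {self.see:.3g} ({self.see_pct:.1f}%, {self.see_class}), "
            f"g = {self.g:.2f} ({self.g_class}), paired p = {self.paired_p:.3g}"
        )


def agreement_report(a, b, variable: str = "") -> AgreementReport:
    """Compare two paired estimate sets ``a`` (test method) vs ``b`` (reference).

    Bundles Bland–Altman, correlation, SEE (regressing the reference on the
    test method, i.e. how well ``a`` predicts ``b``), Hedges' g and the
    paired t-test into one :class:`AgreementReport`.
    """
    a, b = _paired_arrays(a, b)
    bias, lo, hi, pbp = bland_altman(a, b)
    r, r_class = pearson_with_class(a, b)
    see, see_pct, see_class = see_with_class(a, b)
    g, g_class = hedges_g(a, b, paired=True)
    grand_mean = float(np.mean((a + b) / 2.0))
    return AgreementReport(
        variable=variable, n=int(a.size),
        bias=bias,
        bias_pct_mean=(100.0 * bias / grand_mean if grand_mean != 0 else math.nan),
        loa_low=lo, loa_high=hi, proportional_bias_p=pbp,
        r=r, r_class=r_class,
        see=see, see_pct=see_pct, see_class=see_class,
        g=g, g_class=g_class,
        paired_p=paired_t(a, b),
    )
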