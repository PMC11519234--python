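"""Stage-wise incremental-test data model and I/O.

An incremental cycling test is represented as an ordered sequence of
completed stages.  Each :class:`StageRecord` holds the power output (PO, W),
the heart rate averaged over the stage end (HR, beats·min⁻¹) and the
respiratory frequency (f_R, breaths·min⁻¹); metabolic channels
(V̇o₂, V̇co₂, V̇_E, V_T, and raw inspired-side gas data) are optional and
simply enable more detectors when present.

CSV dialect: comma-separated, header row mandatory, decimal point, UTF-8.
Canonical column names::

    stage, po_watts, hr_bpm, fr_brpm,
    vo2_lmin, vco2_lmin, ve_lmin, vt_l, vi_lmin, feo2, feco2

``stage`` is the 0-based stage index with the unloaded (0 W) stage as
index 0.  Column order is irrelevant and unknown columns are ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    InputFormatError,
    InsufficientDataError,
    StageValidationError,
)

__all__ = [
    "StageRecord",
    "StageProtocol",
    "StageSeries",
    "SeriesSummary",
    "read_stage_csv",
    "write_stage_csv",
    "summarize",
    "percent_of_peak",
    "write_results_json",
    "read_results_json",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]

#: Minimum number of completed stages for any detection to make sense.
MIN_STAGES = 4

REQUIRED_COLUMNS = ("po_watts", "hr_bpm", "fr_brpm")
OPTIONAL_COLUMNS = ("vo2_lmin", "vco2_lmin", "ve_lmin", "vt_l", "vi_lmin", "feo2", "feco2")

_CSV_FIELD_MAP = {
    "po_watts": "po",
    "hr_bpm": "hr",
    "fr_brpm": "fr",
    "vo2_lmin": "vo2",
    "vco2_lmin": "vco2",
    "ve_lmin": "ve",
    "vt_l": "vt",
    "vi_lmin": "vi",
    "feo2": "feo2",
    "feco2": "feco2",
}


@dataclass(frozen=True)
class StageRecord:
    """One completed stage of an incremental test."""

    stage_index: int
    po: float  # power output, W
    hr: float  # heart rate, beats·min⁻¹
    fr: float  # respiratory frequency, breaths·min⁻¹
    vo2: float | None = None  # oxygen uptake, L·min⁻¹
    vco2: float | None = None  # carbon-dioxide output, L·min⁻¹
    ve: float | None = None  # minute ventilation, L·min⁻¹
    vt: float | None = None  # tidal volume, L
    vi: float | None = None  # inspired ventilation, L·min⁻¹
    feo2: float | None = None  # expired O2 fraction
    feco2: float | None = None  # expired CO2 fraction

    def __post_init__(self) -> None:
        if self.stage_index < 0:
            raise StageValidationError(f"stage_index must be >= 0, got {self.stage_index}")
        if self.po < 0:
            raise StageValidationError(f"po must be >= 0 W, got {self.po}")
        if not self.hr > 0:
            raise StageValidationError(f"hr must be > 0, got {self.hr}")
        if not self.fr > 0:
            raise StageValidationError(f"fr must be > 0, got {self.fr}")
        for name in ("vo2", "vco2", "ve", "vt", "vi", "feo2", "feco2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise StageValidationError(f"{name} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class StageProtocol:
    """Loading protocol of the test (default: +20 W every minute)."""

    increment_w: float = 20.0
    stage_duration_min: float = 1.0


@dataclass(frozen=True)
class StageSeries:
    """Ordered stages of one incremental test for one subject."""

    stages: tuple[StageRecord, ...]
    protocol: StageProtocol = field(default_factory=StageProtocol)
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if len(self.stages) < MIN_STAGES:
            raise InsufficientDataError(
                f"at least {MIN_STAGES} stages required, got {len(self.stages)}"
            )
        idx = [s.stage_index for s in self.stages]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StageValidationError("stage_index must be strictly increasing")
        po = [s.po for s in self.stages]
        if any(b < a for a, b in zip(po, po[1:])):
            raise StageValidationError("po must be non-decreasing across stages")

    # -- array accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    def column(self, name: str) -> np.ndarray:
        """Return one channel as a float array (NaN where missing)."""
        vals = [getattr(s, name) for s in self.stages]
        return np.array([math.nan if v is None else float(v) for v in vals])

    @property
    def po(self) -> np.ndarray:
        return self.column("po")

    @property
    def hr(self) -> np.ndarray:
        return self.column("hr")

    @property
    def fr(self) -> np.ndarray:
        return self.column("fr")

    @property
    def vo2(self) -> np.ndarray:
        return self.column("vo2")

    def has_channel(self, name: str) -> bool:
        return all(getattr(s, name) is not None for s in self.stages)

    @property
    def has_gas_exchange(self) -> bool:
        """True when the V-slope channels (vo2, vco2, ve) are complete."""
        return all(self.has_channel(c) for c in ("vo2", "vco2", "ve"))

    def to_frame(self) -> pd.DataFrame:
        """Stage table as a DataFrame with canonical CSV column names."""
        cols: dict[str, list] = {"stage": [s.stage_index for s in self.stages]}
        for col, attr in _CSV_FIELD_MAP.items():
            cols[col] = [getattr(s, attr) for s in self.stages]
        df = pd.DataFrame(cols)
        # drop optional columns that are entirely absent
        for col in OPTIONAL_COLUMNS:
            if df[col].isna().all():
                df = df.drop(columns=col)
        return df


@dataclass(frozen=True)
class SeriesSummary:
    """Whole-test summary: maximal workload and channel peaks."""

    w_max: float
    hr_max: float
    fr_max: float
    vo2_peak: float | None = None
    vo2_peak_rel: float | None = None  # mL·kg⁻¹·min⁻¹, needs body mass
    rer_max: float | None = None

    def to_dict(self) -> dict:
        return {
            "w_max": self.w_max,
            "hr_max": self.hr_max,
            "fr_max": self.fr_max,
            "vo2_peak": self.vo2_peak,
            "vo2_peak_rel": self.vo2_peak_rel,
            "rer_max": self.rer_max,
        }


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_stage_csv(path: str | Path, subject_id: str | None = None,
                   protocol: StageProtocol | None = None) -> StageSeries:
    """Read a stage-table CSV into a validated :class:`StageSeries`.

    The ``stage`` column is optional; when absent, rows are numbered 0..n-1
    in file order.  Raises :class:`InputFormatError` naming the first missing
    required column, :class:`StageValidationError` for non-monotone power and
    :class:`InsufficientDataError` for fewer than four rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise InputFormatError(f"required column '{col}' missing from {path}")
    if "stage" not in df.columns:
        df = df.assign(stage=np.arange(len(df)))
    df = df.sort_values("stage", kind="stable").reset_index(drop=True)

    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"stage_index": int(row["stage"])}
        for col, attr in _CSV_FIELD_MAP.items():
            if col in df.columns:
                v = row[col]
                if pd.isna(v):
                    v = None
                else:
                    v = float(v)
                    if not math.isfinite(v):
                        raise InputFormatError(f"non-finite value in column '{col}'")
                kwargs[attr] = v
        records.append(StageRecord(**kwargs))
    if len(records) < MIN_STAGES:
        raise InsufficientDataError(
            f"{path} has {len(records)} stages; at least {MIN_STAGES} required"
        )
    return StageSeries(
        stages=tuple(records),
        protocol=protocol or StageProtocol(),
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_stage_csv(series: StageSeries, path: str | Path) -> None:
    """Write a series back to the canonical CSV dialect (round-trip safe)."""
    series.to_frame().to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(series: StageSeries, body_mass_kg: float | None = None) -> SeriesSummary:
    """Whole-test summary.

    W_max is the power output of the last completed stage; HR_max, f_R max,
    V̇o₂peak and RER_max are channel maxima over stages.  The relative
    V̇o₂peak (mL·kg⁻¹·min⁻¹) is computed only when a body mass is given.
    """
    vo2_peak = rer_max = rel = None
    if series.has_channel("vo2"):
        vo2_peak = float(np.max(series.vo2))
        if body_mass_kg is not None:
            if not body_mass_kg > 0:
                raise DomainError(f"body_mass_kg must be > 0, got {body_mass_kg}")
            rel = 1000.0 * vo2_peak / body_mass_kg
        if series.has_channel("vco2"):
            rer_max = float(np.max(series.column("vco2") / series.vo2))
    return SeriesSummary(
        w_max=float(series.stages[-1].po),
        hr_max=float(np.max(series.hr)),
        fr_max=float(np.max(series.fr)),
        vo2_peak=vo2_peak,
        vo2_peak_rel=rel,
        rer_max=rer_max,
    )


def percent_of_peak(value: float, peak: float) -> float:
    """Express ``value`` as a percentage of ``peak`` (peak must be > 0)."""
    if not peak > 0:
        raise DomainError(f"peak must be > 0, got {peak}")
    return 100.0 * value / peak


# ---------------------------------------------------------------------------
# results JSON
# ---------------------------------------------------------------------------

def _threshold_to_dict(t) -> dict:
    d = {
        "name": t.name,
        "status": t.status,
        "reason": t.reason,
        "fr": t.fr,
        "hr": t.hr,
        "vo2": t.vo2,
        "po": t.po,
        "hr_pct_max": t.hr_pct_max,
        "vo2_pct_peak": t.vo2_pct_peak,
    }
    if t.lines:
        d["lines"] = [
            {"segment": ln.segment, "slope": ln.slope, "intercept": ln.intercept, "n": ln.n}
            for ln in t.lines
        ]
    return d


def write_results_json(path: str | Path, subject_id: str,
                       summary: SeriesSummary | None,
                       thresholds: Iterable) -> None:
    """Write detection output as schema-stable JSON.

    Schema: ``{subject_id, summary{...}, thresholds: [{name, status, reason,
    fr, hr, vo2, po, hr_pct_max, vo2_pct_peak, lines: [...]}]}``.
    ``read_results_json`` returns the same structure.
    """
    payload = {
        "subject_id": subject_id,
        "summary": summary.to_dict() if summary is not None else None,
        "thresholds": [_threshold_to_dict(t) for t in thresholds],
    }
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_json(path: str | Path) -> dict:
    with open(Path(path), encoding="utf-8") as fh:
        return json.load(fh)
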