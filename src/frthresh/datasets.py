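"""Bundled example data.

One fully worked incremental cycling test of a representative middle-aged
participant (1-min stages, +20 W increments, 0–260 W), with the per-stage
heart rate and respiratory frequency.  This series exercises the whole
respiratory-frequency detection pipeline end to end: the 2·SD scan flags
provisional thresholds at the 100 W and 160 W stages and the three-segment
regression places fRT1 at f_R ≈ 22.3 and fRT2 at f_R ≈ 29.3 breaths·min⁻¹.
"""

from __future__ import annotations

from .data import StageProtocol, StageRecord, StageSeries

__all__ = ["example_participant"]

# (po W, hr beats/min, fr breaths/min), one row per completed stage
_EXAMPLE_STAGES = (
    (0, 95, 12.7),
    (20, 93, 16.5),
    (40, 98, 14.7),
    (60, 102, 18.9),
    (80, 122, 17.5),
    (100, 135, 21.5),
    (120, 145, 19.3),
    (140, 154, 22.1),
    (160, 162, 31.0),
    (180, 170, 30.0),
    (200, 175, 35.7),
    (220, 180, 51.4),
    (240, 183, 64.5),
    (260, 184, 92.3),
)


def example_participant() -> StageSeries:
    """The bundled 14-stage example test (PO, HR, f_R only; no gas channels)."""
    stages = tuple(
        StageRecord(stage_index=i, po=float(po), hr=float(hr), fr=float(fr))
        for i, (po, hr, fr) in enumerate(_EXAMPLE_STAGES)
    )
    return StageSeries(stages=stages, protocol=StageProtocol(),
                       subject_id="example-participant")
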