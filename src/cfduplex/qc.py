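"""Sample-level quality control.

Full-scale defaults mirror assay requirements: at least 5 ng cfDNA input
(0.14 ng/uL at typical elution volumes), a minimum average raw base
coverage of 3,000x, and a minimum base quality of Q20.  Desk-scale runs
override the thresholds through the config.
"""
from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class QcThresholds:
    min_input_ng: float = 5.0
    min_mean_raw_depth: float = 3000.0
    min_qscore: int = 20


@dataclasses.dataclass
class QcVerdict:
    passed: bool
    reasons: list[str]


def sample_qc(input_mass_ng: float, raw_depth, thresholds: QcThresholds = QcThresholds()) -> QcVerdict:
    """Pass/fail a sample on input mass and mean raw coverage.

    ``raw_depth`` is the per-position raw read depth (any array-like).
    """
    reasons = []
    if input_mass_ng < thresholds.min_input_ng:
        reasons.append(
            f"insufficient input: {input_mass_ng:g} ng < "
            f"{thresholds.min_input_ng:g} ng")
    mean_depth = float(np.mean(np.asarray(raw_depth, dtype=float)))
    if mean_depth < thresholds.min_mean_raw_depth:
        reasons.append(
            f"insufficient coverage: mean {mean_depth:.0f}x < "
            f"{thresholds.min_mean_raw_depth:.0f}x")
    return QcVerdict(passed=not reasons, reasons=reasons)
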