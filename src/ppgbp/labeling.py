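"""Blood-pressure labels from the arterial pressure waveform.

The invasive ABP channel is the reference: per-beat systolic pressure is the
beat's ABP maximum (the raw waveform, no preprocessing), the subject's SBP
is the median over beats, and the category follows the JNC7 systolic bands
(normotension < 120 mmHg <= prehypertension < 140 mmHg <= hypertension;
stage 1 and stage 2 hypertension are merged).  Thresholds are configurable;
each band's lower bound belongs to the higher category.
"""

from __future__ import annotations

import numpy as np

NORMOTENSION = "normotension"
PREHYPERTENSION = "prehypertension"
HYPERTENSION = "hypertension"

CATEGORIES = (NORMOTENSION, PREHYPERTENSION, HYPERTENSION)

#: JNC7 systolic thresholds (mmHg): [prehypertension, hypertension)
DEFAULT_THRESHOLDS = (120.0, 140.0)


def label_bp_category(
    sbp: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Map a systolic pressure (mmHg) to its JNC7-style category."""
    if not 50.0 < sbp < 300.0:
        raise ValueError(f"sbp out of physiologic range (50, 300) mmHg: {sbp}")
    pre, hyp = thresholds
    if not pre < hyp:
        raise ValueError(f"thresholds must be increasing, got {thresholds}")
    if sbp < pre:
        return NORMOTENSION
    if sbp < hyp:
        return PREHYPERTENSION
    return HYPERTENSION


def extract_sbp(abp: np.ndarray, beats) -> float:
    """Subject SBP (mmHg): median over beats of the per-beat ABP maximum.

    ``beats`` is a list of :class:`~ppgbp.beats.BeatSegment`; their ``abp``
    slices come from the raw (unfiltered) pressure channel.
    """
    if len(beats) == 0:
        raise ValueError("cannot extract SBP from an empty beat list")
    per_beat = [float(np.max(b.abp)) for b in beats if len(b.abp) > 0]
    if not per_beat:
        raise ValueError("all beat ABP slices are empty")
    return float(np.median(per_beat))
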