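"""Pulse arrival time and PPG morphological feature families.

PAT is measured from the ECG R peak to the ``b_-2`` landmark — the PPG read
at the APG b-wave instant, i.e. the middle of the systolic upstroke — the
"PAT-middle" convention, which correlates best with blood pressure.

The morphological families are operators over one beat's fiducial set:
time spans t(q)−t(p); amplitudes from each level's baseline (PPG: the value
at the onset O; VPG/APG: the zero line); waveform areas (baseline-corrected
sample sums); power areas (squared-sample sums); ratios; slopes; and APG
composites such as (b−c−d)/a.  The ten-feature vector used for
classification is:

    f1  power_area(S→c) / power_area(O→O_next)
    f2  slope from b_-2 to d_-2 (PPG)
    f3  time span S→c_-2
    f4  amplitude ratio c_-2 / S (PPG)
    f5  time span S→d_-2
    f6  (b−c−d)/a (APG)
    f7  amplitude of d (APG)
    f8  c_-1 / w (VPG)
    f9  d/a (APG)
    f10 slope from S to c_-2 (PPG)

Beats missing a required landmark contribute a missing value (NaN), never a
zero; per-subject aggregation is the component-wise median over beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import BeatSegment, FiducialSet

FEATURE_NAMES = [f"f{i}" for i in range(1, 11)]
MISSING = float("nan")


@dataclass
class FeatureVector:
    """PAT plus the ten morphological features for a beat or a subject."""

    pat: float = MISSING
    values: dict[str, float] = field(default_factory=dict)
    extended: dict[str, float] = field(default_factory=dict)
    n_beats: int = 1

    def as_row(self) -> dict[str, float]:
        row = {"pat": self.pat}
        row.update({k: self.values.get(k, MISSING) for k in FEATURE_NAMES})
        row.update(self.extended)
        return row


def _baseline(fiducials: FiducialSet, level: str) -> float:
    if level == "ppg":
        if not fiducials.has("O"):
            return MISSING
        return fiducials.value("O")
    return 0.0


def amplitude(fiducials: FiducialSet, p: str) -> float:
    """Landmark amplitude relative to its level's beat baseline."""
    if not fiducials.has(p):
        return MISSING
    lm = fiducials.points[p]
    base = _baseline(fiducials, lm.level)
    return lm.value - base


def time_span(fiducials: FiducialSet, p: str, q: str) -> float:
    """t(q) − t(p); negative when q precedes p."""
    if not (fiducials.has(p) and fiducials.has(q)):
        return MISSING
    return fiducials.time(q) - fiducials.time(p)


def slope(fiducials: FiducialSet, p: str, q: str) -> float:
    """(amplitude(q) − amplitude(p)) / (t(q) − t(p)); symmetric in p, q."""
    dt = time_span(fiducials, p, q)
    if not np.isfinite(dt) or dt == 0.0:
        return MISSING
    return (amplitude(fiducials, q) - amplitude(fiducials, p)) / dt


def waveform_area(beat: BeatSegment, fiducials: FiducialSet, p: str, q: str) -> float:
    """Sum of baseline-corrected PPG samples over [t(p), t(q)], inclusive."""
    if not (fiducials.has(p) and fiducials.has(q)):
        return MISSING
    i_p, i_q = fiducials.points[p].index, fiducials.points[q].index
    if i_q < i_p:
        raise ValueError(f"reversed landmark order: t({q}) < t({p})")
    base = _baseline(fiducials, "ppg")
    return float(np.sum(beat.ppg[i_p : i_q + 1] - base))


def power_area(beat: BeatSegment, fiducials: FiducialSet, p: str, q: str) -> float:
    """Quadratic sum of normalized-PPG samples over [t(p), t(q)], inclusive."""
    if not (fiducials.has(p) and fiducials.has(q)):
        return MISSING
    i_p, i_q = fiducials.points[p].index, fiducials.points[q].index
    if i_q < i_p:
        raise ValueError(f"reversed landmark order: t({q}) < t({p})")
    return float(np.sum(beat.ppg[i_p : i_q + 1] ** 2))


_APG_FORMULAS = ("b/a", "c/a", "d/a", "e/a", "(b-c-d-e)/a", "(b-c-d)/a")


def apg_composite(fiducials: FiducialSet, formula: str) -> float:
    """Arithmetic composites of APG wave amplitudes, e.g. ``(b-c-d)/a``."""
    if formula not in _APG_FORMULAS:
        raise ValueError(f"unknown APG composite {formula!r}")
    needed = [ch for ch in formula if ch in "abcde"]
    vals = {ch: amplitude(fiducials, ch) for ch in needed}
    if any(not np.isfinite(v) for v in vals.values()):
        return MISSING
    a = vals["a"]
    if a == 0.0:
        return MISSING
    num = vals[needed[0]]
    for ch in needed[1:-1]:
        num -= vals[ch]
    return num / a


def compute_pat(r_time: float, fiducials: FiducialSet) -> float:
    """PAT (s): time from the R peak to b_-2 (missing if b undetected)."""
    if not fiducials.has("b"):
        return MISSING
    return fiducials.time("b_-2") - r_time


def compute_table1_features(beat: BeatSegment, fiducials: FiducialSet) -> FeatureVector:
    """The ten-feature morphology vector for one beat (NaN where missing)."""
    fv = FeatureVector()
    fv.pat = compute_pat(beat.r_time, fiducials)
    v = fv.values
    if (
        fiducials.has("S")
        and fiducials.has("c")
        and fiducials.has("O_next")
        and fiducials.points["c"].index >= fiducials.points["S"].index
        and fiducials.points["O_next"].index >= fiducials.points["O"].index
    ):
        denom = power_area(beat, fiducials, "O", "O_next")
        if np.isfinite(denom) and denom > 0:
            v["f1"] = power_area(beat, fiducials, "S", "c_-2") / denom
    v["f2"] = slope(fiducials, "b_-2", "d_-2")
    v["f3"] = time_span(fiducials, "S", "c_-2")
    amp_s = amplitude(fiducials, "S")
    amp_c2 = amplitude(fiducials, "c_-2")
    if np.isfinite(amp_s) and amp_s != 0 and np.isfinite(amp_c2):
        v["f4"] = amp_c2 / amp_s
    v["f5"] = time_span(fiducials, "S", "d_-2")
    v["f6"] = apg_composite(fiducials, "(b-c-d)/a")
    v["f7"] = amplitude(fiducials, "d")
    amp_w = amplitude(fiducials, "w")
    amp_c1 = amplitude(fiducials, "c_-1")
    if np.isfinite(amp_w) and amp_w != 0 and np.isfinite(amp_c1):
        v["f8"] = amp_c1 / amp_w
    v["f9"] = apg_composite(fiducials, "d/a")
    v["f10"] = slope(fiducials, "S", "c_-2")
    for name in FEATURE_NAMES:
        v.setdefault(name, MISSING)
    return fv


def aggregate_subject(per_beat: list[FeatureVector]) -> FeatureVector:
    """Component-wise median over beats (ignoring missing components)."""
    if not per_beat:
        raise ValueError("no valid beats to aggregate")
    agg = FeatureVector(n_beats=len(per_beat))
    pats = np.array([fv.pat for fv in per_beat], dtype=float)
    if np.any(np.isfinite(pats)):
        agg.pat = float(np.nanmedian(pats))
    for name in FEATURE_NAMES:
        col = np.array([fv.values.get(name, MISSING) for fv in per_beat], dtype=float)
        if np.any(np.isfinite(col)):
            agg.values[name] = float(np.nanmedian(col))
        else:
            agg.values[name] = MISSING
    return agg
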