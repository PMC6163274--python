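"""R-peak detection, beat segmentation, and PPG/VPG/APG fiducial points.

The ECG R wave anchors each cardiac cycle; every signal is then sliced into
per-beat segments and the canonical pulse landmarks are located in each:

* PPG level:  O (onset), S (systolic peak), N (dicrotic notch), D (diastolic
  peak), O_next (next onset);
* VPG level:  w, x, y, z (alternating extrema of the velocity waveform);
* APG level:  a, b, c, d, e (alternating extrema of the acceleration
  waveform).

A landmark ``q`` detected at one derivative level is *projected* down:
``q_-1`` is the signal one level below read at t(q), ``q_-2`` two levels
below (so ``b_-2`` is the PPG at the APG b-wave instant).  Projected points
share the source landmark's time exactly.

Landmark times are refined to sub-sample precision by fitting a parabola
through the three samples around each extremum; amplitudes are read at the
integer extremum sample, which keeps projection amplitudes exactly equal to
the lower-level signal's sample value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .preprocess import ProcessedSignals

# R-peak detector defaults: two-moving-average event detection on the
# squared, rectified ECG (windows in seconds)
RPEAK_W_PEAK = 0.097
RPEAK_W_BEAT = 0.611
RPEAK_BETA = 0.08
RPEAK_REFRACTORY = 0.2

#: search margin after the w wave for the APG a wave (s)
A_WINDOW_S = 0.040
#: how far past the VPG x wave the APG c/d/e search extends (s)
DIASTOLE_WINDOW_S = 0.35
#: minimum extremum prominence, as a fraction of the beat's pulse amplitude
#: (PPG) or peak APG magnitude, below which wiggles are ignored
PPG_PROMINENCE_FRAC = 0.02
APG_PROMINENCE_FRAC = 0.02

_LEVELS = {"O": "ppg", "S": "ppg", "N": "ppg", "D": "ppg", "O_next": "ppg"}
_LEVELS.update({k: "vpg" for k in ("w", "x", "y", "z")})
_LEVELS.update({k: "apg" for k in ("a", "b", "c", "d", "e")})


@dataclass
class BeatSegment:
    """One cardiac cycle: slices of all channels over [r_time, r_next)."""

    r_time: float  # s (sub-sample refined)
    r_next: float  # s
    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    abp: np.ndarray
    fs: float
    start_index: int  # sample index of the slice origin within the record


@dataclass(frozen=True)
class Landmark:
    time: float  # s, absolute within the record (sub-sample refined)
    index: int  # sample index within the beat slice
    value: float  # signal sample value at ``index``
    level: str  # 'ppg' | 'vpg' | 'apg'


@dataclass
class FiducialSet:
    """Named landmarks of one beat, plus their −1/−2 projections."""

    beat: BeatSegment
    points: dict[str, Landmark] = field(default_factory=dict)
    valid: bool = True

    def has(self, name: str) -> bool:
        return name in self.points

    def time(self, name: str) -> float:
        return self.points[name].time

    def value(self, name: str) -> float:
        return self.points[name].value


def _refine_time(x: np.ndarray, i: int, fs: float, t0: float) -> float:
    """Sub-sample extremum time by a parabola through (i-1, i, i+1)."""
    if 0 < i < len(x) - 1:
        denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
        if abs(denom) > 1e-12:
            delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return t0 + (i + delta) / fs
    return t0 + i / fs


def detect_r_peaks(
    ecg_f: np.ndarray,
    fs: float,
    w_peak: float = RPEAK_W_PEAK,
    w_beat: float = RPEAK_W_BEAT,
    beta: float = RPEAK_BETA,
    refractory: float = RPEAK_REFRACTORY,
) -> np.ndarray:
    """R-peak times (s) via two-moving-average event detection.

    The filtered ECG is rectified and squared; a short moving average
    (QRS-scale window) is compared against a long one (beat-scale window)
    plus a small offset proportional to the mean signal power.  Runs where
    the short average exceeds the threshold are candidate QRS blocks; each
    block contributes its maximum, and a refractory period keeps the larger
    of any two peaks closer than ``refractory`` seconds.
    """
    ecg_f = np.asarray(ecg_f, dtype=float)
    if ecg_f.size == 0:
        return np.array([])
    y = np.clip(ecg_f, 0.0, None) ** 2
    n1 = max(1, int(round(w_peak * fs)))
    n2 = max(n1 + 1, int(round(w_beat * fs)))
    ma_peak = np.convolve(y, np.ones(n1) / n1, mode="same")
    ma_beat = np.convolve(y, np.ones(n2) / n2, mode="same")
    thr = ma_beat + beta * float(np.mean(y))
    above = ma_peak > thr
    if not np.any(above):
        return np.array([])

    idx = np.flatnonzero(above)
    blocks: list[tuple[int, int]] = []
    b0 = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            blocks.append((b0, prev))
            b0 = i
        prev = i
    blocks.append((b0, prev))

    peaks: list[int] = []
    for lo, hi in blocks:
        if hi - lo + 1 < n1 // 2:  # too narrow to be a QRS complex
            continue
        peaks.append(lo + int(np.argmax(ecg_f[lo : hi + 1])))

    kept: list[int] = []
    min_gap = int(round(refractory * fs))
    for p in peaks:
        if kept and p - kept[-1] < min_gap:
            if ecg_f[p] > ecg_f[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.array([_refine_time(ecg_f, p, fs, 0.0) for p in kept])


def segment_beats(
    processed: ProcessedSignals,
    r_times: np.ndarray,
    abp: np.ndarray | None = None,
) -> list[BeatSegment]:
    """Slice all channels into consecutive R-to-R beats.

    Beats intersecting the filter-transient margins at either end of the
    record are excluded.  ``abp`` is the raw pressure channel (optional).
    """
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        return []
    if np.any(np.diff(r_times) <= 0):
        raise ValueError("non-monotone R sequence")
    fs = processed.fs
    n = len(processed.ppg_n)
    t_lo = processed.margin_s
    t_hi = n / fs - processed.margin_s
    if abp is None:
        abp = np.zeros(n)
    beats = []
    for r, r_next in zip(r_times[:-1], r_times[1:]):
        if r < t_lo or r_next > t_hi:
            continue
        i0 = int(round(r * fs))
        i1 = int(round(r_next * fs))
        if i1 <= i0 + 2:
            continue
        beats.append(
            BeatSegment(
                r_time=float(r),
                r_next=float(r_next),
                ppg=processed.ppg_n[i0:i1],
                vpg=processed.vpg[i0:i1],
                apg=processed.apg[i0:i1],
                abp=np.asarray(abp[i0:i1], dtype=float),
                fs=fs,
                start_index=i0,
            )
        )
    return beats


def _local_maxima(x: np.ndarray) -> np.ndarray:
    peaks, _ = find_peaks(x)
    return peaks


def _prominent_maxima(x: np.ndarray, prominence: float) -> np.ndarray:
    peaks, _ = find_peaks(x, prominence=max(prominence, 0.0) or None)
    return peaks


def locate_fiducials(
    beat: BeatSegment,
    a_window_s: float = A_WINDOW_S,
    diastole_window_s: float = DIASTOLE_WINDOW_S,
) -> FiducialSet:
    """Locate the landmark set of one beat; missing landmarks are omitted.

    Detection order: S (global PPG max) and O (PPG min before S) anchor the
    beat; VPG w/x/y/z and APG a..e follow from windowed extremum searches;
    the diastolic peak D is the first prominent PPG maximum after S and the
    notch N the valley minimum between S and D (both absent for single-lobe
    pulses).  A beat whose S or O cannot be found is marked invalid.
    """
    fs = beat.fs
    t0 = beat.start_index / fs
    ppg, vpg, apg = beat.ppg, beat.vpg, beat.apg
    fid = FiducialSet(beat=beat)
    n = len(ppg)
    if n < 5:
        fid.valid = False
        return fid

    def add(name: str, sig: np.ndarray, i: int) -> Landmark:
        lm = Landmark(
            time=_refine_time(sig, i, fs, t0),
            index=i,
            value=float(sig[i]),
            level=_LEVELS[name],
        )
        fid.points[name] = lm
        return lm

    i_s = int(np.argmax(ppg))
    if i_s == 0 or i_s >= n - 1:
        fid.valid = False
        return fid
    add("S", ppg, i_s)
    i_o = int(np.argmin(ppg[: i_s + 1]))
    add("O", ppg, i_o)

    # VPG landmarks
    if i_o < i_s:
        i_w = i_o + int(np.argmax(vpg[i_o : i_s + 1]))
        add("w", vpg, i_w)
    else:
        fid.valid = False
        return fid
    i_x = i_s + int(np.argmin(vpg[i_s:]))
    if i_x > i_s:
        add("x", vpg, i_x)
        vpg_max_after = _local_maxima(vpg[i_x:])
        if vpg_max_after.size:
            i_y = i_x + int(vpg_max_after[0])
            add("y", vpg, i_y)
            vpg_min_after = _local_maxima(-vpg[i_y:])
            if vpg_min_after.size:
                add("z", vpg, i_y + int(vpg_min_after[0]))

    # APG landmarks
    a_hi = min(n, i_w + int(round(a_window_s * fs)) + 1)
    i_a = i_o + int(np.argmax(apg[i_o:a_hi])) if a_hi > i_o else None
    if i_a is not None:
        add("a", apg, i_a)
        b_hi = (i_x + 1) if fid.has("x") else n
        if b_hi > i_a + 1:
            i_b = i_a + 1 + int(np.argmin(apg[i_a + 1 : b_hi]))
            add("b", apg, i_b)
            cde_hi = n
            if fid.has("x"):
                cde_hi = min(n, i_x + int(round(diastole_window_s * fs)))
            apg_prom = APG_PROMINENCE_FRAC * float(np.max(np.abs(apg)))
            seg = apg[i_b:cde_hi]
            maxima = _prominent_maxima(seg, apg_prom) + i_b
            if maxima.size:
                i_c = int(maxima[0])
                add("c", apg, i_c)
                minima = _prominent_maxima(-apg[i_c:cde_hi], apg_prom) + i_c
                if minima.size:
                    i_d = int(minima[0])
                    add("d", apg, i_d)
                    maxima2 = maxima[maxima > i_d]
                    if maxima2.size:
                        add("e", apg, int(maxima2[0]))

    # PPG diastolic peak and notch: D is the first prominent PPG maximum
    # after S (the dicrotic lobe), N the minimum of the valley before it
    pulse_amp = float(ppg[i_s] - ppg[i_o])
    if pulse_amp > 0:
        ppg_maxima = (
            _prominent_maxima(ppg[i_s + 1 :], PPG_PROMINENCE_FRAC * pulse_amp)
            + i_s
            + 1
        )
        if ppg_maxima.size:
            i_dia = int(ppg_maxima[0])
            i_nt = i_s + 1 + int(np.argmin(ppg[i_s + 1 : i_dia + 1]))
            add("N", ppg, i_nt)
            add("D", ppg, i_dia)

    # next-onset estimate: PPG minimum over the beat's tail
    tail_lo = max(i_s, fid.points["D"].index if fid.has("D") else 0)
    tail_lo = max(tail_lo, n // 2)
    if tail_lo < n:
        i_on = tail_lo + int(np.argmin(ppg[tail_lo:]))
        add("O_next", ppg, i_on)

    # projections: same time/index, read one or two derivative levels down
    proj = {}
    for q in ("w", "x", "y", "z"):
        if fid.has(q):
            lm = fid.points[q]
            proj[f"{q}_-1"] = Landmark(lm.time, lm.index, float(ppg[lm.index]), "ppg")
    for q in ("a", "b", "c", "d", "e"):
        if fid.has(q):
            lm = fid.points[q]
            proj[f"{q}_-1"] = Landmark(lm.time, lm.index, float(vpg[lm.index]), "vpg")
            proj[f"{q}_-2"] = Landmark(lm.time, lm.index, float(ppg[lm.index]), "ppg")
    fid.points.update(proj)
    return fid


def fiducials_to_rows(subject_id: str, beat_index: int, fid: FiducialSet) -> list[dict]:
    """Tidy rows (one per landmark) for CSV export."""
    return [
        {
            "subject": subject_id,
            "beat": beat_index,
            "landmark": name,
            "time_s": lm.time,
            "amplitude": lm.value,
            "level": lm.level,
        }
        for name, lm in sorted(fid.points.items())
    ]
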