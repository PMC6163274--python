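"""Synthetic ECG/ABP/PPG cohort generation with known ground truth.

Real ICU waveform databases publish no per-record ground truth for pulse
timing or PPG landmark positions, so this module builds records where every
quantity the downstream detectors try to recover is known by construction:
R-wave times, PPG pulse onsets, the true pulse arrival time (PAT), the true
systolic pressure, and the blood-pressure category.

One subject is a 120 s record sampled at 125 Hz with three synchronized
channels:

* ``ecg``   — a train of Gaussian R spikes (only R timing is consumed
  downstream, so full P-QRS-T realism is deliberately omitted);
* ``ppg``   — a DC level plus a pulse train whose onsets trail each R wave
  by ``pat_true`` seconds, with two-lobe (systolic + dicrotic) morphology;
* ``abp``   — the same pulse shape scaled to span [dbp, sbp] in mmHg, with
  each systolic peak aligned to a sample so the noise-free maximum equals
  ``sbp`` exactly.

The pulse template is a sum of compactly-supported squared-Hann (cos^4)
lobes.  Compact support makes the inter-beat baseline exactly zero (so ABP
extremes are exact) and the C² edges keep the acceleration-waveform (APG)
landmarks interior, smooth extrema whose positions are stable under
band-pass filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .labeling import label_bp_category

DEFAULT_FS = 125.0
#: coefficient of variation of beat-to-beat period jitter
BEAT_JITTER_CV = 0.02
#: PAT = PAT_INTERCEPT - PAT_SLOPE * SBP (+ noise); spans ~0.20-0.33 s
#: over SBP 95-180 mmHg, the negative-slope trend reported between BP and PAT.
PAT_INTERCEPT = 0.47
PAT_SLOPE = 0.0015
#: ECG R spike width (s); ~20 ms at half maximum
ECG_SPIKE_SIGMA = 0.010
#: raw PPG DC level and pulsatile amplitude (arbitrary units)
PPG_DC = 2.0
PPG_AC = 0.5


class SpecValidationError(ValueError):
    """A SubjectSpec / MorphologyParams field violates its invariant."""


@dataclass(frozen=True)
class MorphologyParams:
    """Shape parameters of one subject's pulse template.

    systolic_width is the onset-to-systolic-peak time; the dicrotic lobe
    peaks ``dicrotic_delay`` seconds after the systolic peak with relative
    amplitude ``dicrotic_amplitude``; ``notch_depth`` is the fraction of the
    inter-lobe valley carved out by the dicrotic notch.
    """

    systolic_width: float = 0.16
    dicrotic_amplitude: float = 0.45
    dicrotic_delay: float = 0.26
    notch_depth: float = 0.5
    baseline_wander_amp: float = 0.0
    baseline_wander_freq: float = 0.25

    def validate(self) -> None:
        for name in ("dicrotic_amplitude", "notch_depth", "baseline_wander_amp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecValidationError(f"{name} must be in [0, 1], got {v}")
        if self.systolic_width <= 0:
            raise SpecValidationError(
                f"systolic_width must be positive, got {self.systolic_width}"
            )
        if self.dicrotic_delay <= 0:
            raise SpecValidationError(
                f"dicrotic_delay must be positive, got {self.dicrotic_delay}"
            )
        if self.baseline_wander_freq < 0:
            raise SpecValidationError("baseline_wander_freq must be >= 0")

    @property
    def support_end(self) -> float:
        """Time after pulse onset at which the template returns to zero."""
        t_s = self.systolic_width
        w_d = 0.8 * self.dicrotic_delay
        return t_s + self.dicrotic_delay + w_d


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to deterministically generate one subject."""

    subject_id: str = "S000"
    heart_rate: float = 70.0  # beats/min
    sbp: float = 115.0  # mmHg
    dbp: float = 72.0  # mmHg
    pat_true: float = 0.25  # s
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    noise_sd: float = 0.0  # fraction of pulse amplitude
    seed: int = 0
    duration: float = 120.0  # s

    def validate(self) -> None:
        if not 40.0 <= self.heart_rate <= 180.0:
            raise SpecValidationError(
                f"heart_rate must be in [40, 180] bpm, got {self.heart_rate}"
            )
        if not self.dbp < self.sbp:
            raise SpecValidationError(
                f"dbp must be < sbp, got dbp={self.dbp}, sbp={self.sbp}"
            )
        if not 0.05 < self.pat_true < 0.6:
            raise SpecValidationError(
                f"pat_true must be in (0.05, 0.6) s, got {self.pat_true}"
            )
        if self.noise_sd < 0:
            raise SpecValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.duration <= 0:
            raise SpecValidationError(f"duration must be positive, got {self.duration}")
        self.morphology.validate()


@dataclass
class GroundTruth:
    r_times: np.ndarray  # s, strictly increasing
    ppg_onset_times: np.ndarray  # s, one per R wave
    pat_true: float  # s
    sbp_true: float  # mmHg
    category_true: str
    morphology: MorphologyParams | None = None


@dataclass
class WaveformRecord:
    """One subject's synchronized ECG/ABP/PPG traces."""

    subject_id: str
    fs: float
    ecg: np.ndarray
    abp: np.ndarray  # mmHg
    ppg: np.ndarray  # arbitrary units
    duration: float
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        n = int(round(self.fs * self.duration))
        for name in ("ecg", "abp", "ppg"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(
                    f"{name} has {len(arr)} samples, expected {n} "
                    f"(= round(fs x duration))"
                )


def _bump(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Squared-Hann bump: cos^4(pi (t-c) / (2 W)) on |t-c| <= W, else 0."""
    x = (t - center) / halfwidth
    out = np.zeros_like(t, dtype=float)
    m = np.abs(x) <= 1.0
    out[m] = np.cos(0.5 * np.pi * x[m]) ** 4
    return out


@lru_cache(maxsize=256)
def _template_shape_constants(morphology: MorphologyParams) -> tuple[float, float]:
    """(notch amplitude, peak value) of the un-normalized two-lobe template.

    The notch amplitude is bounded by the valley floor over the notch's own
    support, which guarantees the notched waveform never goes below zero;
    the peak is located on a dense grid and refined by a parabola so the
    normalized template's continuous maximum is 1 to high precision.
    """
    t_s = morphology.systolic_width
    d = morphology.dicrotic_delay
    w_d = 0.8 * d
    t_n = t_s + 0.5 * d
    w_n = 0.25 * d

    def base(t: np.ndarray) -> np.ndarray:
        return _bump(t, t_s, t_s) + morphology.dicrotic_amplitude * _bump(
            t, t_s + d, w_d
        )

    dt = 2e-4
    support = np.arange(max(0.0, t_n - w_n), t_n + w_n + dt, dt)
    valley_floor = float(np.min(base(support))) if support.size else 0.0
    notch_amp = morphology.notch_depth * min(
        valley_floor, morphology.dicrotic_amplitude
    )

    dense = np.arange(0.0, morphology.support_end + dt, dt)
    y = base(dense) - notch_amp * _bump(dense, t_n, w_n)
    i = int(np.argmax(y))
    peak = float(y[i])
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < -1e-12:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            peak = float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
    return notch_amp, peak


def pulse_waveform(
    morphology: MorphologyParams, beat_period: float, t: np.ndarray
) -> np.ndarray:
    """Evaluate one pulse at times ``t`` (seconds after pulse onset).

    The waveform is zero for t < 0 and for t past ``min(beat_period,
    support_end)``; its onset sample (t = 0) is a minimum of the beat and
    the systolic peak has amplitude exactly 1.
    """
    morphology.validate()
    if morphology.dicrotic_delay >= beat_period:
        raise ValueError(
            f"dicrotic_delay ({morphology.dicrotic_delay} s) must be smaller "
            f"than the beat period ({beat_period} s)"
        )
    t = np.asarray(t, dtype=float)
    t_s = morphology.systolic_width
    d = morphology.dicrotic_delay
    w_d = 0.8 * d
    t_n = t_s + 0.5 * d
    w_n = 0.25 * d

    # dicrotic notch: carve a fraction of the inter-lobe valley; its
    # amplitude is bounded so the waveform stays non-negative and vanishes
    # continuously as the dicrotic lobe does
    notch_amp, peak = _template_shape_constants(morphology)
    y = _bump(t, t_s, t_s)
    y += morphology.dicrotic_amplitude * _bump(t, t_s + d, w_d)
    y -= notch_amp * _bump(t, t_n, w_n)
    y /= peak
    y[(t < 0) | (t >= beat_period)] = 0.0
    return y


def pulse_template(
    morphology: MorphologyParams, beat_period: float, fs: float
) -> np.ndarray:
    """Sample one pulse over a whole beat: ``round(beat_period*fs)`` samples."""
    if beat_period <= morphology.systolic_width:
        raise ValueError(
            f"beat_period ({beat_period} s) must exceed systolic_width "
            f"({morphology.systolic_width} s)"
        )
    n = int(round(beat_period * fs))
    t = np.arange(n) / fs
    return pulse_waveform(morphology, beat_period, t)


def template_landmarks(
    morphology: MorphologyParams,
    beat_period: float,
    oversample_fs: float = 4000.0,
) -> dict[str, float]:
    """Ground-truth landmark times (s after pulse onset) of the clean template.

    Computed on a densely sampled noise-free template with plain extremum
    searches — independent of the 125 Hz detection pipeline.  Returns times
    for S, N, D (PPG), w, x (VPG) and a, b, c, d, e (APG); landmarks that do
    not exist for the given morphology are omitted.
    """
    n = int(round(beat_period * oversample_fs))
    t = np.arange(n) / oversample_fs
    ppg = pulse_waveform(morphology, beat_period, t)
    vpg = np.gradient(ppg, 1.0 / oversample_fs)
    apg = np.gradient(vpg, 1.0 / oversample_fs)

    from scipy.signal import find_peaks

    out: dict[str, float] = {}
    i_s = int(np.argmax(ppg))
    out["S"] = t[i_s]

    def prominent_max(x: np.ndarray, prom: float) -> np.ndarray:
        peaks, _ = find_peaks(x, prominence=prom)
        return peaks

    # VPG: w = max upstroke before S, x = min after S
    out["w"] = t[int(np.argmax(vpg[: i_s + 1]))]
    i_x = i_s + int(np.argmin(vpg[i_s:]))
    out["x"] = t[i_x]
    # APG: a = max before S, b = min between a and x
    i_a = int(np.argmax(apg[: i_s + 1]))
    out["a"] = t[i_a]
    i_b = i_a + int(np.argmin(apg[i_a : i_x + 1]))
    out["b"] = t[i_b]
    # c, d, e: alternating prominent extrema of APG after b (micro-wiggles
    # below 2% of the APG range are not landmarks)
    apg_prom = 0.02 * float(np.max(np.abs(apg)))
    maxima = [i for i in prominent_max(apg, apg_prom) if i > i_b]
    if maxima:
        i_c = maxima[0]
        out["c"] = t[i_c]
        minima = [i for i in prominent_max(-apg, apg_prom) if i > i_c]
        if minima:
            i_d = minima[0]
            out["d"] = t[i_d]
            maxima2 = [i for i in maxima if i > i_d]
            if maxima2:
                out["e"] = t[maxima2[0]]
    # PPG: D = first prominent max after S (dicrotic lobe), N = valley
    # minimum between S and D
    ppg_prom = 0.02 * float(ppg[i_s] - np.min(ppg[: i_s + 1]))
    maxs_ppg = [i for i in prominent_max(ppg, ppg_prom) if i > i_s]
    if maxs_ppg:
        i_dia = maxs_ppg[0]
        out["D"] = t[i_dia]
        out["N"] = t[i_s + int(np.argmin(ppg[i_s : i_dia + 1]))]
    return out


def generate_subject(spec: SubjectSpec, fs: float = DEFAULT_FS) -> WaveformRecord:
    """Generate one subject's record; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(fs * spec.duration))
    t = np.arange(n) / fs
    base_period = 60.0 / spec.heart_rate

    # beat onset (R) times with small period jitter; leave margins so the
    # first/last pulses are complete
    r_times: list[float] = []
    periods: list[float] = []
    t_r = 0.5
    while t_r < spec.duration - max(1.0, spec.morphology.support_end + spec.pat_true):
        r_times.append(t_r)
        period = base_period * (1.0 + BEAT_JITTER_CV * rng.standard_normal())
        period = max(period, 0.25)
        periods.append(period)
        t_r += period
    r_arr = np.asarray(r_times)

    ecg = np.zeros(n)
    for r in r_arr:
        lo = max(0, int((r - 5 * ECG_SPIKE_SIGMA) * fs))
        hi = min(n, int((r + 5 * ECG_SPIKE_SIGMA) * fs) + 1)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - r) / ECG_SPIKE_SIGMA) ** 2)

    ppg = np.zeros(n)
    abp = np.zeros(n)
    onset_times = r_arr + spec.pat_true
    t_s = spec.morphology.systolic_width
    for onset, period in zip(onset_times, periods):
        lo = int(np.ceil(onset * fs))
        hi = min(n, int(np.ceil((onset + period) * fs)))
        if lo >= hi:
            continue
        ppg[lo:hi] += pulse_waveform(spec.morphology, period, t[lo:hi] - onset)
        # ABP pulse: snap the systolic peak onto the sampling grid so the
        # noise-free maximum equals sbp exactly
        onset_abp = np.round((onset + t_s) * fs) / fs - t_s
        lo_a = int(np.ceil(onset_abp * fs))
        hi_a = min(n, int(np.ceil((onset_abp + period) * fs)))
        if lo_a >= hi_a:
            continue
        abp[lo_a:hi_a] += pulse_waveform(spec.morphology, period, t[lo_a:hi_a] - onset_abp)

    m = spec.morphology
    wander = m.baseline_wander_amp * np.sin(
        2 * np.pi * m.baseline_wander_freq * t + rng.uniform(0, 2 * np.pi)
    )
    ppg_out = PPG_DC + PPG_AC * (ppg + wander)
    abp_out = spec.dbp + (spec.sbp - spec.dbp) * abp
    if spec.noise_sd > 0:
        ecg = ecg + 0.1 * spec.noise_sd * rng.standard_normal(n)
        ppg_out = ppg_out + PPG_AC * spec.noise_sd * rng.standard_normal(n)
        abp_out = abp_out + 0.05 * spec.noise_sd * (
            spec.sbp - spec.dbp
        ) * rng.standard_normal(n)

    gt = GroundTruth(
        r_times=r_arr,
        ppg_onset_times=onset_times,
        pat_true=spec.pat_true,
        sbp_true=spec.sbp,
        category_true=label_bp_category(spec.sbp),
        morphology=spec.morphology,
    )
    return WaveformRecord(
        subject_id=spec.subject_id,
        fs=fs,
        ecg=ecg,
        abp=abp_out,
        ppg=ppg_out,
        duration=spec.duration,
        ground_truth=gt,
    )


# class index 0/1/2 = normotension / prehypertension / hypertension
_SBP_RANGES = {0: (96.0, 119.0), 1: (120.5, 139.5), 2: (140.5, 180.0)}
# per-class morphology shifts (scaled by class_effect): stiffer arteries ->
# wider systolic lobe, earlier and smaller dicrotic reflection, shallower notch
_CLASS_SHIFTS = {
    "systolic_width": 0.012,
    "dicrotic_amplitude": -0.10,
    "dicrotic_delay": -0.025,
    "notch_depth": -0.15,
}


def generate_cohort(
    n_normo: int,
    n_prehyp: int,
    n_hyp: int,
    class_effect: float = 1.0,
    seed: int = 0,
    *,
    duration: float = 120.0,
    noise_sd: float = 0.03,
    pat_slope: float = PAT_SLOPE,
    pat_intercept: float = PAT_INTERCEPT,
    pat_noise_sd: float = 0.03,
    morph_jitter: float = 0.06,
    baseline_wander_amp: float = 0.05,
    fs: float = DEFAULT_FS,
) -> list[WaveformRecord]:
    """Generate a labeled cohort of subjects.

    SBP is drawn uniformly within each category's band; ``pat_true``
    decreases linearly with SBP plus Gaussian noise (``pat_noise_sd``, the
    knob emulating imperfect ECG–PPG synchronization); morphology parameters
    shift monotonically across classes scaled by ``class_effect`` (0 means
    identical morphology distributions) with per-subject lognormal-ish
    jitter of relative scale ``morph_jitter``.
    """
    if class_effect < 0:
        raise SpecValidationError(f"class_effect must be >= 0, got {class_effect}")
    if min(n_normo, n_prehyp, n_hyp) < 0:
        raise SpecValidationError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[WaveformRecord] = []
    idx = 0
    for klass, count in ((0, n_normo), (1, n_prehyp), (2, n_hyp)):
        lo, hi = _SBP_RANGES[klass]
        for _ in range(count):
            sbp = rng.uniform(lo, hi)
            dbp = 0.62 * sbp + rng.normal(0.0, 2.0)
            hr = float(np.clip(rng.normal(70.0, 6.0), 55.0, 80.0))
            pat = pat_intercept - pat_slope * sbp + rng.normal(0.0, pat_noise_sd)
            pat = float(np.clip(pat, 0.08, 0.55))

            base = MorphologyParams(baseline_wander_amp=baseline_wander_amp)
            params = {}
            for name, shift in _CLASS_SHIFTS.items():
                v = getattr(base, name) + shift * klass * class_effect
                v *= 1.0 + morph_jitter * rng.standard_normal()
                params[name] = v
            morph = dataclasses.replace(
                base,
                systolic_width=float(np.clip(params["systolic_width"], 0.10, 0.24)),
                dicrotic_amplitude=float(
                    np.clip(params["dicrotic_amplitude"], 0.05, 0.9)
                ),
                dicrotic_delay=float(np.clip(params["dicrotic_delay"], 0.15, 0.38)),
                notch_depth=float(np.clip(params["notch_depth"], 0.0, 1.0)),
            )
            spec = SubjectSpec(
                subject_id=f"S{idx:03d}",
                heart_rate=hr,
                sbp=float(sbp),
                dbp=float(dbp),
                pat_true=pat,
                morphology=morph,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                duration=duration,
            )
            records.append(generate_subject(spec, fs=fs))
            idx += 1
    return records
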