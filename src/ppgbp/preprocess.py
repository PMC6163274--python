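"""Filtering, AC/DC normalization and derivative waveforms.

The PPG is band-passed with a 4th-order Chebyshev type II filter (0.5-10 Hz,
20 dB stopband) and the ECG with a 4th-order Butterworth (0.5-40 Hz).  Both
are applied forward-backward (zero phase): pulse arrival time is a timing
measurement and a one-pass IIR group delay would bias it.

The filtered PPG is normalized by its DC component (mean of the raw trace),
making the signal dimensionless and invariant to the sensor's overall gain.
Velocity (VPG) and acceleration (APG) waveforms are obtained by repeated
forward differencing scaled by the sampling rate, so they carry 1/s and
1/s^2 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

#: seconds trimmed from each end of a filtered record before beat extraction,
#: to keep IIR start-up transients out of the analysis
EDGE_MARGIN_S = 1.0


@dataclass
class ProcessedSignals:
    """Filtered/derived channels of one record (arrays keep input length)."""

    ecg_f: np.ndarray
    ppg_n: np.ndarray  # normalized (AC/DC), dimensionless
    vpg: np.ndarray  # 1/s
    apg: np.ndarray  # 1/s^2
    fs: float
    margin_s: float = EDGE_MARGIN_S


def _bandpass_sos(
    kind: str, low: float, high: float, order: int, fs: float, rs: float
) -> np.ndarray:
    if fs <= 2.0 * high:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {high} Hz band edge "
            f"(need fs > {2 * high} Hz)"
        )
    if kind == "cheby2":
        return sps.cheby2(order, rs, [low, high], btype="bandpass", fs=fs, output="sos")
    if kind == "butter":
        return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    raise ValueError(f"unknown filter kind {kind!r}")


def filter_ppg(
    ppg: np.ndarray,
    fs: float,
    low: float = 0.5,
    high: float = 10.0,
    order: int = 4,
    stopband_db: float = 20.0,
) -> np.ndarray:
    """Zero-phase 0.5-10 Hz Chebyshev-II band-pass of the raw PPG.

    The record mean is subtracted before filtering: a Chebyshev II stopband
    is equiripple rather than zero at DC, so removing the mean first gives
    exact DC rejection and avoids a large start-up transient.
    """
    sos = _bandpass_sos("cheby2", low, high, order, fs, stopband_db)
    x = np.asarray(ppg, dtype=float)
    return sps.sosfiltfilt(sos, x - x.mean())


def filter_ecg(
    ecg: np.ndarray,
    fs: float,
    low: float = 0.5,
    high: float = 40.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 0.5-40 Hz Butterworth band-pass of the raw ECG."""
    sos = _bandpass_sos("butter", low, high, order, fs, rs=0.0)
    return sps.sosfiltfilt(sos, np.asarray(ecg, dtype=float))


def normalize_ac_dc(ppg_filtered: np.ndarray, ppg_raw: np.ndarray) -> np.ndarray:
    """Divide the pulsatile (AC) part by the quasi-static (DC) part.

    AC is the band-passed signal; DC is the mean of the raw record.  Scaling
    the raw record by any positive constant leaves the output unchanged.
    """
    ppg_raw = np.asarray(ppg_raw, dtype=float)
    dc = float(np.mean(ppg_raw))
    rms = float(np.sqrt(np.mean(ppg_raw**2)))
    if abs(dc) < 1e-8 * max(1.0, rms):
        raise ValueError("degenerate DC: raw PPG mean is (near) zero")
    return np.asarray(ppg_filtered, dtype=float) / dc


def derive(x: np.ndarray, fs: float) -> np.ndarray:
    """Forward difference scaled by fs; the last sample is replicated.

    ``out[i] = (x[i+1] - x[i]) * fs`` estimates the derivative at the
    midpoint of each sampling interval.  Applying it twice to a normalized
    PPG yields the acceleration waveform (APG).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("derive requires at least 2 samples")
    out = np.empty_like(x)
    out[:-1] = np.diff(x) * fs
    out[-1] = out[-2]
    return out


def preprocess_record(record, **filter_kwargs) -> ProcessedSignals:
    """Run the full conditioning chain on a WaveformRecord.

    Keyword arguments are routed to the two filters by prefix, e.g.
    ``ppg_high=10.0`` or ``ecg_order=4``.
    """
    ppg_kw = {
        k[4:]: v for k, v in filter_kwargs.items() if k.startswith("ppg_")
    }
    ecg_kw = {
        k[4:]: v for k, v in filter_kwargs.items() if k.startswith("ecg_")
    }
    ecg_f = filter_ecg(record.ecg, record.fs, **ecg_kw)
    ppg_f = filter_ppg(record.ppg, record.fs, **ppg_kw)
    ppg_n = normalize_ac_dc(ppg_f, record.ppg)
    vpg = derive(ppg_n, record.fs)
    apg = derive(vpg, record.fs)
    return ProcessedSignals(ecg_f=ecg_f, ppg_n=ppg_n, vpg=vpg, apg=apg, fs=record.fs)
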