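"""Record and table I/O: three-column CSV, WFDB-style .hea/.dat, sidecars.

Two on-disk record forms are supported:

* **CSV**: columns ``ECG,ABP,PLETH`` with full-precision floats and a
  ``# fs=<Hz>`` comment line; lossless round trip.
* **WFDB-style**: a text ``.hea`` header plus a format-16 ``.dat`` file
  (interleaved little-endian int16 with per-channel gain/offset).  This is
  a minimal subset of the waveform-database conventions — enough to exchange
  ECG/ABP/PLETH records — and quantizes samples to the int16 gain step.

Ground truth (when present) travels in a JSON sidecar next to the record.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruth, MorphologyParams, WaveformRecord

#: channel-name aliases (upper-cased) for mapping arbitrary headers
CHANNEL_ALIASES = {
    "ecg": {"ECG", "I", "II", "III", "MLII", "V", "V5", "AVR", "EKG"},
    "abp": {"ABP", "ART", "BP", "AOBP"},
    "ppg": {"PLETH", "PPG", "PLETHYSMOGRAM"},
}


def _resolve_channels(names: list[str]) -> dict[str, int]:
    mapping = {}
    upper = [n.upper() for n in names]
    for target, aliases in CHANNEL_ALIASES.items():
        hits = [i for i, n in enumerate(upper) if n in aliases]
        if not hits:
            raise ValueError(
                f"channel {target.upper()} not found; candidates present: {names}"
            )
        mapping[target] = hits[0]
    return mapping


# ---------------------------------------------------------------- CSV form

def write_record_csv(record: WaveformRecord, path: str | Path) -> Path:
    """Write ECG/ABP/PLETH columns (lossless) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs!r} duration={record.duration!r} "
                 f"subject={record.subject_id}\n")
        fh.write("ECG,ABP,PLETH\n")
        for e, a, p in zip(record.ecg, record.abp, record.ppg):
            fh.write(f"{float(e)!r},{float(a)!r},{float(p)!r}\n")
    _write_sidecar(record, path.with_suffix(".json"))
    return path


def read_record_csv(path: str | Path) -> WaveformRecord:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline().strip()
    meta = dict(
        kv.split("=", 1) for kv in meta_line.lstrip("# ").split() if "=" in kv
    )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    idx = _resolve_channels(list(df.columns))
    fs = float(meta.get("fs", 125.0))
    duration = float(meta.get("duration", len(df) / fs))
    gt = _read_sidecar(path.with_suffix(".json"))
    return WaveformRecord(
        subject_id=meta.get("subject", path.stem),
        fs=fs,
        ecg=df.iloc[:, idx["ecg"]].to_numpy(),
        abp=df.iloc[:, idx["abp"]].to_numpy(),
        ppg=df.iloc[:, idx["ppg"]].to_numpy(),
        duration=duration,
        ground_truth=gt,
    )


# ------------------------------------------------------- WFDB-style records

_WFDB_FMT = 16  # little-endian int16, interleaved


def write_record_wfdb(record: WaveformRecord, path: str | Path) -> Path:
    """Write ``<path>.hea`` + ``<path>.dat`` (format 16) and a JSON sidecar."""
    path = Path(path)
    base = path.with_suffix("")
    name = base.name
    channels = [("ECG", record.ecg), ("ABP", record.abp), ("PLETH", record.ppg)]
    n = len(record.ecg)
    gains, offsets, quantized = [], [], []
    for _, sig in channels:
        lo, hi = float(np.min(sig)), float(np.max(sig))
        span = max(hi - lo, 1e-12)
        gain = 60000.0 / span  # counts per physical unit
        offset = lo
        q = np.round((sig - offset) * gain) - 30000.0
        gains.append(gain)
        offsets.append(offset)
        quantized.append(q.astype("<i2"))
    with open(base.with_suffix(".hea"), "w") as fh:
        fh.write(f"{name} {len(channels)} {record.fs:g} {n}\n")
        for (ch, _), gain, offset in zip(channels, gains, offsets):
            # store the physical offset in the description field comment
            fh.write(f"{name}.dat {_WFDB_FMT} {gain:.6f}({offset:.6f}) "
                     f"16 0 0 0 0 {ch}\n")
    np.stack(quantized, axis=1).tofile(base.with_suffix(".dat"))
    _write_sidecar(record, base.with_suffix(".json"))
    return base.with_suffix(".hea")


def read_record_wfdb(path: str | Path) -> WaveformRecord:
    path = Path(path).with_suffix(".hea")
    lines = path.read_text().strip().splitlines()
    name, n_sig, fs, n = lines[0].split()[:4]
    n_sig, fs, n = int(n_sig), float(fs), int(n)
    names, gains, offsets = [], [], []
    for line in lines[1 : 1 + n_sig]:
        parts = line.split()
        gain_str = parts[2]
        if "(" in gain_str:
            g, off = gain_str.rstrip(")").split("(")
        else:
            g, off = gain_str, "0"
        gains.append(float(g))
        offsets.append(float(off))
        names.append(parts[-1])
    data = np.fromfile(path.with_suffix(".dat"), dtype="<i2").reshape(n, n_sig)
    signals = [
        (data[:, i].astype(float) + 30000.0) / gains[i] + offsets[i]
        for i in range(n_sig)
    ]
    idx = _resolve_channels(names)
    gt = _read_sidecar(path.with_suffix(".json"))
    return WaveformRecord(
        subject_id=path.stem,
        fs=fs,
        ecg=signals[idx["ecg"]],
        abp=signals[idx["abp"]],
        ppg=signals[idx["ppg"]],
        duration=n / fs,
        ground_truth=gt,
    )


def read_record(path: str | Path) -> WaveformRecord:
    """Dispatch on extension: ``.csv`` or WFDB-style ``.hea``/``.dat``."""
    path = Path(path)
    if path.suffix == ".csv":
        return read_record_csv(path)
    if path.suffix in ("", ".hea", ".dat"):
        return read_record_wfdb(path)
    raise ValueError(f"unknown record format: {path.suffix!r}")


# ---------------------------------------------------------------- sidecars

def _write_sidecar(record: WaveformRecord, path: Path) -> None:
    if record.ground_truth is None:
        return
    gt = record.ground_truth
    payload = {
        "r_times": [float(x) for x in gt.r_times],
        "ppg_onset_times": [float(x) for x in gt.ppg_onset_times],
        "pat_true": gt.pat_true,
        "sbp_true": gt.sbp_true,
        "category_true": gt.category_true,
    }
    if gt.morphology is not None:
        payload["morphology"] = dataclasses.asdict(gt.morphology)
    path.write_text(json.dumps(payload))


def _read_sidecar(path: Path) -> GroundTruth | None:
    if not path.exists():
        return None
    d = json.loads(path.read_text())
    morph = d.get("morphology")
    return GroundTruth(
        r_times=np.asarray(d["r_times"]),
        ppg_onset_times=np.asarray(d["ppg_onset_times"]),
        pat_true=d["pat_true"],
        sbp_true=d["sbp_true"],
        category_true=d["category_true"],
        morphology=MorphologyParams(**morph) if morph else None,
    )
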