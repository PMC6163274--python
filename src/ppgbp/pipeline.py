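"""End-to-end orchestration: records -> per-subject labeled feature table."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import features as feat_mod
from . import labeling
from .preprocess import preprocess_record
from .synthetic import WaveformRecord

log = logging.getLogger("ppgbp")


def extract_subject(record: WaveformRecord, config=None) -> dict | None:
    """Process one record into a feature-table row (None if unusable).

    Runs filtering, R-peak detection, beat segmentation, fiducial location,
    per-beat features, median aggregation, and SBP labeling from the raw ABP.
    """
    cfg = config or {}
    processed = preprocess_record(record)
    r_times = beats_mod.detect_r_peaks(
        processed.ecg_f,
        processed.fs,
        **{k: cfg[k] for k in ("w_peak", "w_beat", "beta", "refractory") if k in cfg},
    )
    beats = beats_mod.segment_beats(processed, r_times, abp=record.abp)
    if not beats:
        log.warning("%s: no usable beats, subject excluded", record.subject_id)
        return None
    per_beat = []
    dropped = 0
    for beat in beats:
        fid = beats_mod.locate_fiducials(beat)
        if not fid.valid:
            dropped += 1
            continue
        per_beat.append(feat_mod.compute_table1_features(beat, fid))
    if not per_beat:
        log.warning("%s: all %d beats invalid, subject excluded",
                    record.subject_id, len(beats))
        return None
    agg = feat_mod.aggregate_subject(per_beat)
    sbp = labeling.extract_sbp(record.abp, beats)
    thresholds = cfg.get("thresholds", labeling.DEFAULT_THRESHOLDS)
    row = {"subject_id": record.subject_id}
    row.update(agg.as_row())
    row["n_beats"] = agg.n_beats
    row["sbp"] = sbp
    row["label"] = labeling.label_bp_category(sbp, thresholds)
    log.info(
        "%s: %d beats kept, %d dropped, SBP %.1f mmHg (%s)",
        record.subject_id, len(per_beat), dropped, sbp, row["label"],
    )
    return row


def build_feature_table(records: list[WaveformRecord], config=None) -> pd.DataFrame:
    """Feature table with one row per usable subject; deterministic columns."""
    rows = [r for rec in records if (r := extract_subject(rec, config)) is not None]
    cols = (
        ["subject_id", "label", "sbp", "pat"]
        + feat_mod.FEATURE_NAMES
        + ["n_beats"]
    )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


def subject_pat(record: WaveformRecord) -> float:
    """Median per-beat PAT (s) for one record (NaN if unmeasurable)."""
    row = extract_subject(record)
    return row["pat"] if row is not None else float("nan")
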