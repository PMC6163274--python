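"""Hand-construct FiducialSets over random signals, bypassing detection.

Used to test the feature formulas against independent arithmetic: landmark
indices are drawn in a valid order, amplitudes are read straight from random
signal arrays, and projections copy the source landmark's time/index with
the lower-level signal's value — exactly the projection convention.
"""

from __future__ import annotations

import numpy as np

from ppgbp.beats import BeatSegment, FiducialSet, Landmark


def build_random_fiducials(rng: np.random.Generator, fs: float = 125.0):
    """Returns (beat, fiducials, idx) with idx mapping landmark -> index."""
    n = 100
    ppg = rng.normal(0.0, 0.3, n)
    vpg = rng.normal(0.0, 2.0, n)
    apg = rng.normal(0.0, 20.0, n)
    # APG a amplitude must be nonzero for the composite ratios
    order = ["O", "w", "a", "b", "S", "c", "d", "e", "N", "D", "O_next"]
    picks = np.sort(rng.choice(np.arange(2, n - 2), size=len(order), replace=False))
    idx = dict(zip(order, (int(i) for i in picks)))
    if abs(apg[idx["a"]]) < 1.0:
        apg[idx["a"]] = 5.0

    beat = BeatSegment(
        r_time=0.0,
        r_next=n / fs,
        ppg=ppg,
        vpg=vpg,
        apg=apg,
        abp=np.zeros(n),
        fs=fs,
        start_index=0,
    )
    fid = FiducialSet(beat=beat)
    levels = {
        "O": "ppg", "S": "ppg", "N": "ppg", "D": "ppg", "O_next": "ppg",
        "w": "vpg", "x": "vpg", "y": "vpg", "z": "vpg",
        "a": "apg", "b": "apg", "c": "apg", "d": "apg", "e": "apg",
    }
    sig = {"ppg": ppg, "vpg": vpg, "apg": apg}
    for name, i in idx.items():
        level = levels[name]
        fid.points[name] = Landmark(i / fs, i, float(sig[level][i]), level)
    for q in ("w",):
        i = idx[q]
        fid.points[f"{q}_-1"] = Landmark(i / fs, i, float(ppg[i]), "ppg")
    for q in ("a", "b", "c", "d", "e"):
        i = idx[q]
        fid.points[f"{q}_-1"] = Landmark(i / fs, i, float(vpg[i]), "vpg")
        fid.points[f"{q}_-2"] = Landmark(i / fs, i, float(ppg[i]), "ppg")
    return beat, fid, idx
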