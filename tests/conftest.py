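"""Shared fixtures: synthetic records and cohort-level feature tables.

Cohort fixtures are session-scoped because feature extraction over a
121-subject, 120 s cohort is the expensive step; every test that needs the
faithful cohort shares one table.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppgbp.pipeline import build_feature_table
from ppgbp.synthetic import (
    MorphologyParams,
    SubjectSpec,
    generate_cohort,
    generate_subject,
)

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 120 s subject at 60 bpm with default morphology."""
    spec = SubjectSpec(
        subject_id="CLEAN", heart_rate=60.0, sbp=120.0, dbp=80.0,
        pat_true=0.25, noise_sd=0.0,
    )
    return spec, generate_subject(spec)


@pytest.fixture(scope="session")
def faithful_table():
    """Feature table of the full-size reference cohort: 46/41/34 subjects, 120 s
    records, moderate noise, PAT and morphology both informative."""
    records = generate_cohort(46, 41, 34, class_effect=1.0, seed=7)
    return build_feature_table(records)


@pytest.fixture(scope="session")
def null_table():
    """Feature table of a null cohort: identical morphology distributions and
    no PAT-SBP relation, so features carry no class information."""
    records = generate_cohort(
        20, 0, 20, class_effect=0.0, seed=11, pat_slope=0.0, pat_intercept=0.25
    )
    return build_feature_table(records)


def make_pat_cohort(noise_sd: float, seed0: int = 0, n: int = 30):
    """Subjects with evenly spaced SBP, PAT exactly linear in SBP, and
    identical morphology — the PAT-recovery study conditions."""
    sbps = np.linspace(96.0, 180.0, n)
    records = []
    for i, sbp in enumerate(sbps):
        spec = SubjectSpec(
            subject_id=f"P{i:02d}",
            heart_rate=70.0,
            sbp=float(sbp),
            dbp=float(0.62 * sbp),
            pat_true=float(0.47 - 0.0015 * sbp),
            morphology=MorphologyParams(),
            noise_sd=noise_sd,
            seed=seed0 + i,
        )
        records.append(generate_subject(spec))
    return records
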