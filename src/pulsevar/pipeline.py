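"""Glue between stages: recording -> profile, cohort -> feature table."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .harmonics import (
    MIN_BEAT_SAMPLES,
    HarmonicProfile,
    aggregate_profile,
    beat_harmonics,
)
from .preprocess import BeatSet, PulseRecording, beats_from_feet, detect_feet
from .simulate import Cohort


def extract_profile(
    rec: PulseRecording,
    beatset: Optional[BeatSet] = None,
    use_truth: bool = False,
    method: str = "tangent",
    cn_norm: str = "sum",
    circular: bool = True,
) -> HarmonicProfile:
    """Full per-recording extraction: segment, decompose, aggregate.

    ``use_truth=True`` segments at the simulator's exact foot indices
    instead of running detection (only available on simulated recordings).
    """
    if beatset is None:
        if use_truth:
            if rec.truth is None:
                raise InvalidParameterError("recording carries no ground truth")
            beatset = beats_from_feet(rec, rec.truth.foot_indices)
        else:
            beatset = detect_feet(rec, method=method)
    beats = [
        beat_harmonics(b, rec.fs)
        for b in beatset.beats
        if len(b) >= MIN_BEAT_SAMPLES
    ]
    return aggregate_profile(beats, cn_norm=cn_norm, circular=circular)


def cohort_feature_table(
    cohort: Cohort,
    use_truth: bool = False,
    method: str = "tangent",
    cn_norm: str = "sum",
    circular: bool = True,
) -> pd.DataFrame:
    """One row of the 42 per-recording indices for every recording."""
    rows = []
    for rec in cohort.recordings:
        profile = extract_profile(
            rec, use_truth=use_truth, method=method,
            cn_norm=cn_norm, circular=circular,
        )
        row = {
            "subject": rec.subject_id,
            "session": rec.session,
            "channel": rec.channel,
            "n_beats": profile.n_beats,
        }
        row.update(profile.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
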