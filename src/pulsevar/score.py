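"""Pulse-variability score and threshold classification.

The score for one subject is the product of six post/pre ratios of
variability indices (by default CV2 and P1_SD..P5_SD): a value near 1 means
the beat-to-beat variability was unchanged between sessions, values far
above 1 mean it inflated after the intervention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import DegenerateScoreError, InvalidBandError, InvalidParameterError
from .harmonics import HarmonicProfile

#: default selected indices (variability of harmonic 2 amplitude, phase SDs 1-5)
DEFAULT_FEATURES = ("CV2", "P1_SD", "P2_SD", "P3_SD", "P4_SD", "P5_SD")
DEFAULT_EPS = 1e-9

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class PairedFeatures:
    """Pre (M0) and post (M1) profiles for one subject."""

    subject_id: str
    pre: HarmonicProfile
    post: HarmonicProfile
    label: str = ""  # one of N / C / V ("" when unknown)

    @property
    def cv_flag(self) -> bool:
        return self.label in ("C", "V")


@dataclass(frozen=True)
class ScoreDecision:
    score: float
    decision: str
    thresholds: tuple[float, ...] = field(default=())


def pv_score(
    pf: PairedFeatures,
    features: Sequence[str] = DEFAULT_FEATURES,
    eps: float = DEFAULT_EPS,
) -> float:
    """Product over the selected indices of post-value / pre-value.

    Raises DegenerateScoreError (naming the index) when a pre-session
    denominator is at or below ``eps``.
    """
    score = 1.0
    for name in features:
        denom = pf.pre.value(name)
        if not denom > eps:
            raise DegenerateScoreError(name, denom, eps)
        score *= pf.post.value(name) / denom
    return score


def classify_single(score: float, threshold: float) -> str:
    """Positive iff score is strictly above the threshold."""
    if threshold <= 0:
        raise InvalidParameterError(f"threshold must be positive, got {threshold}")
    return POSITIVE if score > threshold else NEGATIVE


def classify_band(score: float, low: float, high: float) -> str:
    """Two-threshold rule with an ambiguity band.

    Strictly above ``high`` -> positive; strictly below ``low`` -> negative;
    anything inside [low, high] is excluded from classification.
    """
    if low <= 0 or low >= high:
        raise InvalidBandError(f"need 0 < low < high, got ({low}, {high})")
    if score > high:
        return POSITIVE
    if score < low:
        return NEGATIVE
    return EXCLUDED


def score_table(
    features: pd.DataFrame,
    labels: Optional[pd.DataFrame] = None,
    selected: Sequence[str] = DEFAULT_FEATURES,
    eps: float = DEFAULT_EPS,
    threshold: Optional[float] = None,
    band: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Score every subject in a per-recording feature table.

    ``features`` must have one row per (subject, session) with the index
    columns produced by the harmonics stage. Returns one row per subject
    with the score and, if a threshold or band is given, the decision.
    """
    required = {"subject", "session"}
    if not required.issubset(features.columns):
        raise InvalidParameterError(f"feature table needs columns {sorted(required)}")
    rows = []
    for subject, grp in features.groupby("subject", sort=True):
        sessions = dict(zip(grp["session"], grp.index))
        if "M0" not in sessions or "M1" not in sessions:
            continue
        pre = grp.loc[sessions["M0"]]
        post = grp.loc[sessions["M1"]]
        score = 1.0
        for name in selected:
            denom = float(pre[name])
            if not denom > eps:
                raise DegenerateScoreError(name, denom, eps)
            score *= float(post[name]) / denom
        row = {"subject": subject, "score": score}
        if band is not None:
            row["decision"] = classify_band(score, *band)
        elif threshold is not None:
            row["decision"] = classify_single(score, threshold)
        rows.append(row)
    out = pd.DataFrame(rows)
    if labels is not None and not out.empty:
        out = out.merge(labels, on="subject", how="left")
    return out
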