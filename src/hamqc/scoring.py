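"""Subjective visual DES scoring of destructured-ham defects.

Two trained observers each assign an integer severity score 0-3 per ham
(0 = no defect, 3 = severe structural disintegration with very pale
color).  The final DES value for a sample is the two-observer average, so
it lives on the half-integer grid {0, 0.5, ..., 3}, and averages are
grouped into four defect ranks::

    0, 0.5  -> DES0 (none)      1, 1.5 -> DES1 (mild)
    2, 2.5  -> DES2 (moderate)  3      -> DES3 (severe)

Training samples are scored jointly (both observers agree by construction)
and carry ``joint=True`` so downstream analyses can include or exclude
them.  Inter-observer agreement is summarized by the Pearson correlation
of the paired integer scores and by the RMSE of a second-degree
polynomial regression of one observer on the other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConsistencyError, DegenerateDataError, InputError

VALID_SCORES = (0, 1, 2, 3)
OBSERVERS = ("obs1", "obs2")


class DesRank(enum.IntEnum):
    """Four-rank defect grouping; the integer value is the rank index."""

    DES0 = 0
    DES1 = 1
    DES2 = 2
    DES3 = 3


@dataclass(frozen=True)
class ObserverScores:
    """A single observer's integer score for one sample."""

    sample_id: str
    observer_id: str
    score: int
    joint: bool = False

    def __post_init__(self):
        if self.observer_id not in OBSERVERS:
            raise InputError(
                f"observer_id must be one of {OBSERVERS}, got {self.observer_id!r}"
            )
        if self.score not in VALID_SCORES:
            raise InputError(f"score must be in {VALID_SCORES}, got {self.score!r}")


@dataclass(frozen=True)
class DesResult:
    """Final DES value for a sample: half-integer average and rank."""

    sample_id: str
    average_score: float
    rank: DesRank


_RANK_MAP = {
    0.0: DesRank.DES0,
    0.5: DesRank.DES0,
    1.0: DesRank.DES1,
    1.5: DesRank.DES1,
    2.0: DesRank.DES2,
    2.5: DesRank.DES2,
    3.0: DesRank.DES3,
}


def average_scores(s1, s2) -> float:
    """Two-observer average score; half-integer in [0, 3].

    Accepts two :class:`ObserverScores` (checked for matching sample and
    joint consistency) or two plain integers.
    """
    if isinstance(s1, ObserverScores) and isinstance(s2, ObserverScores):
        if s1.sample_id != s2.sample_id:
            raise InputError(
                f"sample_id mismatch: {s1.sample_id!r} vs {s2.sample_id!r}"
            )
        if (s1.joint or s2.joint) and s1.score != s2.score:
            raise ConsistencyError(
                f"joint-scored sample {s1.sample_id!r} has unequal scores "
                f"({s1.score}, {s2.score})"
            )
        a, b = s1.score, s2.score
    else:
        a, b = int(s1), int(s2)
        if a not in VALID_SCORES or b not in VALID_SCORES:
            raise InputError(f"scores must be in {VALID_SCORES}, got ({s1}, {s2})")
    return (a + b) / 2.0


def rank_from_average(avg: float) -> DesRank:
    """Map a half-integer average score to its DES rank."""
    try:
        return _RANK_MAP[float(avg)]
    except (KeyError, TypeError, ValueError):
        raise InputError(
            f"average score must be a multiple of 0.5 in [0, 3], got {avg!r}"
        ) from None


def des_result(s1: ObserverScores, s2: ObserverScores) -> DesResult:
    """Average two observers and attach the rank."""
    avg = average_scores(s1, s2)
    return DesResult(sample_id=s1.sample_id, average_score=avg, rank=rank_from_average(avg))


@dataclass(frozen=True)
class AgreementResult:
    """Inter-observer agreement: correlation and polynomial prediction error."""

    r: float
    p_value: float
    prediction_error: float  # RMSE of degree-2 polynomial fit of y on x
    mae: float
    n: int
    coefficients: tuple  # (c0, c1, c2) of the quadratic fit


def observer_agreement(scores1, scores2) -> AgreementResult:
    """Agreement between two observers' integer score series.

    ``r`` is the Pearson correlation; ``prediction_error`` is the RMSE of
    the ordinary least-squares degree-2 polynomial regression of
    ``scores2`` on ``scores1`` (how well observer 1 predicts observer 2).
    The regression direction matters for the error but not for ``r``.
    """
    x = np.asarray(scores1, dtype=float)
    y = np.asarray(scores2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("score lists must be 1-D and of equal length")
    if len(x) < 4:
        raise InputError(f"need at least 4 paired scores, got {len(x)}")
    for name, v in (("scores1", x), ("scores2", y)):
        if not np.all(np.isin(v, VALID_SCORES)):
            raise InputError(f"{name} must contain only integers in {VALID_SCORES}")
        if np.std(v) == 0:
            raise DegenerateDataError(f"{name} has zero variance")
    r, p = sps.pearsonr(x, y)
    # lstsq instead of polyfit: tolerates rank deficiency (few distinct x) silently
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return AgreementResult(
        r=float(r),
        p_value=float(p),
        prediction_error=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        n=len(x),
        coefficients=tuple(float(c) for c in coef),
    )
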