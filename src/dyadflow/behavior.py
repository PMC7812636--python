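"""Behavioural performance scoring and questionnaire aggregation.

The bridge-building task gives 240 s to place 15 pieces; performance is

    score = 1 - (t_el / 240) * ((w + m) / 15)

with elapsed time t_el, wrongly placed pieces w and missing pieces m, so a
finished, correct bridge scores 1 regardless of speed and an untouched one
scores down to 0 as the clock runs out.  Cooperative trials are pooled and
labelled effective (>= third quartile) or ineffective (<= first quartile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialOutcome",
    "QuestionnaireResponse",
    "compute_score",
    "label_effectiveness",
    "nasa_tlx_weighted",
    "team_workload_score",
    "cooperation_score",
]

TOTAL_TIME = 240.0
TOTAL_PIECES = 15


@dataclass(frozen=True)
class TrialOutcome:
    """One condition's behavioural record for a subject or dyad."""

    t_el: float  # elapsed seconds, (0, 240]
    w: int  # wrongly placed pieces
    m: int  # missing pieces

    def __post_init__(self) -> None:
        if not 0 < self.t_el <= TOTAL_TIME:
            raise ValueError("elapsed time must be in (0, 240] s")
        if not (0 <= self.w <= TOTAL_PIECES and 0 <= self.m <= TOTAL_PIECES):
            raise ValueError("piece counts out of range")
        if self.w + self.m > TOTAL_PIECES:
            raise ValueError("wrong + missing cannot exceed 15 pieces")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """NASA-TLX, team-workload and cooperation questionnaire entries."""

    nasa_ratings: tuple[float, ...] = ()
    nasa_pair_choices: tuple[int, ...] = ()  # per-dimension win counts
    team_subscales: tuple[float, ...] = ()
    cooperation_items: tuple[float, ...] = ()


def compute_score(outcome: TrialOutcome) -> float:
    """Performance score in [0, 1] (higher is better)."""
    return 1.0 - (outcome.t_el / TOTAL_TIME) * ((outcome.w + outcome.m) / TOTAL_PIECES)


def label_effectiveness(scores) -> tuple[list[str], tuple[float, float]]:
    """Split pooled cooperative scores at the first/third quartiles.

    Quartiles use linear interpolation between order statistics; boundary
    scores fall into the extreme class.  Returns (labels, (q1, q3)).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 8:
        raise ValueError("need at least 8 pooled scores to define quartiles")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    if q1 == q3:
        warnings.warn("degenerate score distribution; all trials labelled neutral", stacklevel=2)
        return ["neutral"] * scores.size, (float(q1), float(q3))
    labels = np.where(scores <= q1, "ineffective", np.where(scores >= q3, "effective", "neutral"))
    return labels.tolist(), (float(q1), float(q3))


def nasa_tlx_weighted(response: QuestionnaireResponse) -> float:
    """Weighted NASA-TLX: sum(rating_i * weight_i) / 15, with weight_i the
    number of times dimension i won its pairwise comparisons."""
    ratings = np.asarray(response.nasa_ratings, dtype=float)
    weights = np.asarray(response.nasa_pair_choices, dtype=float)
    if ratings.size != 6 or weights.size != 6:
        raise ValueError("NASA-TLX needs six ratings and six weights")
    if np.any((ratings < 0) | (ratings > 100)):
        raise ValueError("ratings must be on the 0-100 scale")
    if weights.sum() != 15:
        raise ValueError("pairwise-comparison weights must sum to 15")
    return float(np.dot(ratings, weights) / 15.0)


def _mean_of_six(items, what: str) -> float:
    values = np.asarray(items, dtype=float)
    if values.size != 6:
        raise ValueError(f"{what} needs exactly six items")
    return float(values.mean())


def team_workload_score(response: QuestionnaireResponse) -> float:
    """Unweighted mean of the six team-workload subscales."""
    return _mean_of_six(response.team_subscales, "team workload")


def cooperation_score(response: QuestionnaireResponse) -> float:
    """Unweighted mean of the six cooperation items."""
    return _mean_of_six(response.cooperation_items, "cooperation assessment")
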