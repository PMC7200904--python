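"""Confidence-interval accuracy rule for equation predictions.

A prediction is judged *accurate* if it falls inside the 95% confidence
interval of the in vivo observed mean: mean +/- margin, with the margin
the Student-t half-width t(0.975, n-1) x sd / sqrt(n) of the per-pig
estimates.  The margin may also be supplied directly when only published
bounds are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .prediction import PredictionOutcome


@dataclass(frozen=True)
class AccuracyVerdict:
    """Verdict on one prediction against the observed in vivo mean."""

    ingredient: str
    equation_id: str
    observed_mean: float
    margin: float
    predicted: float
    within: bool
    signed_error: float  # predicted - observed_mean, kcal

    @property
    def lower(self) -> float:
        return self.observed_mean - self.margin

    @property
    def upper(self) -> float:
        return self.observed_mean + self.margin


def margin_of_error(values: Sequence[float], level: float = 0.95) -> float:
    """Half-width of the Student-t confidence interval of the mean.

    ``t(1 - (1-level)/2, n-1) x sd / sqrt(n)`` over the per-pig
    estimates; requires at least two values.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"margin of error needs n >= 2 values, got {n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    sd = values.std(ddof=1)
    t = stats.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1)
    return float(t * sd / math.sqrt(n))


def assess(
    observed_mean: float,
    margin: float,
    predictions: Sequence[PredictionOutcome],
) -> list[AccuracyVerdict]:
    """Judge each prediction against mean +/- margin.

    Returns verdicts ranked by absolute signed error (best prediction
    first); ranking does not affect the verdicts themselves.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    verdicts = []
    for p in predictions:
        err = p.predicted - observed_mean
        verdicts.append(
            AccuracyVerdict(
                ingredient=p.ingredient,
                equation_id=p.equation_id,
                observed_mean=observed_mean,
                margin=margin,
                predicted=p.predicted,
                within=abs(err) <= margin,
                signed_error=err,
            )
        )
    return sorted(verdicts, key=lambda v: abs(v.signed_error))
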