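"""Prediction-model evaluation: RMSE, mean error, bias correction.

Scores tables of model-predicted log K_aw against experimental values.
Errors are predicted minus experimental; the root-mean-squared error
uses the population mean (divide by n).  A model with a consistent
offset can be "bias-corrected" by subtracting its mean error, leaving
sqrt(RMSE^2 - ME^2) — e.g., a model at RMSE 0.42 with ME -0.34 drops to
~0.25 once the offset is removed.  Compounds missing from either table
are excluded pairwise and reported, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, NoOverlapError


@dataclass
class PredictionSet:
    """One model's per-compound predicted log K_aw.

    ``ad_flags`` carries applicability-domain annotations as opaque
    labels for reporting; no AD computation happens here.
    """

    model_name: str
    entries: Dict[str, float]
    ad_flags: Optional[Dict[str, str]] = None


@dataclass
class ErrorSummary:
    """Prediction-vs-experiment metrics for one model."""

    model_name: str
    n: int
    rmse: float
    me: float
    per_compound_errors: Dict[str, float]
    excluded: Sequence[str] = field(default_factory=list)


def error_summary(
    pred: PredictionSet, experimental: Mapping[str, float]
) -> ErrorSummary:
    """RMSE and mean error of predictions against experimental values."""
    common = sorted(set(pred.entries) & set(experimental))
    if not common:
        raise NoOverlapError(
            f"{pred.model_name}: no compound in both tables"
        )
    excluded = sorted(
        (set(pred.entries) | set(experimental)) - set(common)
    )
    errors = {
        c: pred.entries[c] - experimental[c] for c in common
    }
    e = np.array(list(errors.values()))
    return ErrorSummary(
        model_name=pred.model_name,
        n=len(common),
        rmse=float(np.sqrt(np.mean(e ** 2))),
        me=float(np.mean(e)),
        per_compound_errors=errors,
        excluded=excluded,
    )


def bias_corrected_rmse(summary: ErrorSummary) -> float:
    """RMSE after removing the mean error: sqrt(rmse^2 - me^2)."""
    if summary.n < 2:
        raise InvalidInputError("bias correction needs n >= 2")
    return math.sqrt(max(summary.rmse ** 2 - summary.me ** 2, 0.0))


def apply_offset(pred: PredictionSet, offset: float) -> PredictionSet:
    """Shift every prediction by a constant offset (bias correction)."""
    name = (
        pred.model_name
        if offset == 0
        else f"{pred.model_name}{offset:+g}"
    )
    return PredictionSet(
        model_name=name,
        entries={c: v + offset for c, v in pred.entries.items()},
        ad_flags=pred.ad_flags,
    )


def compare_models(
    pred_sets: Sequence[PredictionSet],
    experimental: Mapping[str, float],
) -> pd.DataFrame:
    """Rank models by RMSE (ties: |ME|, then name) against one dataset."""
    if not pred_sets:
        raise InvalidInputError("need at least one prediction set")
    summaries = [error_summary(p, experimental) for p in pred_sets]
    summaries.sort(key=lambda s: (s.rmse, abs(s.me), s.model_name))
    return pd.DataFrame(
        {
            "model": [s.model_name for s in summaries],
            "n": [s.n for s in summaries],
            "rmse": [s.rmse for s in summaries],
            "me": [s.me for s in summaries],
            "bias_corrected_rmse": [
                bias_corrected_rmse(s) if s.n >= 2 else float("nan")
                for s in summaries
            ],
            "n_excluded": [len(s.excluded) for s in summaries],
        }
    )
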