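"""Linear-correlation baseline: weight proportional to similarity score.

The comparison method assumes a missing link's weight is proportional to
its link-prediction similarity score, ŵ = λ·s, with λ the least-squares
(Frobenius-norm) minimizer of ||λS − W||.  Note the protocol this baseline
comes from fits λ against the *validation* weights, so predictive
information from the validation set leaks into the optimization; the
evaluation module reproduces that faithfully for comparability and logs a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["LinearFit", "fit_lambda", "predict_linear"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearFit:
    """A fitted proportionality coefficient λ for one similarity index."""

    lambda_: float
    index: Optional[str] = None


def fit_lambda(scores: Sequence[float], weights: Sequence[float], index: Optional[str] = None) -> LinearFit:
    """Closed-form λ = (Σ sᵢwᵢ) / (Σ sᵢ²) minimizing ||λS − W||."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape or s.ndim != 1 or s.size < 1:
        raise ValueError("scores and weights must be equal-length 1-D vectors of length >= 1")
    ss = float(s @ s)
    if ss == 0.0:
        raise ValueError("all similarity scores are zero; lambda is undefined")
    return LinearFit(lambda_=float(s @ w) / ss, index=index)


def predict_linear(scores: Sequence[float], fit: LinearFit) -> np.ndarray:
    """Element-wise λ·s."""
    return fit.lambda_ * np.asarray(scores, dtype=float)
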