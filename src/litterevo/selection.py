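"""Information-theoretic multi-model comparison (AICc, Akaike weights).

Shared by the trait-evolution fits and the subset regressions.  Candidates
are ranked by the small-sample-corrected criterion

    AICc = -2 lnL + 2p + 2p(p+1)/(n - p - 1),

and compared through the AICc differences ``delta_i`` to the best model, the
Akaike weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``, cumulative
weights in rank order, and evidence ratios ``ER_i = exp(delta_i/2)``
(how many times better the best model is supported than candidate i).  All
quantities are computed from unrounded scores; rounding is display-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CandidateScore",
    "ModelComparison",
    "aic",
    "aicc",
    "compare",
    "confidence_set",
]


def aic(lnl: float, p: int) -> float:
    return -2.0 * lnl + 2.0 * p


def aicc(lnl: float, p: int, n: int) -> float:
    """AICc; undefined (error) when n <= p + 1."""
    if n <= p + 1:
        raise ValueError(
            f"AICc undefined for n={n}, p={p} (needs n > p + 1)"
        )
    return aic(lnl, p) + 2.0 * p * (p + 1) / (n - p - 1)


@dataclass
class CandidateScore:
    label: str
    lnL: float
    p: int
    n: int

    @property
    def aic(self) -> float:
        return aic(self.lnL, self.p)

    @property
    def aicc(self) -> float:
        return aicc(self.lnL, self.p, self.n)


@dataclass
class ModelComparison:
    """Candidates ranked by the selection criterion (ascending)."""

    labels: list[str]
    criterion: np.ndarray  # AICc (or AIC) per candidate, in rank order
    delta: np.ndarray
    wi: np.ndarray
    acc_wi: np.ndarray
    er: np.ndarray
    criterion_name: str = "AICc"

    @property
    def best(self) -> str:
        return self.labels[0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                self.criterion_name: self.criterion,
                "delta": self.delta,
                "wi": self.wi,
                "acc_wi": self.acc_wi,
                "ER": self.er,
            }
        )


def compare(
    candidates: list[CandidateScore], criterion: str = "AICc"
) -> ModelComparison:
    """Rank candidates and compute delta, Akaike weights and evidence ratios.

    Weights are normalized over *all* supplied candidates; ties in the
    criterion are broken by label order.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to compare")
    if criterion == "AICc":
        scores = np.array([c.aicc for c in candidates])
    elif criterion == "AIC":
        scores = np.array([c.aic for c in candidates])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not np.all(np.isfinite(scores)):
        raise ValueError("all candidate scores must be finite")
    labels = [c.label for c in candidates]
    order = sorted(range(len(labels)), key=lambda i: (scores[i], labels[i]))
    scores = scores[order]
    labels = [labels[i] for i in order]
    delta = scores - scores[0]
    rel = np.exp(-delta / 2.0)
    wi = rel / rel.sum()
    return ModelComparison(
        labels=labels,
        criterion=scores,
        delta=delta,
        wi=wi,
        acc_wi=np.cumsum(wi),
        er=np.exp(delta / 2.0),
        criterion_name=criterion,
    )


def confidence_set(comparison: ModelComparison, level: float = 0.95) -> list[str]:
    """Minimal rank-prefix of candidates whose cumulative weight reaches
    ``level`` (includes every model while the preceding prefix is below it)."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    out = []
    acc = 0.0
    for label, w in zip(comparison.labels, comparison.wi):
        out.append(label)
        acc += w
        if acc >= level:
            break
    return out
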