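"""Position-specific weights and imputation between the two training passes.

Pass 1 trains with weight 6 on verified interactions (r_ij = 1) and 1
elsewhere, and no imputation.  Its fitted probabilities then (a) raise by one
the weight of every cell the model is confident about (p below p_low or above
p_high), and (b) set the pass-2 effective target to 1 where p >= p_high and
to max(r_ij, p_ij) otherwise -- verified interactions always keep target 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cosine.data_io import InteractionDataset


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ReweightConfig:
    """Thresholds for the pass-2 weight increment and imputation.

    ``p_low``/``p_high`` bound the "confident" region: the weight of a cell
    is incremented when its pass-1 probability falls below p_low (confident
    negative) or at/above p_high (confident positive); imputation to 1
    triggers at p >= p_high (closed boundary).
    """

    positive_weight: float = 6.0
    baseline_weight: float = 1.0
    p_low: float = 0.1
    p_high: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.p_low < self.p_high < 1.0):
            raise ConfigError(
                f"thresholds must satisfy 0 < p_low < p_high < 1, got ({self.p_low}, {self.p_high})"
            )
        if self.positive_weight < self.baseline_weight or self.baseline_weight < 1:
            raise ConfigError("weights must satisfy positive_weight >= baseline_weight >= 1")


def initial_weights(data: InteractionDataset, cfg: ReweightConfig = ReweightConfig()) -> np.ndarray:
    """W with 6 on observed interactions and 1 elsewhere (defaults)."""
    return np.where(data.R == 1, cfg.positive_weight, cfg.baseline_weight).astype(float)


def update_weights(W: np.ndarray, P: np.ndarray, p_low: float = 0.1, p_high: float = 0.9) -> np.ndarray:
    """Increment weights by 1 on the confident set {p < p_low or p >= p_high}."""
    if not (0.0 < p_low < p_high < 1.0):
        raise ConfigError(f"thresholds must satisfy 0 < p_low < p_high < 1, got ({p_low}, {p_high})")
    W = np.asarray(W, dtype=float)
    P = np.asarray(P, dtype=float)
    if W.shape != P.shape:
        raise ValueError("weight and probability shapes differ")
    confident = (P < p_low) | (P >= p_high)
    return W + confident.astype(float)


def impute(data: InteractionDataset, P: np.ndarray, p_high: float = 0.9) -> np.ndarray:
    """Imputation matrix Q from pass-1 probabilities.

    The effective target t_ij = r_ij + q_ij is 1 where p_ij >= p_high and
    max(r_ij, p_ij) otherwise, so q_ij = 0 wherever r_ij = 1.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != data.R.shape:
        raise ValueError("probability matrix does not match data shape")
    T = np.where(P >= p_high, 1.0, np.maximum(data.R, P))
    return T - data.R
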