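"""AdaGrad minimization and the two-pass training driver.

Full-batch AdaGrad: each coordinate of F and G keeps a running sum of its
squared gradients and is updated by

    theta <- theta - lr * g / (sqrt(sum of past g^2) + eps).

The driver runs the loss minimization twice: pass 1 with initial weights
(6 on positives, 1 elsewhere) and no imputation; then weights are
incremented on confidently-predicted cells and targets imputed from the
pass-1 probabilities; pass 2 re-minimizes under the updated weights and
targets, warm-started from the pass-1 solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from cosine.data_io import InteractionDataset, SimilarityMatrix
from cosine.factor_model import (
    FactorModel,
    NumericError,
    TrainingState,
    gradients,
    loss,
    predict_probability,
)
from cosine.reweight import ReweightConfig, impute, initial_weights, update_weights


@dataclass(frozen=True)
class OptimizerConfig:
    """Solver knobs: learning rate, AdaGrad epsilon, iteration budget, init."""

    learning_rate: float = 0.5
    adagrad_epsilon: float = 1e-8
    iterations: int = 600
    seed: int = 0
    init_scale: Optional[float] = None  # default 1/sqrt(rank)
    loss_tol: float = 0.0  # optional relative-change early stop; 0 disables

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")


@dataclass(frozen=True)
class ModelConfig:
    """Model hyperparameters for a fit."""

    rank: int = 5
    lambda_F: float = 0.1
    lambda_G: float = 0.1
    lambda_M: float = 0.25
    lambda_N: float = 0.25
    mode: str = "logistic"


@dataclass
class FitResult:
    """Two-pass fit output: final model/state plus both pass loss traces."""

    model: FactorModel
    state: TrainingState
    pass1_model: FactorModel
    pass1_trace: list[float]
    pass2_trace: list[float]


def init_factors(m: int, n: int, rank: int, cfg: OptimizerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian initialization F, G ~ N(0, init_scale^2), seeded."""
    scale = cfg.init_scale if cfg.init_scale is not None else 1.0 / np.sqrt(rank)
    rng = np.random.default_rng(cfg.seed)
    return scale * rng.standard_normal((m, rank)), scale * rng.standard_normal((n, rank))


def adagrad_minimize(
    model: FactorModel,
    data: InteractionDataset,
    state: TrainingState,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
    cfg: OptimizerConfig,
) -> tuple[FactorModel, list[float]]:
    """Minimize the model's loss in place (on a copy); returns (model, loss_trace).

    The trace records the loss after each of ``cfg.iterations`` updates.
    """
    model = model.copy()
    state.accum_F = np.zeros_like(model.F) if state.accum_F is None else state.accum_F
    state.accum_G = np.zeros_like(model.G) if state.accum_G is None else state.accum_G
    trace: list[float] = []
    prev = None
    for it in range(cfg.iterations):
        dF, dG = gradients(model, data, state, M, N)
        state.accum_F += dF**2
        state.accum_G += dG**2
        model.F -= cfg.learning_rate * dF / (np.sqrt(state.accum_F) + cfg.adagrad_epsilon)
        model.G -= cfg.learning_rate * dG / (np.sqrt(state.accum_G) + cfg.adagrad_epsilon)
        value = loss(model, data, state, M, N)
        if not np.isfinite(value):
            raise NumericError(f"non-finite loss at iteration {it + 1}")
        trace.append(value)
        if cfg.loss_tol > 0 and prev is not None and abs(prev - value) <= cfg.loss_tol * abs(prev):
            break
        prev = value
    state.loss_trace.extend(trace)
    return model, trace


def fit_pass1(
    data: InteractionDataset,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
    model_cfg: ModelConfig = ModelConfig(),
    opt_cfg: OptimizerConfig = OptimizerConfig(),
    reweight_cfg: ReweightConfig = ReweightConfig(),
) -> tuple[FactorModel, TrainingState, list[float]]:
    """Single minimization with initial weights and Q = 0."""
    m, n = data.R.shape
    F0, G0 = init_factors(m, n, model_cfg.rank, opt_cfg)
    model = FactorModel(
        F0, G0,
        model_cfg.lambda_F, model_cfg.lambda_G, model_cfg.lambda_M, model_cfg.lambda_N,
        model_cfg.mode,
    )
    state = TrainingState(W=initial_weights(data, reweight_cfg), Q=np.zeros((m, n)))
    state.validate(data.R)
    model, trace = adagrad_minimize(model, data, state, M, N, opt_cfg)
    return model, state, trace


def fit_cosine(
    data: InteractionDataset,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
    model_cfg: ModelConfig = ModelConfig(),
    opt_cfg: OptimizerConfig = OptimizerConfig(),
    reweight_cfg: ReweightConfig = ReweightConfig(),
    Q_override: Optional[np.ndarray] = None,
) -> FitResult:
    """Full two-pass training.

    ``Q_override`` lets callers inject externally-derived imputation values
    for pass 2 in place of the probability-driven rule.
    """
    model1, state1, trace1 = fit_pass1(data, M, N, model_cfg, opt_cfg, reweight_cfg)
    P1 = predict_probability(model1)
    W2 = update_weights(state1.W, P1, reweight_cfg.p_low, reweight_cfg.p_high)
    Q2 = impute(data, P1, reweight_cfg.p_high) if Q_override is None else np.asarray(Q_override, float)
    state2 = TrainingState(W=W2, Q=Q2)
    state2.validate(data.R)
    # pass 2 warm-starts from the pass-1 solution with fresh AdaGrad accumulators
    model2 = model1.copy()
    model2, trace2 = adagrad_minimize(model2, data, state2, M, N, opt_cfg)
    return FitResult(
        model=model2, state=state2, pass1_model=model1, pass1_trace=trace1, pass2_trace=trace2
    )
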