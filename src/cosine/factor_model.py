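"""The probabilistic factorization model and its loss/gradients.

The interaction matrix R (m targets x n chemicals) is approximated by the
low-rank product F G^T with F of shape (m, r) and G of shape (n, r).  In
logistic mode the interaction probability is

    p_ij = sigma(f_i . g_j) = exp(f_i . g_j) / (1 + exp(f_i . g_j)),

and the training objective is weighted logistic matrix factorization over
all cells, with per-cell confidence weights w_ij and imputation values q_ij
shifting the effective target to t_ij = r_ij + q_ij:

    L = sum_ij w_ij [ log(1 + exp(x_ij)) - t_ij x_ij ]            (data term)
      + (lambda_F / 2) ||F||_Fro^2 + (lambda_G / 2) ||G||_Fro^2   (Gaussian priors)
      + (lambda_M / 2) H(F; M) + (lambda_N / 2) H(G; N)           (dual homophily)

where x = F G^T and H(L; S) = (1/2) sum_ij s_ij ||l_i - l_j||^2 is the
graph-Laplacian homophily penalty pulling similar entities (by sequence
similarity M or chemical similarity N) toward nearby latent vectors.  The
data term is the negative log of the weighted Bernoulli likelihood of R + Q,
so minimizing L is maximum a posteriori estimation under Gaussian priors.

Linear mode swaps the data term for weighted squared error
sum_ij w_ij (t_ij - x_ij)^2 and predicts scores x_ij directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, log1p

from cosine.data_io import InteractionDataset, SimilarityMatrix


class NumericError(FloatingPointError):
    """Non-finite values encountered in model quantities."""


@dataclass
class FactorModel:
    """Latent factor matrices plus model hyperparameters.

    Attributes
    ----------
    F, G : ndarray
        Target (m x r) and chemical (n x r) latent matrices.
    lambda_F, lambda_G : float
        Frobenius (ridge) penalties on F and G.
    lambda_M, lambda_N : float
        Homophily penalties tied to the target/chemical similarity graphs.
    mode : {"logistic", "linear"}
    """

    F: np.ndarray
    G: np.ndarray
    lambda_F: float = 0.0
    lambda_G: float = 0.0
    lambda_M: float = 0.0
    lambda_N: float = 0.0
    mode: str = "logistic"

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.F.ndim != 2 or self.G.ndim != 2 or self.F.shape[1] != self.G.shape[1]:
            raise ValueError(f"incompatible factor shapes {self.F.shape}, {self.G.shape}")
        if self.mode not in ("logistic", "linear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for lam in (self.lambda_F, self.lambda_G, self.lambda_M, self.lambda_N):
            if lam < 0:
                raise ValueError("regularization parameters must be nonnegative")

    @property
    def rank(self) -> int:
        return self.F.shape[1]

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.F.copy(), self.G.copy(),
            self.lambda_F, self.lambda_G, self.lambda_M, self.lambda_N, self.mode,
        )


@dataclass
class TrainingState:
    """Per-cell weights, imputation values, and optimizer bookkeeping.

    Invariants: w_ij >= 1 everywhere (the baseline negative weight) and
    0 <= r_ij + q_ij <= 1 for every cell.
    """

    W: np.ndarray
    Q: np.ndarray
    loss_trace: list[float] = field(default_factory=list)
    accum_F: Optional[np.ndarray] = None
    accum_G: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.W.shape != self.Q.shape:
            raise ValueError("W and Q shapes differ")

    def validate(self, R: np.ndarray) -> None:
        if (self.W < 1).any():
            raise ValueError("weights below the baseline of 1")
        T = R + self.Q
        if (T < -1e-12).any() or (T > 1 + 1e-12).any():
            raise ValueError("effective targets r_ij + q_ij outside [0, 1]")


def _scores(model: FactorModel) -> np.ndarray:
    X = model.F @ model.G.T
    if not np.isfinite(X).all():
        raise NumericError("non-finite latent scores")
    return X


def predict_scores(model: FactorModel) -> np.ndarray:
    """Raw factorization scores x_ij = f_i . g_j (the linear-mode prediction)."""
    return _scores(model)


def predict_probability(model: FactorModel) -> np.ndarray:
    """Interaction probabilities p_ij = sigma(f_i . g_j), overflow-safe.

    In linear mode the raw scores are still mapped through the sigmoid so
    downstream ranking code sees one probability-like scale.
    """
    p = expit(_scores(model))
    # saturated scores round to exactly 0/1 in float64; keep the open interval
    return np.clip(p, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)) without overflow: max(x, 0) + log1p(exp(-|x|))
    return np.maximum(x, 0.0) + log1p(np.exp(-np.abs(x)))


def homophily_penalty(L: np.ndarray, S: np.ndarray) -> float:
    """Graph homophily H(L; S) = (1/2) sum_ij s_ij ||l_i - l_j||^2.

    Computed via the Laplacian quadratic form trace(L^T (D - S) L) with
    D = diag(row sums of S); requires symmetric S.
    """
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1] or S.shape[0] != L.shape[0]:
        raise ValueError(f"shape mismatch: L {L.shape}, S {S.shape}")
    if not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    lap = np.diag(S.sum(axis=1)) - S
    return float(np.trace(L.T @ lap @ L))


def _check_shapes(model, data, state, M, N) -> None:
    m, n = data.R.shape
    if model.F.shape[0] != m or model.G.shape[0] != n:
        raise ValueError(
            f"factor shapes {model.F.shape}, {model.G.shape} do not match data {data.R.shape}"
        )
    if state.W.shape != (m, n):
        raise ValueError("weight/impute matrices do not match data shape")
    if M.S.shape != (m, m) or N.S.shape != (n, n):
        raise ValueError("similarity matrices do not match data shape")


def _regularization(model: FactorModel, M: SimilarityMatrix, N: SimilarityMatrix) -> float:
    reg = 0.5 * model.lambda_F * float(np.sum(model.F**2))
    reg += 0.5 * model.lambda_G * float(np.sum(model.G**2))
    if model.lambda_M > 0:
        reg += 0.5 * model.lambda_M * homophily_penalty(model.F, M.S)
    if model.lambda_N > 0:
        reg += 0.5 * model.lambda_N * homophily_penalty(model.G, N.S)
    return reg


def logistic_loss(
    model: FactorModel,
    data: InteractionDataset,
    state: TrainingState,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
) -> float:
    """Full regularized weighted logistic loss (see module docstring)."""
    _check_shapes(model, data, state, M, N)
    X = _scores(model)
    T = data.R + state.Q
    data_term = float(np.sum(state.W * (_softplus(X) - T * X)))
    return data_term + _regularization(model, M, N)


def linear_loss(
    model: FactorModel,
    data: InteractionDataset,
    state: TrainingState,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
) -> float:
    """Weighted squared-error loss sum_ij w_ij (t_ij - x_ij)^2 plus the same regularizers."""
    _check_shapes(model, data, state, M, N)
    X = _scores(model)
    T = data.R + state.Q
    data_term = float(np.sum(state.W * (T - X) ** 2))
    return data_term + _regularization(model, M, N)


def loss(model, data, state, M, N) -> float:
    """Dispatch on ``model.mode``."""
    fn = logistic_loss if model.mode == "logistic" else linear_loss
    return fn(model, data, state, M, N)


def gradients(
    model: FactorModel,
    data: InteractionDataset,
    state: TrainingState,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients (dL/dF, dL/dG) of the mode's loss.

    Logistic data-term gradient: [W o (P - (R+Q))] G for F (transposed for G),
    with o the Hadamard product; linear: 2 [W o (X - (R+Q))] G.  Plus ridge
    terms lambda_F F / lambda_G G and Laplacian terms lambda_M (D_M - M) F /
    lambda_N (D_N - N) G.
    """
    _check_shapes(model, data, state, M, N)
    X = _scores(model)
    T = data.R + state.Q
    if model.mode == "logistic":
        E = state.W * (expit(X) - T)
    else:
        E = 2.0 * state.W * (X - T)
    dF = E @ model.G + model.lambda_F * model.F
    dG = E.T @ model.F + model.lambda_G * model.G
    if model.lambda_M > 0:
        lap_M = np.diag(M.S.sum(axis=1)) - M.S
        dF = dF + model.lambda_M * (lap_M @ model.F)
    if model.lambda_N > 0:
        lap_N = np.diag(N.S.sum(axis=1)) - N.S
        dG = dG + model.lambda_N * (lap_N @ model.G)
    return dF, dG
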