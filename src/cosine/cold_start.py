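"""Weighted-profile cold start for entities with no observed interactions.

A brand-new chemical (or target) has an uninformative trained latent row --
during training its column carried only baseline-weight zeros.  The
weighted-profile rule replaces that row with a blend of the trained row and
the similarity-weighted mean of the J most similar entities that DO have
interaction data:

    f_i' = v * f_i + (1 - v) * (1 / SM) * sum_{j in top-J} m_ij f_j,
    SM = sum_{j in top-J} m_ij,

and symmetrically for chemical rows of G using the chemical similarities.
v = 0 gives the pure neighbor profile, v = 1 keeps the trained row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from cosine.data_io import InteractionDataset, SimilarityMatrix
from cosine.factor_model import FactorModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColdStartConfig:
    """J = neighbor count; v in [0, 1] = weight on the trained latent row."""

    J: int = 5
    v: float = 0.5

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not (0.0 <= self.v <= 1.0):
            raise ValueError("v must lie in [0, 1]")


def weighted_profile_row(
    trained_row: np.ndarray,
    neighbor_rows: np.ndarray,
    neighbor_sims: np.ndarray,
    v: float,
) -> np.ndarray:
    """Blend a trained latent row with its similarity-weighted neighbor profile.

    Falls back to the trained row (with a warning) when no neighbor has
    positive similarity, since the profile is then undefined.
    """
    trained_row = np.asarray(trained_row, dtype=float)
    neighbor_rows = np.atleast_2d(np.asarray(neighbor_rows, dtype=float))
    neighbor_sims = np.atleast_1d(np.asarray(neighbor_sims, dtype=float))
    keep = neighbor_sims > 0
    SM = float(neighbor_sims[keep].sum())
    if SM <= 0:
        logger.warning("no positive-similarity neighbor; falling back to trained row")
        return trained_row.copy()
    profile = (neighbor_sims[keep] @ neighbor_rows[keep]) / SM
    return v * trained_row + (1.0 - v) * profile


def _top_neighbors(sims: np.ndarray, pool: np.ndarray, J: int) -> np.ndarray:
    """Indices of the J highest-similarity pool members; ties broken by index order."""
    order = np.lexsort((pool, -sims[pool]))  # primary: similarity desc, secondary: index asc
    return pool[order[:J]]


def apply_cold_start(
    model: FactorModel,
    data: InteractionDataset,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
    cfg: ColdStartConfig = ColdStartConfig(),
    new_targets: Iterable[int] = (),
    new_chemicals: Iterable[int] = (),
) -> FactorModel:
    """Rewrite the designated rows of F and G with weighted profiles.

    Neighbors are drawn only from entities NOT in the new sets (those with
    interaction data).  Only the designated rows change.
    """
    new_t = np.asarray(sorted(set(new_targets)), dtype=int)
    new_c = np.asarray(sorted(set(new_chemicals)), dtype=int)
    out = model.copy()
    if new_t.size:
        pool = np.setdiff1d(np.arange(model.F.shape[0]), new_t)
        if pool.size == 0:
            raise ValueError("no targets with interaction data to serve as neighbors")
        for i in new_t:
            nbrs = _top_neighbors(M.S[i], pool, cfg.J)
            out.F[i] = weighted_profile_row(model.F[i], model.F[nbrs], M.S[i, nbrs], cfg.v)
    if new_c.size:
        pool = np.setdiff1d(np.arange(model.G.shape[0]), new_c)
        if pool.size == 0:
            raise ValueError("no chemicals with interaction data to serve as neighbors")
        for j in new_c:
            nbrs = _top_neighbors(N.S[j], pool, cfg.J)
            out.G[j] = weighted_profile_row(model.G[j], model.G[nbrs], N.S[j, nbrs], cfg.v)
    return out
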