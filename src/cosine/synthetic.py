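"""Synthetic interaction/similarity fixtures with the structure the model assumes.

Targets and chemicals are drawn around a small number of cluster centroids in
a shared latent space, interactions arise from the logistic link on the
latent inner products, and the similarity matrices are computed from the SAME
latent vectors (RBF kernel) -- so the low-rank and homophily assumptions hold
by construction.  Noise knobs break them controllably for robustness
experiments.  Binary sampling uses deterministic quantile thresholding so the
positive count is exact; a Bernoulli mode exists behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from cosine.data_io import InteractionDataset, SimilarityMatrix, _standardize_similarity


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters: sizes, true rank, cluster structure, density, noise."""

    m: int = 50
    n: int = 80
    rank: int = 3
    n_target_clusters: int = 4
    n_chemical_clusters: int = 5
    interaction_density: float = 0.08
    similarity_noise: float = 0.0
    within_cluster_sd: float = 0.3
    seed: int = 0
    bernoulli: bool = False

    def __post_init__(self) -> None:
        if self.rank > min(self.m, self.n):
            raise ValueError("rank must not exceed min(m, n)")
        if not (0.0 < self.interaction_density < 1.0):
            raise ValueError("interaction_density must lie in (0, 1)")
        if self.n_target_clusters > self.m or self.n_chemical_clusters > self.n:
            raise ValueError("cluster counts must not exceed entity counts")


@dataclass
class Fixture:
    """A generated dataset plus its full ground truth."""

    data: InteractionDataset
    M: SimilarityMatrix
    N: SimilarityMatrix
    F_true: np.ndarray
    G_true: np.ndarray
    scores: np.ndarray  # true latent scores F_true @ G_true.T
    target_clusters: np.ndarray
    chemical_clusters: np.ndarray


def _latent_clusters(rng, k_entities, n_clusters, rank, within_sd):
    centroids = rng.standard_normal((n_clusters, rank))
    assignment = np.sort(rng.integers(0, n_clusters, size=k_entities))
    latent = centroids[assignment] + within_sd * rng.standard_normal((k_entities, rank))
    return latent, assignment


def _rbf_similarity(latent: np.ndarray, noise_sd: float, rng, ids) -> SimilarityMatrix:
    dist = squareform(pdist(latent))
    positive = dist[dist > 0]
    bandwidth = np.median(positive) if positive.size else 1.0
    S = np.exp(-(dist**2) / (2.0 * bandwidth**2))
    if noise_sd > 0:
        S = S + noise_sd * rng.standard_normal(S.shape)
    return _standardize_similarity(ids, S, source="synthetic")


def generate_fixture(spec: SyntheticSpec) -> Fixture:
    """Generate (interactions, target similarity, chemical similarity) + truth."""
    rng = np.random.default_rng(spec.seed)
    F_true, t_clusters = _latent_clusters(
        rng, spec.m, spec.n_target_clusters, spec.rank, spec.within_cluster_sd
    )
    G_true, c_clusters = _latent_clusters(
        rng, spec.n, spec.n_chemical_clusters, spec.rank, spec.within_cluster_sd
    )
    X = F_true @ G_true.T
    n_pos = int(round(spec.interaction_density * spec.m * spec.n))
    if n_pos < 1 or n_pos >= spec.m * spec.n:
        raise ValueError("interaction density yields no achievable threshold")
    if spec.bernoulli:
        # calibrate a scale so the expected positive count matches the density
        from scipy.special import expit

        flat = X.ravel()
        thresh = np.partition(flat, -n_pos)[-n_pos]
        P = expit(4.0 * (X - thresh))
        R = (rng.random(X.shape) < P).astype(float)
    else:
        flat = X.ravel()
        cutoff_idx = np.argpartition(flat, -n_pos)[-n_pos:]
        R = np.zeros(spec.m * spec.n)
        R[cutoff_idx] = 1.0
        R = R.reshape(spec.m, spec.n)
    target_ids = [f"T{i:04d}" for i in range(spec.m)]
    chemical_ids = [f"C{j:04d}" for j in range(spec.n)]
    data = InteractionDataset(target_ids, chemical_ids, R)
    M = _rbf_similarity(F_true, spec.similarity_noise, rng, target_ids)
    N = _rbf_similarity(G_true, spec.similarity_noise, rng, chemical_ids)
    return Fixture(data, M, N, F_true, G_true, X, t_clusters, c_clusters)


def hide_positives(
    data: InteractionDataset, fraction: float, seed: int
) -> tuple[InteractionDataset, list[tuple[int, int]]]:
    """Zero a random round(fraction * positives) subset of positive entries.

    Returns the masked dataset and the hidden (target, chemical) index pairs.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    pos = np.argwhere(data.R == 1)
    if pos.shape[0] == 0:
        raise ValueError("dataset has no positives to hide")
    n_hide = int(round(fraction * pos.shape[0]))
    rng = np.random.default_rng(seed)
    chosen = pos[rng.choice(pos.shape[0], size=n_hide, replace=False)]
    masked = data.copy()
    masked.R[chosen[:, 0], chosen[:, 1]] = 0.0
    return masked, [tuple(map(int, ij)) for ij in chosen]


def inject_noise(
    data: InteractionDataset, flip_fraction: float, mode: str, seed: int
) -> tuple[InteractionDataset, list[tuple[int, int]]]:
    """Flip a fraction of entries to emulate missing or spurious interactions.

    ``remove_true_positives`` flips round(fraction * positives) ones to zero;
    ``add_false_positives`` flips the same count of zeros to one (fraction is
    always relative to the current positive count, so the two modes inject
    comparable corruption).
    """
    if mode not in ("add_false_positives", "remove_true_positives"):
        raise ValueError(f"unknown mode {mode!r}")
    if flip_fraction < 0:
        raise ValueError("flip_fraction must be nonnegative")
    corrupted = data.copy()
    if flip_fraction == 0:
        return corrupted, []
    n_pos = int((data.R == 1).sum())
    n_flip = int(round(flip_fraction * n_pos))
    rng = np.random.default_rng(seed)
    if mode == "remove_true_positives":
        candidates = np.argwhere(data.R == 1)
        new_value = 0.0
    else:
        candidates = np.argwhere(data.R == 0)
        new_value = 1.0
    if n_flip > candidates.shape[0]:
        raise ValueError(f"requested {n_flip} flips but only {candidates.shape[0]} candidate cells")
    chosen = candidates[rng.choice(candidates.shape[0], size=n_flip, replace=False)]
    corrupted.R[chosen[:, 0], chosen[:, 1]] = new_value
    return corrupted, [tuple(map(int, ij)) for ij in chosen]


@dataclass
class ColdStartFixture:
    """Fixture whose designated chemicals have one known target, hidden from training."""

    data: InteractionDataset  # cold chemicals' columns are all-zero here
    M: SimilarityMatrix
    N: SimilarityMatrix
    cold_chemicals: list[int]
    hidden_targets: dict[int, int]  # chemical index -> its single true target index
    ligands_per_target: dict[int, int]  # chemical index -> visible ligand count of its target
    max_chemical_similarity: dict[int, float]  # chemical index -> max sim to a training chemical
    F_true: np.ndarray
    G_true: np.ndarray


def make_coldstart_fixture(
    spec: SyntheticSpec, n_cold: Optional[int] = None
) -> ColdStartFixture:
    """Designate a chemical subset as cold start: one hidden true target each.

    Each designated chemical keeps exactly one true target (its strongest by
    latent score), hidden from training along with the rest of its column.
    Strata metadata (ligands per target, max chemical similarity to the
    training pool) is attached for stratified evaluation.
    """
    fx = generate_fixture(spec)
    rng = np.random.default_rng(spec.seed + 1)
    if n_cold is None:
        n_cold = max(2, spec.n // 5)
    cold = sorted(rng.choice(spec.n, size=n_cold, replace=False).tolist())
    data = fx.data.copy()
    hidden: dict[int, int] = {}
    for j in cold:
        hidden[j] = int(np.argmax(fx.scores[:, j]))
        data.R[:, j] = 0.0
    warm = [j for j in range(spec.n) if j not in set(cold)]
    ligands = {j: int(data.R[hidden[j], warm].sum()) for j in cold}
    max_sim = {j: float(fx.N.S[j, warm].max()) for j in cold}
    return ColdStartFixture(
        data=data,
        M=fx.M,
        N=fx.N,
        cold_chemicals=cold,
        hidden_targets=hidden,
        ligands_per_target=ligands,
        max_chemical_similarity=max_sim,
        F_true=fx.F_true,
        G_true=fx.G_true,
    )
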