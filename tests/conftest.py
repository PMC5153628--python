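import numpy as np
import pytest

from cosine.data_io import InteractionDataset, SimilarityMatrix
from cosine.factor_model import FactorModel, TrainingState
from cosine.synthetic import SyntheticSpec, generate_fixture, hide_positives


def random_instance(seed: int, m: int = 4, n: int = 5, rank: int = 2, mode: str = "logistic"):
    """A small random model/data/state/similarity bundle for oracle tests."""
    rng = np.random.default_rng(seed)
    R = (rng.random((m, n)) < 0.3).astype(float)
    data = InteractionDataset([f"t{i}" for i in range(m)], [f"c{j}" for j in range(n)], R)
    model = FactorModel(
        F=rng.standard_normal((m, rank)),
        G=rng.standard_normal((n, rank)),
        lambda_F=rng.uniform(0.01, 1.0),
        lambda_G=rng.uniform(0.01, 1.0),
        lambda_M=rng.uniform(0.01, 1.0),
        lambda_N=rng.uniform(0.01, 1.0),
        mode=mode,
    )
    W = 1.0 + 5.0 * rng.random((m, n))
    P_fake = rng.random((m, n))
    Q = np.where(R == 1, 0.0, 0.5 * P_fake)  # keeps r+q in [0,1]
    state = TrainingState(W=W, Q=Q)

    def sym01(k):
        A = rng.random((k, k))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        return S

    M = SimilarityMatrix([f"t{i}" for i in range(m)], sym01(m))
    N = SimilarityMatrix([f"c{j}" for j in range(n)], sym01(n))
    return model, data, state, M, N


@pytest.fixture(scope="session")
def standard_fixture():
    """The 50x80 rank-3 fixture with 25% of positives hidden (fixed seeds)."""
    fx = generate_fixture(SyntheticSpec(seed=0))
    masked, hidden = hide_positives(fx.data, 0.25, seed=100)
    return fx, masked, hidden


@pytest.fixture(scope="session")
def nr_sized_fixture():
    """A Nuclear-Receptor-sized instance (~26 targets x 54 chemicals)."""
    return generate_fixture(
        SyntheticSpec(
            m=26, n=54, rank=3, n_target_clusters=3, n_chemical_clusters=4,
            interaction_density=0.06, seed=0,
        )
    )
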