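import numpy as np
import pytest

from sleepstrat.containers import EmbeddingMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_regime_embeddings(
    n_per_regime: int,
    centers,
    embed_dim: int = 8,
    n_epochs_range=(40, 80),
    spread: float = 0.3,
    seed: int = 0,
):
    """Gaussian epoch-embedding matrices from planted regimes.

    Each regime has a center vector; a recording's epoch embeddings are
    draws around that center, with the epoch count varying per recording.
    Returns (labels, embeddings).
    """
    rng = np.random.default_rng(seed)
    labels, embs = [], []
    for i in range(n_per_regime * len(centers)):
        g = i % len(centers)
        n = int(rng.integers(*n_epochs_range))
        vals = np.asarray(centers[g])[:, None] + spread * rng.standard_normal(
            (embed_dim, n)
        )
        embs.append(EmbeddingMatrix(vals[:embed_dim], recording_id=f"r{i:03d}"))
        labels.append(g)
    return np.array(labels), embs
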