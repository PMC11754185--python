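import numpy as np
import pytest

from lrcl.data import encode_labels
from lrcl.simulate import GeneratorSpec, generate, generate_worked_instance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked():
    """Frozen N=8, K=2, d=(3,3) instance with clean class structure."""
    return generate_worked_instance()


@pytest.fixture
def small_dataset():
    """Compact synthetic dataset fast enough for solver round trips."""
    return generate(GeneratorSpec(N=80, d=(6, 5), sep=1.5, seed=7, distractor_multiplier=1))


def random_instance(rng, N=12, d=(4, 3), C=2, with_graph=True, alpha=0.3, beta=0.5):
    """A small random solver instance: views, one-hot labels, graphs, priors."""
    from lrcl.graph import edge_weights
    from lrcl.relaxation import build_luxury_matrix
    from lrcl.solver import consensus_target, ridge_prior

    labels = rng.integers(0, C, size=N)
    while len(np.unique(labels)) < C:
        labels = rng.integers(0, C, size=N)
    X_all = [rng.standard_normal((N, dk)) + labels[:, None] for dk in d]
    lm = encode_labels(labels)
    Y = lm.Y
    U = build_luxury_matrix(lm)
    graphs = [edge_weights(X, labels, delta="auto", view_index=k) for k, X in enumerate(X_all)]
    P = [ridge_prior(X, Y, 1.0) for X in X_all]
    K = len(X_all)
    if K >= 2 and beta > 0:
        C_all = [consensus_target(X_all, P, k) for k in range(K)]
    else:
        C_all = [np.zeros_like(Y) for _ in range(K)]
    return {
        "X": X_all, "labels": labels, "Y": Y, "U": U,
        "graphs": graphs, "P": P, "C": C_all, "alpha": alpha, "beta": beta,
    }
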