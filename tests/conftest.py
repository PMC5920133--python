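import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tppc import (
    AnalysisConfig,
    Layer,
    MatchedDataset,
    OmicsMatrix,
    classify_pairs,
    compute_pair_statistics,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def exact_corr_data(R, n, seed=0):
    """Variables x samples data whose sample correlation matrix equals R exactly.

    Columns of an orthonormalised Gaussian basis are mixed by the Cholesky
    factor of R, so the construction is exact up to floating point.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, k))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    L = np.linalg.cholesky(R)
    return (Q @ L.T).T


def make_matrix(values, layer=Layer.METABOLITE, prefix="v"):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        values,
        tuple(f"{prefix}{i:03d}" for i in range(values.shape[0])),
        tuple(f"s{j:03d}" for j in range(values.shape[1])),
        layer,
    )


def noise_dataset(n_transcripts=50, n_metabolites=8, n_samples=40, seed=0):
    """Matched dataset in which every variable is independent Gaussian noise."""
    rng = np.random.default_rng(seed)
    return MatchedDataset(
        transcripts=make_matrix(
            rng.standard_normal((n_transcripts, n_samples)), Layer.TRANSCRIPT, "t"
        ),
        metabolites=make_matrix(
            rng.standard_normal((n_metabolites, n_samples)), Layer.METABOLITE, "m"
        ),
    )


def classify_dataset(dataset, config: AnalysisConfig):
    """Statistics + classification without the (slow) PC-retention criteria."""
    stats = compute_pair_statistics(dataset, config)
    return classify_pairs(stats, config)


@pytest.fixture
def tiny_tsv(tmp_path):
    path = tmp_path / "tiny.tsv"
    path.write_text("id\ts1\ts2\ngeneA\t1.0\t2.0\ngeneB\t3.5\t-1.5\ngeneC\t0\t4\n")
    return path
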