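import numpy as np
import pytest

from pharmlink.aers import (
    build_profiles,
    build_vocabulary,
    filter_suspect_drugs,
)
from pharmlink.similarity import (
    align_to,
    pharm_similarity_matrix,
    seq_similarity_matrix,
)
from pharmlink.synthetic import WorldSpec, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (seed 42), shared across the session."""
    return generate_world(WorldSpec())


@pytest.fixture(scope="session")
def world_kernels(default_world):
    """Drug (AERS-freq pharmacological) and target (sequence) kernels."""
    truth = default_world
    spec = truth.spec
    reports = filter_suspect_drugs(truth.reports)
    vocab = build_vocabulary(
        reports, max_freq=spec.max_freq, min_reports=spec.min_reports
    )
    profiles = build_profiles(reports, vocab, mode="freq")
    Kx = align_to(pharm_similarity_matrix(profiles, vocab), truth.drug_ids)
    Ky = seq_similarity_matrix(sorted(truth.sequences.items()))
    return Kx, Ky


def random_spd_kernel(n: int, rng: np.random.Generator, jitter: float = 1e-6):
    """Random symmetric positive-definite kernel with unit-scale diagonal."""
    A = rng.standard_normal((n, 2 * n))
    K = A @ A.T
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    return K + jitter * np.eye(n)
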