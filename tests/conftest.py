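import numpy as np
import pytest
from hypothesis import settings

import h2rs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_matrix() -> h2rs.SimilarityMatrix:
    """Full-size BLOSUM62-derived example similarity matrix."""
    return h2rs.example_similarity_matrix()


@pytest.fixture(scope="session")
def identity_matrix() -> h2rs.SimilarityMatrix:
    return h2rs.SimilarityMatrix.identity()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140427)


@pytest.fixture()
def small_alignment() -> h2rs.Alignment:
    return h2rs.Alignment(
        ["s1", "s2", "s3", "s4"],
        ["ACDEF", "ACDEG", "AKDEF", "ACWEF"],
    )
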