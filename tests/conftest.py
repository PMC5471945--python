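import numpy as np
import pytest

import metlike as ml


@pytest.fixture(scope="session")
def bundle():
    return ml.load_fixture_bundle()


@pytest.fixture(scope="session")
def fixture_matrix(bundle):
    """Similarity matrix of the bundled benchmark structures."""
    return ml.build_matrix(bundle.drugs, bundle.metabolites)


@pytest.fixture(scope="session")
def fixture_gsp(bundle, fixture_matrix):
    """Gold standard recomputed from the bundled structures."""
    return ml.select_gsp(fixture_matrix, bundle.drug_enzyme_pairs(),
                         bundle.enzymes)


def planted_block_matrix(n_drugs, n_mets, block_drugs, block_mets, seed=0):
    """Similarity matrix with one high-similarity block on a structured
    low-similarity background.

    Block cells are ~U(0.8, 0.9); background cells follow a shared
    per-column base level (so background rows cluster together, away from
    the block) plus small jitter, all below 0.2.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.02, 0.15, size=n_mets)
    values = np.clip(base[None, :] + rng.uniform(-0.02, 0.02,
                                                 size=(n_drugs, n_mets)),
                     0.0, 0.2)
    values[:block_drugs, :block_mets] = rng.uniform(
        0.8, 0.9, size=(block_drugs, block_mets))
    return ml.SimilarityMatrix(
        drug_ids=[f"D{i:03d}" for i in range(n_drugs)],
        metabolite_ids=[f"M{j:03d}" for j in range(n_mets)],
        values=values,
        scheme="synthetic-test",
    )


@pytest.fixture
def block_matrix_factory():
    return planted_block_matrix
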