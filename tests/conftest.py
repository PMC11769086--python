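import numpy as np
import pandas as pd
import pytest

from lakehealth.data_model import OccurrenceMatrix
from lakehealth.synthetic_data import WorldSpec, generate_reference_world


def make_matrix(presence: np.ndarray, abundance: np.ndarray | None = None,
                phyla: list[str] | None = None) -> OccurrenceMatrix:
    """Build a small validated occurrence matrix with a generic taxonomy."""
    n_sites, n_taxa = presence.shape
    sites = [f"s{i + 1}" for i in range(n_sites)]
    taxa = [f"t{j + 1}" for j in range(n_taxa)]
    phyla = phyla or ["Mollusca"] * n_taxa
    taxonomy = pd.DataFrame(
        {"phylum": phyla, "subgroup": ["x"] * n_taxa},
        index=pd.Index(taxa, name="taxon_id"))
    pres = pd.DataFrame(presence.astype(int), index=sites, columns=taxa)
    ab = (pd.DataFrame(abundance.astype(float), index=sites, columns=taxa)
          if abundance is not None else None)
    return OccurrenceMatrix(pres, taxonomy, ab)


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    A = rng.random((n, n))
    D = (A + A.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


@pytest.fixture
def tiny_matrix() -> OccurrenceMatrix:
    presence = np.array([[1, 1, 0, 0],
                         [1, 0, 1, 0],
                         [0, 0, 0, 1]])
    abundance = np.array([[3, 5, 0, 0],
                          [1, 0, 2, 0],
                          [0, 0, 0, 7]])
    return make_matrix(presence, abundance,
                       phyla=["Mollusca", "Mollusca", "Annelida", "Arthropoda"])


@pytest.fixture(scope="session")
def reference_world():
    """The small fixture world: 3 planted groups x 5 reference sites, 40 taxa."""
    spec = WorldSpec(seed=1234)
    matrix, sites, labels = generate_reference_world(spec)
    return spec, matrix, sites, labels
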