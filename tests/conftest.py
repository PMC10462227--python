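import numpy as np
import pytest
import scipy.sparse as sp

from myelomap import SyntheticConfig, generate_cohort
from myelomap.types import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared by read-only tests (2/2/2 patients)."""
    cfg = SyntheticConfig(
        seed=7,
        n_patients_per_group=(2, 2, 2),
        cells_per_patient=150,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (12 patients x 400 cells)."""
    return generate_cohort(SyntheticConfig(seed=11))


def make_matrix(counts, modality="RNA", prefix="C", features=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    return ExpressionMatrix(
        sp.csr_matrix(counts),
        [f"{prefix}{i:04d}" for i in range(n)],
        features or [f"G{j:04d}" for j in range(m)],
        modality,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
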