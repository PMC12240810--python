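import numpy as np
import pytest
import scipy.sparse as sp

from loki import simdata
from loki.st_io import SpotMatrix


@pytest.fixture
def toy_matrix() -> SpotMatrix:
    """3 genes x 2 spots with simple integer counts."""
    counts = np.array([[1.0, 0.0], [2.0, 3.0], [0.0, 4.0]])
    return SpotMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=["ENSG_A", "ENSG_B", "ENSG_X"],
        barcodes=["bc1", "bc2"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def cohort() -> simdata.PairedCohort:
    """A default 200-spot, 4-type noiseless paired cohort (seed 7)."""
    return simdata.simulate_paired_cohort(simdata.CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort() -> simdata.PairedCohort:
    """A 60-spot cohort for quicker end-to-end tests."""
    return simdata.simulate_paired_cohort(
        simdata.CohortSpec(n_spots=60, n_genes=120, seed=13)
    )
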