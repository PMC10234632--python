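import numpy as np
import pytest

import popassoc as pa


@pytest.fixture(scope="session")
def admix_model_200():
    """Fitted 1D admixture model, n=200, K=10, FST=0.1, kinship ratio 0.5."""
    return pa.fit_admixture_model(200, 10, 0.1, 0.5)


@pytest.fixture(scope="session")
def admix_geno_200(admix_model_200):
    """One large genotype draw (m=50,000) from the fitted model."""
    G, freqs = pa.draw_admixture_genotypes(
        admix_model_200, 50_000, rng=np.random.default_rng(42)
    )
    return G, freqs


@pytest.fixture(scope="session")
def true_kinship_200(admix_model_200):
    """True total kinship of the admixture model: coancestry off-diagonal,
    (1 + f_j) / 2 on the diagonal."""
    theta = admix_model_200.coancestry()
    phi = theta.copy()
    np.fill_diagonal(phi, (1.0 + np.diag(theta)) / 2.0)
    return phi
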