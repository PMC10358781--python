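import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*FactorAnalysis did not converge.*")


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(20231104)


def random_lds_params(rng, q, p):
    from cilds.models import LDSParams

    return LDSParams(
        A=rng.standard_normal((q, p)),
        b=rng.standard_normal(q) * 0.3,
        R_diag=rng.uniform(0.1, 0.8, q),
        D_diag=rng.uniform(-0.5, 0.95, p),
        P_diag=rng.uniform(0.1, 1.0, p),
        h1=rng.standard_normal(p) * 0.5,
        G1_diag=rng.uniform(0.3, 1.0, p),
    )


def random_cilds_params(rng, q, p, gamma_range=(0.3, 0.95)):
    from cilds.models import CILDSParams

    return CILDSParams(
        B_diag=rng.uniform(0.5, 2.0, q),
        R_diag=rng.uniform(0.05, 0.5, q),
        Gamma_diag=rng.uniform(*gamma_range, q),
        A=rng.standard_normal((q, p)),
        b=rng.standard_normal(q) * 0.2,
        Q_diag=rng.uniform(0.05, 0.5, q),
        mu1=rng.standard_normal(q) * 0.5,
        V1_diag=rng.uniform(0.1, 1.0, q),
        D_diag=rng.uniform(-0.5, 0.95, p),
        P_diag=rng.uniform(0.1, 1.0, p),
        h2=rng.standard_normal(p) * 0.5,
        G2_diag=rng.uniform(0.2, 1.0, p),
    )
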