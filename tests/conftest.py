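import numpy as np
import pytest

from mlfdr.regress import CoefSummary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def draw_summary(
    rng,
    m=2000,
    pi=(0.4, 0.2, 0.2, 0.2),
    mu=2.0,
    psi=1.0,
    theta=-3.0,
    kappa=4.0,
    var1=1.0,
    var2=1.0,
    n=300,
):
    """Draw (a_i, b_i) directly from the bivariate mixture model.

    Returns (CoefSummary, xi) where xi is the m x 2 latent state array.
    Constant base variances by default; pass arrays for heteroscedastic ones.
    """
    cells = rng.choice(4, size=m, p=np.asarray(pi))
    xi1 = np.isin(cells, (1, 3)).astype(int)
    xi2 = np.isin(cells, (2, 3)).astype(int)
    v1 = np.broadcast_to(np.asarray(var1, dtype=float), (m,)).copy()
    v2 = np.broadcast_to(np.asarray(var2, dtype=float), (m,)).copy()
    a = np.sqrt(v1) * rng.standard_normal(m) + xi1 * (
        mu + np.sqrt(psi) * rng.standard_normal(m)
    )
    b = np.sqrt(v2) * rng.standard_normal(m) + xi2 * (
        theta + np.sqrt(kappa) * rng.standard_normal(m)
    )
    summary = CoefSummary(a=a, b=b, var1=v1, var2=v2, n=n)
    return summary, np.column_stack([xi1, xi2])


@pytest.fixture
def mixture_summary(rng):
    return draw_summary(rng)
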