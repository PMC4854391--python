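import numpy as np
import pytest

from sdqpsych.synthgen import make_population_spec, simulate_responses


@pytest.fixture(scope="session")
def no_dif_small():
    """Exactly invariant population at the scale where the delta-CFI rule
    is calibrated (its null noise shrinks like 1/n), no missingness."""
    spec = make_population_spec("no_dif", n_per_group=(2000, 2000),
                                missing_rate=0.0)
    return simulate_responses(spec, seed=11)


@pytest.fixture(scope="session")
def table2_small():
    """Published-parameter population at reduced n with default missingness."""
    spec = make_population_spec("table2_full", n_per_group=(1500, 1500))
    return simulate_responses(spec, seed=5)


def single_factor_table(rho: float, tau_r, tau_c, n: int, seed: int = 0):
    """3x3 contingency table from a latent bivariate normal pair."""
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = (z[:, 0] > tau_r[0]).astype(int) + (z[:, 0] > tau_r[1])
    y = (z[:, 1] > tau_c[0]).astype(int) + (z[:, 1] > tau_c[1])
    tab = np.zeros((3, 3))
    np.add.at(tab, (x, y), 1.0)
    return tab
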