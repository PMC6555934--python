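import numpy as np
import pytest

from nbreg import CEDataset


@pytest.fixture
def toy_ds() -> CEDataset:
    """Four patients, two per arm; dC = 50, dE = 0.5, ICER = 100 by hand."""
    return CEDataset.from_arrays(
        tx=[0, 0, 1, 1],
        cost=[50.0, 150.0, 100.0, 200.0],
        effect=[0.5, 1.5, 1.0, 2.0],
    )


def make_bivariate_normal(
    seed: int,
    n_per_arm: int = 400,
    delta_cost: float = 30_843.0,
    delta_effect: float = 0.1769,
    control_cost: float = 12_000.0,
    control_effect: float = 0.28,
    cost_sd: float = 9_000.0,
    effect_sd: float = 0.18,
    rho: float = 0.3,
) -> CEDataset:
    """Bivariate-normal cost/effect trial with known moments (oracle-friendly)."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    rows = []
    for arm in (0, 1):
        z = rng.standard_normal((n_per_arm, 2)) @ chol.T
        cost = control_cost + arm * delta_cost + cost_sd * z[:, 0]
        eff = control_effect + arm * delta_effect + effect_sd * z[:, 1]
        rows.append((np.full(n_per_arm, arm), cost, eff))
    tx = np.concatenate([r[0] for r in rows])
    cost = np.concatenate([r[1] for r in rows])
    eff = np.concatenate([r[2] for r in rows])
    return CEDataset.from_arrays(tx=tx, cost=cost, effect=eff, allow_negative_cost=True)


@pytest.fixture
def bivnorm_ds() -> CEDataset:
    return make_bivariate_normal(seed=11)
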