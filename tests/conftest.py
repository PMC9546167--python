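import numpy as np
import pytest

from vineflow import FlowHyper, ParametricCopulaSpec, PairCopulaFlow, copula_sample

# the six family/strength settings of the simulation design
SETTINGS = {
    "clayton-weak": ParametricCopulaSpec("clayton", theta=2.0),
    "clayton-strong": ParametricCopulaSpec("clayton", theta=5.0),
    "frank-weak": ParametricCopulaSpec("frank", theta=3.0),
    "frank-strong": ParametricCopulaSpec("frank", theta=7.0),
    "gaussian-weak": ParametricCopulaSpec("gaussian", rho=0.4),
    "gaussian-strong": ParametricCopulaSpec("gaussian", rho=0.8),
}

_FIT_SEEDS = {name: 1000 + i for i, name in enumerate(SETTINGS)}


@pytest.fixture(scope="session")
def fitted_six():
    """Bivariate spline flows fitted to 5000 ground-truth samples of each of
    the six family/strength settings (shared across tests; fitting is the
    expensive step)."""
    out = {}
    for name, spec in SETTINGS.items():
        data = copula_sample(spec, 5000, seed=_FIT_SEEDS[name])
        res = PairCopulaFlow(data).fit(
            hyper=FlowHyper(n_layers=2, hidden_units=32, n_bins=8, dim=2),
            seed=_FIT_SEEDS[name] + 1,
        )
        out[name] = (spec, res)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
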