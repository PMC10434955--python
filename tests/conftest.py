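import numpy as np
import pytest

from ntsg import LifetimeSample, load_survival_times
from ntsg.family import BaselineSpec


@pytest.fixture(scope="session")
def survival() -> LifetimeSample:
    """The bundled 128 published survival times."""
    return load_survival_times()


@pytest.fixture(scope="session")
def printed_fit():
    """Published parameter estimates of the amplified Weibull on that data."""
    return {"delta": 0.42771, "alpha": 0.88512, "lambda_": 1.02405}


@pytest.fixture()
def uniform_baseline() -> BaselineSpec:
    """Standard uniform baseline: lets tests dial the baseline CDF level directly."""
    return BaselineSpec(
        name="uniform",
        cdf=lambda t: np.clip(np.asarray(t, dtype=float), 0.0, 1.0),
        pdf=lambda t: np.where(
            (np.asarray(t, dtype=float) >= 0) & (np.asarray(t, dtype=float) <= 1), 1.0, 0.0
        ),
        quantile=lambda u: np.asarray(u, dtype=float),
        sf=lambda t: 1.0 - np.clip(np.asarray(t, dtype=float), 0.0, 1.0),
    )


@pytest.fixture()
def exponential_baseline() -> BaselineSpec:
    """Unit exponential baseline."""
    return BaselineSpec(
        name="exponential",
        cdf=lambda t: -np.expm1(-np.asarray(t, dtype=float)),
        pdf=lambda t: np.exp(-np.asarray(t, dtype=float)),
        quantile=lambda u: -np.log1p(-np.asarray(u, dtype=float)),
        sf=lambda t: np.exp(-np.asarray(t, dtype=float)),
    )
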