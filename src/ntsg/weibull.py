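"""The sine-amplified Weibull lifetime model and its competitor distributions.

The baseline is a Weibull in rate-scale form, ``G(t) = 1 - exp(-alpha t**delta)``
with shape ``delta > 0`` and rate-scale ``alpha > 0`` (units ``time**-delta``).
Amplifying it gives a three-parameter family whose hazard covers decreasing,
increasing, bathtub and decreasing-increasing-decreasing shapes.

The module also provides the five two/three-parameter competitor survival
models used for benchmarking fits on lifetime data: plain Weibull,
exponentiated Weibull, sine-Weibull, sine inverse-Weibull and the alpha-power
cosine Weibull.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

from .family import (
    LAMBDA_MIN,
    BaselineSpec,
    NtsParams,
    _check_lambda,
    nts_cdf,
    nts_chf,
    nts_hf,
    nts_pdf,
    nts_quantile,
    nts_sample,
    nts_sf,
    sine_cdf,
)

__all__ = [
    "NtsWeibullParams",
    "weibull_baseline",
    "ntsw_cdf",
    "ntsw_pdf",
    "ntsw_sf",
    "ntsw_hf",
    "ntsw_chf",
    "ntsw_quantile",
    "ntsw_sample",
    "CompetitorParams",
    "COMPETITOR_MODELS",
    "competitor_cdf",
    "competitor_pdf",
    "competitor_sf",
]


@dataclass(frozen=True)
class NtsWeibullParams:
    """Parameter triple (delta shape, alpha rate-scale, lambda amplification)."""

    delta: float
    alpha: float
    lambda_: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta) or self.delta <= 0.0:
            raise ValueError(f"Weibull shape delta must be positive; got {self.delta!r}")
        if not np.isfinite(self.alpha) or self.alpha <= 0.0:
            raise ValueError(f"Weibull rate-scale alpha must be positive; got {self.alpha!r}")
        _check_lambda(self.lambda_)

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.delta, self.alpha, self.lambda_)


def weibull_baseline(delta: float, alpha: float) -> BaselineSpec:
    """Weibull baseline in rate-scale form, with a closed-form survival."""
    if delta <= 0.0 or alpha <= 0.0:
        raise ValueError("Weibull parameters must be positive")

    def cdf(t):
        return -np.expm1(-alpha * np.power(t, delta))

    def sf(t):
        return np.exp(-alpha * np.power(t, delta))

    def pdf(t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = alpha * delta * np.power(t, delta - 1.0) * np.exp(-alpha * np.power(t, delta))
        return out

    def quantile(u):
        u = np.asarray(u, dtype=float)
        return np.power(-np.log1p(-u) / alpha, 1.0 / delta)

    return BaselineSpec(
        name="weibull",
        cdf=cdf,
        pdf=pdf,
        quantile=quantile,
        sf=sf,
        kappa={"delta": delta, "alpha": alpha},
        bounds={"delta": (1e-3, 50.0), "alpha": (1e-8, 1e3)},
    )


def _split(p: NtsWeibullParams) -> Tuple[NtsParams, BaselineSpec]:
    base = weibull_baseline(p.delta, p.alpha)
    return NtsParams(lambda_=p.lambda_, kappa=base.kappa), base


def _check_nonneg(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("lifetimes must be nonnegative")
    return t


def ntsw_cdf(t, p: NtsWeibullParams):
    params, base = _split(p)
    return nts_cdf(_check_nonneg(t), params, base)


def ntsw_pdf(t, p: NtsWeibullParams):
    params, base = _split(p)
    return nts_pdf(_check_nonneg(t), params, base)


def ntsw_sf(t, p: NtsWeibullParams):
    params, base = _split(p)
    return nts_sf(_check_nonneg(t), params, base)


def ntsw_hf(t, p: NtsWeibullParams):
    params, base = _split(p)
    return nts_hf(_check_nonneg(t), params, base)


def ntsw_chf(t, p: NtsWeibullParams):
    params, base = _split(p)
    return nts_chf(_check_nonneg(t), params, base)


def ntsw_quantile(u, p: NtsWeibullParams):
    """Closed-form inverse CDF

    ``t = ( -(1/alpha) log[1 - (2/pi) arcsin(lambda u / (lambda - 1 + u))] )**(1/delta)``.
    """
    params, base = _split(p)
    return nts_quantile(u, params, base)


def ntsw_sample(m: int, p: NtsWeibullParams, seed) -> np.ndarray:
    params, base = _split(p)
    return nts_sample(m, params, base, seed)


# ---------------------------------------------------------------------------
# Competitor survival models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompetitorParams:
    """A named competitor model with its parameter vector."""

    model: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        if self.model not in COMPETITOR_MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(COMPETITOR_MODELS)}"
            )
        spec = COMPETITOR_MODELS[self.model]
        missing = [k for k in spec.param_names if k not in self.values]
        if missing:
            raise ValueError(f"model {self.model!r} missing parameters {missing}")
        for k in spec.param_names:
            v = self.values[k]
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"parameter {k}={v!r} must be positive and finite")
        if self.model == "napc_weibull" and self.values["alpha1"] == 1.0:
            raise ValueError("alpha-power cosine Weibull requires alpha1 != 1")


@dataclass(frozen=True)
class CompetitorModel:
    name: str
    param_names: Tuple[str, ...]
    cdf: Callable[..., np.ndarray]
    pdf: Callable[..., np.ndarray]


def _wb(t, delta, alpha):
    """Weibull CDF/pdf pieces shared by the sine-type competitors."""
    t = np.asarray(t, dtype=float)
    at = alpha * np.power(t, delta)
    G = -np.expm1(-at)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = alpha * delta * np.power(t, delta - 1.0) * np.exp(-at)
    return G, g


def _weibull_cdf(t, delta, alpha):
    G, _ = _wb(t, delta, alpha)
    return G


def _weibull_pdf(t, delta, alpha):
    _, g = _wb(t, delta, alpha)
    return g


def _exp_weibull_cdf(t, delta, alpha, tau):
    G, _ = _wb(t, delta, alpha)
    return np.power(G, tau)


def _exp_weibull_pdf(t, delta, alpha, tau):
    G, g = _wb(t, delta, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = tau * g * np.power(G, tau - 1.0)
    return np.where(G > 0.0, out, 0.0)


def _sine_weibull_cdf(t, delta, alpha):
    G, _ = _wb(t, delta, alpha)
    return sine_cdf(G)


def _sine_weibull_pdf(t, delta, alpha):
    G, g = _wb(t, delta, alpha)
    return 0.5 * np.pi * g * np.cos(0.5 * np.pi * G)


def _sine_inv_weibull_cdf(t, delta, alpha):
    # inverse-Weibull baseline exp(-alpha t**-delta) under the sine transform
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        B = np.exp(-alpha * np.power(t, -delta))
    return sine_cdf(B)


def _sine_inv_weibull_pdf(t, delta, alpha):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.exp(-alpha * np.power(t, -delta))
        b = alpha * delta * np.power(t, -delta - 1.0) * B
    return 0.5 * np.pi * b * np.cos(0.5 * np.pi * B)


def _napc_weibull_cdf(t, delta, alpha, alpha1):
    # alpha-power cosine form: F = (alpha1**sin[(pi/2)G] - 1) / (alpha1 - 1)
    G, _ = _wb(t, delta, alpha)
    s = sine_cdf(G)
    return (np.power(alpha1, s) - 1.0) / (alpha1 - 1.0)


def _napc_weibull_pdf(t, delta, alpha, alpha1):
    G, g = _wb(t, delta, alpha)
    s = sine_cdf(G)
    return (
        np.log(alpha1)
        * np.power(alpha1, s)
        * 0.5
        * np.pi
        * np.cos(0.5 * np.pi * G)
        * g
        / (alpha1 - 1.0)
    )


COMPETITOR_MODELS: Dict[str, CompetitorModel] = {
    "weibull": CompetitorModel("weibull", ("delta", "alpha"), _weibull_cdf, _weibull_pdf),
    "exp_weibull": CompetitorModel(
        "exp_weibull", ("delta", "alpha", "tau"), _exp_weibull_cdf, _exp_weibull_pdf
    ),
    "sine_weibull": CompetitorModel(
        "sine_weibull", ("delta", "alpha"), _sine_weibull_cdf, _sine_weibull_pdf
    ),
    "sine_inv_weibull": CompetitorModel(
        "sine_inv_weibull", ("delta", "alpha"), _sine_inv_weibull_cdf, _sine_inv_weibull_pdf
    ),
    "napc_weibull": CompetitorModel(
        "napc_weibull", ("delta", "alpha", "alpha1"), _napc_weibull_cdf, _napc_weibull_pdf
    ),
}


def _competitor_args(c: CompetitorParams):
    spec = COMPETITOR_MODELS[c.model]
    return spec, [c.values[k] for k in spec.param_names]


def competitor_cdf(t, c: CompetitorParams):
    spec, args = _competitor_args(c)
    return spec.cdf(_check_nonneg(t), *args)


def competitor_pdf(t, c: CompetitorParams):
    spec, args = _competitor_args(c)
    return spec.pdf(_check_nonneg(t), *args)


def competitor_sf(t, c: CompetitorParams):
    """Survival of a named competitor model; value in [0, 1], nonincreasing."""
    return 1.0 - np.asarray(competitor_cdf(t, c), dtype=float)
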