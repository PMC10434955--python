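"""Goodness-of-fit statistics and fitted-model comparison for lifetime data.

Implements the three classical EDF criteria on order statistics
``t_(1) <= ... <= t_(n)`` with fitted CDF values ``u_i = G(t_(i))``:

* Cramer-von Mises:  ``sum_i [ (2i-1)/(2n) - u_i ]^2 + 1/(12n)``
* Anderson-Darling:  ``-n - (1/n) sum_i (2i-1) [ log u_i + log(1 - u_{n-i+1}) ]``
* Kolmogorov-Smirnov: two-sided sup distance
  ``max_i max( i/n - u_i , u_i - (i-1)/n )``

The KS p-value is the asymptotic Kolmogorov tail
``2 sum_{k>=1} (-1)^{k-1} exp(-2 k^2 n D^2)`` with no estimated-parameter
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .fitting import MODELS, FitResult, LifetimeSample, _as_values, fit_mle

__all__ = [
    "GofReport",
    "cvm_stat",
    "ad_stat",
    "ks_stat",
    "ks_pvalue",
    "gof_report",
    "compare_models",
    "plot_data",
]

_CDF_CLIP = 1e-15


@dataclass(frozen=True)
class GofReport:
    """EDF goodness-of-fit criteria for one fitted model."""

    model: str
    cvm: float
    ad: float
    ks: float
    ks_pvalue: float


def _fitted_u(data, fitted_cdf) -> np.ndarray:
    x = np.sort(_as_values(data), kind="stable")
    u = np.asarray(fitted_cdf(x), dtype=float)
    if np.any(~np.isfinite(u)):
        raise ValueError("fitted CDF produced non-finite values at the data")
    return u


def cvm_stat(data, fitted_cdf) -> float:
    """Cramer-von Mises criterion of ``fitted_cdf`` against the sample EDF."""
    u = _fitted_u(data, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    return float(np.sum(((2 * i - 1) / (2 * n) - u) ** 2) + 1.0 / (12 * n))


def ad_stat(data, fitted_cdf) -> float:
    """Anderson-Darling criterion; CDF values are clipped away from {0, 1}."""
    u = _fitted_u(data, fitted_cdf)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn(
            "fitted CDF hit 0 or 1 at a data point; clipping for the AD statistic",
            stacklevel=2,
        )
    u = np.clip(u, _CDF_CLIP, 1.0 - _CDF_CLIP)
    n = u.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1.0 - u[::-1]))))


def ks_stat(data, fitted_cdf) -> float:
    """Two-sided Kolmogorov-Smirnov sup distance."""
    u = _fitted_u(data, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))


def ks_pvalue(ks: float, n: int) -> float:
    """Asymptotic Kolmogorov p-value for a sup distance ``ks`` at sample size ``n``."""
    if not (0.0 <= ks <= 1.0):
        raise ValueError("KS statistic must lie in [0, 1]")
    if ks == 0.0:
        return 1.0
    return float(np.clip(kolmogorov(np.sqrt(n) * ks), 0.0, 1.0))


def gof_report(data, fitted_cdf, model: str = "") -> GofReport:
    """All three criteria plus the KS p-value for one fitted CDF."""
    n = _as_values(data).size
    ks = ks_stat(data, fitted_cdf)
    return GofReport(
        model=model,
        cvm=cvm_stat(data, fitted_cdf),
        ad=ad_stat(data, fitted_cdf),
        ks=ks,
        ks_pvalue=ks_pvalue(ks, n),
    )


def compare_models(
    data,
    models: Sequence[str],
    seed: Optional[int] = None,
) -> List[Tuple[FitResult, Optional[GofReport]]]:
    """Fit every model in ``models`` and score each with all three criteria.

    Individual model failures are recorded (``GofReport`` of ``None``) and the
    comparison proceeds with the remaining candidates.
    """
    if len(models) < 2:
        raise ValueError("model comparison needs at least 2 candidates")
    out: List[Tuple[FitResult, Optional[GofReport]]] = []
    for name in models:
        if name not in MODELS:
            raise ValueError(f"unknown model {name!r}; choose from {sorted(MODELS)}")
        fit = fit_mle(data, model=name, seed=seed)
        if not np.isfinite(fit.loglik):
            out.append((fit, None))
            continue
        out.append((fit, gof_report(data, fit.cdf, model=name)))
    return out


def comparison_table(results: Sequence[Tuple[FitResult, Optional[GofReport]]]) -> pd.DataFrame:
    """Tabulate a ``compare_models`` result with per-criterion ranks."""
    rows = []
    for fit, rep in results:
        row = {"model": fit.model, "loglik": fit.loglik, "converged": fit.converged}
        row.update({f"param_{k}": v for k, v in fit.estimates.items()})
        if rep is not None:
            row.update(cvm=rep.cvm, ad=rep.ad, ks=rep.ks, ks_pvalue=rep.ks_pvalue)
        rows.append(row)
    df = pd.DataFrame(rows)
    for crit, ascending in (("cvm", True), ("ad", True), ("ks", True), ("ks_pvalue", False)):
        if crit in df:
            df[f"rank_{crit}"] = df[crit].rank(ascending=ascending, method="min")
    return df


def plot_data(data, fitted_cdf) -> pd.DataFrame:
    """Point sets for fitted-CDF overlay, PP and QQ displays, as a tidy frame."""
    x = np.sort(_as_values(data), kind="stable")
    n = x.size
    i = np.arange(1, n + 1)
    ecdf = i / n
    u = np.asarray(fitted_cdf(x), dtype=float)
    return pd.DataFrame(
        {
            "time": x,
            "ecdf": ecdf,
            "fitted_cdf": u,
            "pp_theoretical": u,
            "pp_empirical": (i - 0.5) / n,
        }
    )
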