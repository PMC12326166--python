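"""Lognormal fits and population summaries for vesicle size (and sigma) data.

Vesicle diameters within a sample are well described by a lognormal law, so a
sample is fitted by the moments of its natural logarithm: ``mu = mean(ln d)``,
``s = SD(ln d)`` (n-1 denominator, matching the downstream t/F tests).  The
fit is the Gaussian MLE on the log scale up to the n vs n-1 choice, and its
median ``exp(mu)`` equals the geometric mean of the data.

Derived descriptors follow the standard lognormal closed forms:

* median  ``exp(mu)``
* mode    ``exp(mu - s^2)``  (the histogram peak)
* q-quantile ``exp(mu + z_q s)`` with standard-normal ``z_q``

The total apparent membrane area of a sample is accounted as the sum of
per-vesicle spherical surface areas ``sum 4 pi (d_i/2)^2`` over the raw data
(not the fit), so it is additive across merged tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["LognormalFit", "SampleSummary", "fit_lognormal", "summarize", "surface_ratio"]

_Z95 = float(norm.ppf(0.95))  # 1.6449 — 5th/95th percentile band


@dataclass(frozen=True)
class LognormalFit:
    """Log-scale moments of a positive sample: ``mu = mean(ln x)``, ``s = SD(ln x)``."""

    mu: float
    s: float
    n: int

    def __post_init__(self) -> None:
        if self.s < 0.0:
            raise ValueError(f"log-SD must be non-negative, got {self.s}")
        if self.n < 2 and self.s > 0.0:
            raise ValueError("a fit with nonzero spread needs n >= 2")


@dataclass(frozen=True)
class SampleSummary:
    """Descriptive summary of one sample under its lognormal fit."""

    fit: LognormalFit
    median: float
    mode: float
    p05: float
    p95: float
    count: int
    total_surface: float


def fit_lognormal(values) -> LognormalFit:
    """Fit a lognormal by log-moments.

    Parameters
    ----------
    values : array-like of float
        Strictly positive observations, n >= 2.

    Raises
    ------
    ValueError
        Non-positive entries (the error lists their indices) or n < 2.
    """
    x = np.asarray(values, dtype=float).ravel()
    bad = np.flatnonzero(~(x > 0.0))
    if bad.size:
        raise ValueError(f"values must be positive; offending indices: {bad.tolist()}")
    if x.size < 2:
        raise ValueError(f"need at least 2 values to fit, got {x.size}")
    logs = np.log(x)
    return LognormalFit(mu=float(logs.mean()), s=float(logs.std(ddof=1)), n=int(x.size))


def summarize(fit: LognormalFit, values) -> SampleSummary:
    """Population summary: median, mode, 5th-95th band, and total surface area.

    The quantile band is that of the *fitted* lognormal (standard-normal
    z-values: the band describes the population, not an estimator), while the
    total surface area ``sum 4 pi (d_i/2)^2`` is computed from the raw values
    so that it stays additive when tables are merged.
    """
    x = np.asarray(values, dtype=float).ravel()
    return SampleSummary(
        fit=fit,
        median=float(np.exp(fit.mu)),
        mode=float(np.exp(fit.mu - fit.s**2)),
        p05=float(np.exp(fit.mu - _Z95 * fit.s)),
        p95=float(np.exp(fit.mu + _Z95 * fit.s)),
        count=int(x.size),
        total_surface=float(np.sum(np.pi * x**2)),
    )


def surface_ratio(summary_on: SampleSummary, summary_t0: SampleSummary) -> float:
    """Overnight-to-pristine total-surface-area ratio, in percent.

    ``100 * A_s(overnight) / A_s(t0)`` — the stability figure of merit: 100%
    means the total apparent membrane area of the observed population was
    conserved overnight.
    """
    if summary_t0.total_surface == 0.0:
        raise ValueError("t0 total surface is zero; ratio undefined")
    return 100.0 * summary_on.total_surface / summary_t0.total_surface
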