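"""Log-scale two-sample inference and minimum-detectable-ratio power analysis.

Diameters and surface-area deformations are treated as lognormal, so all
significance testing happens on the natural logarithm of the data, where the
values are normal: a two-sample t-test on log-data compares group medians
(geometric means) via their ratio, and an F-test on log-data compares the
multiplicative spreads.

Significance is reported against a strict default alpha of 0.005.  The power
side of the same framework gives the minimum detectable ratio (MDR): the
smallest true ratio of group medians that the log-scale t-test would flag at
a target power, using the classic t-approximation

    MDR = exp( (t_{1-alpha/2, df} + t_{power, df}) * s_log * sqrt(1/n1 + 1/n2) )

with df = n1 + n2 - 2.  Power analysis conventionally uses alpha = 0.05
(two-sided) regardless of the stricter reporting threshold; both are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "LogTestResult",
    "PowerSpec",
    "log_t_test",
    "log_f_test",
    "minimum_detectable_ratio",
    "DEFAULT_ALPHA",
]

#: significance threshold used for reporting throughout
DEFAULT_ALPHA = 0.005


@dataclass(frozen=True)
class LogTestResult:
    """Outcome of a two-sample test on log-transformed data.

    ``degenerate`` flags zero-variance situations where the sampling
    distribution collapses (p is then 0, 1 or NaN by limiting argument
    rather than by quadrature).
    """

    statistic: float
    df: float
    p_value: float
    test: str  # "t-pooled" | "t-welch" | "F"
    groups: tuple[str, str]
    significant: bool
    alpha: float
    n: tuple[int, int]
    degenerate: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the MDR computation for a log-scale two-sample t-test."""

    n1: int
    n2: int
    s_log: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n >= 2 per group")
        if self.s_log < 0.0:
            raise ValueError("s_log must be non-negative")


def _validated_logs(x, y) -> tuple[np.ndarray, np.ndarray]:
    ax = np.asarray(x, dtype=float).ravel()
    ay = np.asarray(y, dtype=float).ravel()
    for name, arr in (("x", ax), ("y", ay)):
        if np.any(~(arr > 0.0)):
            raise ValueError(f"{name} must be strictly positive for a log-scale test")
        if arr.size < 2:
            raise ValueError(f"{name} needs at least 2 observations")
    return np.log(ax), np.log(ay)


def log_t_test(
    x,
    y,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
    groups: tuple[str, str] = ("x", "y"),
) -> LogTestResult:
    """Two-sample t-test on ln(x) vs ln(y); two-sided p.

    ``variant="pooled"`` is the classical Student test (the default,
    pairing naturally with the F-test on the same data); ``"welch"`` drops
    the equal-variance assumption (Welch-Satterthwaite df).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    lx, ly = _validated_logs(x, y)
    n1, n2 = lx.size, ly.size
    v1, v2 = lx.var(ddof=1), ly.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        # degenerate: all mass at one point per group
        same = lx.mean() == ly.mean()
        df = float(n1 + n2 - 2) if variant == "pooled" else float("nan")
        return LogTestResult(
            statistic=0.0 if same else float("inf"),
            df=df,
            p_value=1.0 if same else 0.0,
            test=f"t-{variant}",
            groups=groups,
            significant=not same,
            alpha=alpha,
            n=(n1, n2),
            degenerate=True,
        )
    res = sps.ttest_ind(lx, ly, equal_var=(variant == "pooled"))
    stat, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    return LogTestResult(
        statistic=stat,
        df=df,
        p_value=p,
        test=f"t-{variant}",
        groups=groups,
        significant=bool(p < alpha),
        alpha=alpha,
        n=(n1, n2),
    )


def log_f_test(
    x, y, alpha: float = DEFAULT_ALPHA, groups: tuple[str, str] = ("x", "y")
) -> LogTestResult:
    """F-test of equal variances on ln(x) vs ln(y).

    ``F = var(ln x) / var(ln y)`` with (n1-1, n2-1) df; two-sided p as twice
    the smaller tail (capped at 1), so ``p(x, y) == p(y, x)``.
    """
    lx, ly = _validated_logs(x, y)
    n1, n2 = lx.size, ly.size
    v1, v2 = lx.var(ddof=1), ly.var(ddof=1)
    if v2 == 0.0 or v1 == 0.0:
        return LogTestResult(
            statistic=float("inf") if v2 == 0.0 and v1 > 0.0 else float("nan"),
            df=float(n1 - 1),
            p_value=float("nan"),
            test="F",
            groups=groups,
            significant=False,
            alpha=alpha,
            n=(n1, n2),
            degenerate=True,
        )
    f = float(v1 / v2)
    cdf = sps.f.cdf(f, n1 - 1, n2 - 1)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return LogTestResult(
        statistic=f,
        df=float(n1 - 1),  # numerator df; denominator df is n2 - 1
        p_value=p,
        test="F",
        groups=groups,
        significant=bool(p < alpha),
        alpha=alpha,
        n=(n1, n2),
    )


def minimum_detectable_ratio(spec: PowerSpec) -> float:
    """Smallest detectable true median ratio of two lognormal groups.

    At the spec's group sizes and pooled log-scale SD, returns the ratio
    ``exp(delta)`` whose log-scale t-test reaches the target power at the
    two-sided alpha, via the t-quantile approximation (df = n1 + n2 - 2).
    Always >= 1; equals 1 when ``s_log == 0``.
    """
    df = spec.n1 + spec.n2 - 2
    t_alpha = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    t_power = sps.t.ppf(spec.power, df)
    delta = (t_alpha + t_power) * spec.s_log * np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
    return float(np.exp(delta))


def pooled_log_sd(x, y) -> float:
    """Pooled SD of the natural logs of two positive samples (df-weighted)."""
    lx, ly = _validated_logs(x, y)
    n1, n2 = lx.size, ly.size
    v = ((n1 - 1) * lx.var(ddof=1) + (n2 - 1) * ly.var(ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(v))
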