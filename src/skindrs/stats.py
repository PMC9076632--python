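"""Correlation and group-comparison statistics.

Implements Pearson correlation with the p-value of the test against the
no-correlation model y = constant, the Fisher r-to-z transformation, the
normal-theory comparison of two correlation coefficients, and the pooled
two-sample Student's t-test.

The Fisher comparison uses the independent-samples standard error
sqrt(1/(n1-3) + 1/(n2-3)) and a standard-normal reference for the one-tailed
p-value; negative coefficients can be compared by magnitude via an explicit
flag (useful when both correlations are negative and the question is which
is the stronger association).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "TTestResult",
    "pearson_with_p",
    "fisher_z",
    "compare_correlations",
    "two_sample_ttest",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with the two-sided p for slope != 0 (t, n-2 df)."""

    r: float
    n: int
    p_value: float


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher comparison; z1 is the larger of the two transformed values."""

    z1: float
    z2: float
    z_stat: float
    p_one_tailed: float
    p_two_tailed: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    degenerate: bool = False


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson product-moment correlation and its significance.

    The p-value comes from t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of
    freedom (two-sided), which is exactly the test of the fitted straight
    line against the constant model. Perfectly collinear data give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p_value=p)


def fisher_z(r: float) -> float:
    """Fisher transformation z = arctanh(r) = 0.5 ln((1+r)/(1-r))."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def compare_correlations(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    tail: str = "one",
    use_magnitudes: bool = False,
) -> CorrelationComparison:
    """Test whether two independent Pearson coefficients differ.

    z_stat = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) with z1 the larger Fisher
    transform, so z_stat >= 0 and the one-tailed p = 1 - Phi(z_stat) is at
    most 0.5 (equal coefficients give exactly 0.5). With ``use_magnitudes``
    the absolute values are compared, which is the relevant question when
    both correlations share a sign.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in each sample (variance undefined)")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if use_magnitudes:
        r1, r2 = abs(r1), abs(r2)
    za, zb = fisher_z(r1), fisher_z(r2)
    if abs(zb) > abs(za):
        za, zb = zb, za
        n1, n2 = n2, n1
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (za - zb) / se
    p_one = float(sps.norm.sf(z_stat))
    return CorrelationComparison(
        z1=za, z2=zb, z_stat=float(z_stat), p_one_tailed=p_one,
        p_two_tailed=min(1.0, 2.0 * p_one),
    )


def two_sample_ttest(a, b, tails: str = "two", paired: bool = False) -> TTestResult:
    """Student's t-test, pooled-variance unpaired by default.

    Degenerate zero-variance inputs are resolved by convention: equal means
    give p = 1, unequal means p = 0, both flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal lengths")
        d = a - b
        n = len(d)
        if n < 2:
            raise ValueError("need >= 2 pairs")
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0:
            return _degenerate(d.mean(), df)
        t = d.mean() / (sd / np.sqrt(n))
    else:
        n1, n2 = len(a), len(b)
        if n1 < 2 or n2 < 2:
            raise ValueError("each series needs length >= 2")
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            return _degenerate(a.mean() - b.mean(), df)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(sps.t.sf(abs(t), df))
    if tails == "two":
        p = min(1.0, 2.0 * p)
    return TTestResult(t=float(t), df=df, p_value=p)


def _degenerate(mean_diff: float, df: int) -> TTestResult:
    if mean_diff == 0:
        return TTestResult(t=0.0, df=df, p_value=1.0, degenerate=True)
    return TTestResult(
        t=np.inf if mean_diff > 0 else -np.inf, df=df, p_value=0.0, degenerate=True
    )
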