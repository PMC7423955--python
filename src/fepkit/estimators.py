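"""Free-energy estimators for per-window work samples.

Implements the one-sided Zwanzig (exponential-averaging) estimator, the
two-sided Bennett acceptance ratio (BAR), autocorrelation-based
subsampling to effectively independent samples, and accumulation of
per-window estimates into a leg total with root-sum-square uncertainty.

Conventions
-----------
Forward work w_F is the energy difference U(B) - U(A) evaluated on
configurations sampled in the low-lambda state A; reverse work w_R is
U(A) - U(B) sampled in the high-lambda state B. All estimates are the
A -> B free-energy difference in kcal/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import kt
from .synthetic import WindowSamples

__all__ = [
    "FreeEnergyEstimate",
    "DecorrelationResult",
    "zwanzig",
    "bar",
    "statistical_inefficiency",
    "subsample",
    "estimate_window",
    "accumulate",
]

Method = Literal["zwanzig_forward", "zwanzig_reverse", "bar"]


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with its standard error (kcal/mol)."""

    value: float
    stderr: float
    method: str
    n_effective_forward: int = 0
    n_effective_reverse: int = 0

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")

    def __str__(self) -> str:
        return f"{self.value:+.4f} ± {self.stderr:.4f} kcal/mol ({self.method})"


@dataclass(frozen=True)
class DecorrelationResult:
    """Statistical inefficiency g and the indices of retained samples.

    g = 1 + 2 * (integrated autocorrelation time); thinning a correlated
    series by ceil(g) yields effectively independent samples.
    """

    g: float
    retained_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("statistical inefficiency must be >= 1")


def _as_array(samples: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def zwanzig(dU: Sequence[float] | np.ndarray, temperature: float) -> FreeEnergyEstimate:
    """One-sided exponential-averaging free-energy estimate.

    dG = -kT ln < exp(-dU / kT) >, evaluated through a log-sum-exp so
    that large work values cannot overflow. The standard error follows
    from first-order propagation of the sample variance of the
    exponential through the logarithm.
    """
    w = _as_array(dU, "dU")
    kT = kt(temperature)
    n = w.size
    if np.ptp(w) == 0.0:
        # constant work: the estimator is exact with zero variance
        return FreeEnergyEstimate(float(w[0]), 0.0, "zwanzig_forward", n, 0)
    log_mean = logsumexp(-w / kT) - math.log(n)
    value = -kT * log_mean
    # sample variance of x = exp(-w/kT) relative to its mean, shift-stable
    x = np.exp(-w / kT - logsumexp(-w / kT) + math.log(n))  # x_i / mean(x)
    rel_var = np.var(x, ddof=1)
    stderr = kT * math.sqrt(rel_var / n)
    return FreeEnergyEstimate(value, stderr, "zwanzig_forward", n, 0)


def _bar_objective(dg: float, w_f: np.ndarray, w_r: np.ndarray, beta: float, M: float) -> float:
    # Fermi-weighted counts; increasing in dg
    with np.errstate(over="ignore"):
        lhs = np.sum(1.0 / (1.0 + np.exp(M + beta * (w_f - dg))))
        rhs = np.sum(1.0 / (1.0 + np.exp(-M + beta * (w_r + dg))))
    return lhs - rhs


def bar(
    forward_w: Sequence[float] | np.ndarray,
    reverse_w: Sequence[float] | np.ndarray,
    temperature: float,
    tolerance: float = 1e-8,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate from two-sided work samples.

    Solves the self-consistent Bennett equation

        sum_i f(M + beta (w_F,i - dG)) = sum_j f(-M + beta (w_R,j + dG))

    with f the Fermi function and M = ln(n_F / n_R), by bracketed root
    finding on the monotone objective to ``tolerance`` (kcal/mol). The
    bracket is seeded from the two one-sided Zwanzig estimates widened by
    50 kT. The standard error is the maximum-likelihood asymptotic
    variance evaluated over the pooled work samples.

    BAR is the minimum-variance combination of forward and reverse data;
    the result always lies between the forward-Zwanzig and negated
    reverse-Zwanzig estimates.
    """
    w_f = _as_array(forward_w, "forward_w")
    w_r = _as_array(reverse_w, "reverse_w")
    kT = kt(temperature)
    beta = 1.0 / kT
    n_f, n_r = w_f.size, w_r.size
    M = math.log(n_f / n_r)

    if np.ptp(w_f) == 0.0 and np.ptp(w_r) == 0.0 and math.isclose(w_f[0], -w_r[0]):
        # degenerate constant-work window: answer is exact
        return FreeEnergyEstimate(float(w_f[0]), 0.0, "bar", n_f, n_r)

    dg_f = zwanzig(w_f, temperature).value
    dg_r = -zwanzig(w_r, temperature).value
    lo = min(dg_f, dg_r) - 50.0 * kT
    hi = max(dg_f, dg_r) + 50.0 * kT
    f_lo = _bar_objective(lo, w_f, w_r, beta, M)
    f_hi = _bar_objective(hi, w_f, w_r, beta, M)
    if f_lo == 0.0:
        value = lo
    elif f_hi == 0.0:
        value = hi
    elif f_lo * f_hi > 0:
        raise ValueError(
            "Bennett equation admits no root in the bracket "
            f"[{lo:.3f}, {hi:.3f}] kcal/mol; forward/reverse work "
            "distributions do not overlap"
        )
    else:
        value = brentq(
            _bar_objective, lo, hi, args=(w_f, w_r, beta, M), xtol=tolerance
        )

    # asymptotic (maximum-likelihood) variance over the pooled works
    pooled = np.concatenate([w_f, -w_r])
    x = M + beta * (pooled - value)
    with np.errstate(over="ignore"):
        weights = 1.0 / (2.0 + 2.0 * np.cosh(np.clip(x, -700, 700)))
    s = weights.sum()
    var = (1.0 / s - (1.0 / n_f + 1.0 / n_r)) / beta**2 if s > 0 else math.inf
    if not math.isfinite(var) or var > 1e12:
        # every pooled work sits far from the crossover: the two
        # directions share no statistical overlap at all
        raise ValueError(
            "forward and reverse work distributions do not overlap; "
            "BAR variance is undefined"
        )
    stderr = math.sqrt(max(var, 0.0))
    return FreeEnergyEstimate(float(value), stderr, "bar", n_f, n_r)


def statistical_inefficiency(series: Sequence[float] | np.ndarray) -> DecorrelationResult:
    """Statistical inefficiency of a scalar time series.

    g = 1 + 2 * sum_t C(t), with the normalized autocorrelation sum
    truncated at its first non-positive value, clamped to [1, n].
    Retained indices run from 0 with spacing ceil(g). A constant series
    carries no information; it yields g = n with a warning.
    """
    x = _as_array(series, "series")
    n = x.size
    if n < 2:
        raise ValueError("series must have length >= 2")
    var = np.var(x)
    if var == 0.0:
        warnings.warn("constant series: statistical inefficiency set to series length")
        g = float(n)
    else:
        xc = x - x.mean()
        g = 1.0
        for lag in range(1, n):
            c = np.dot(xc[:-lag], xc[lag:]) / ((n - lag) * var)
            if c <= 0.0:
                break
            g += 2.0 * c
        g = float(min(max(g, 1.0), n))
    stride = math.ceil(g)
    return DecorrelationResult(g=g, retained_indices=np.arange(0, n, stride))


def subsample(series: np.ndarray) -> tuple[np.ndarray, DecorrelationResult]:
    """Thin a series to effectively independent samples."""
    res = statistical_inefficiency(series)
    return np.asarray(series, dtype=float)[res.retained_indices], res


def estimate_window(
    samples: WindowSamples,
    method: Method = "bar",
    decorrelate: bool = True,
    tolerance: float = 1e-8,
) -> FreeEnergyEstimate:
    """Free-energy estimate for one lambda window.

    Each direction is subsampled independently (when ``decorrelate``)
    before the chosen estimator runs; effective sample counts are
    recorded on the estimate.
    """
    fwd = samples.forward_dU
    rev = samples.reverse_dU
    if decorrelate:
        if fwd.size >= 2:
            fwd, _ = subsample(fwd)
        if rev.size >= 2:
            rev, _ = subsample(rev)
    T = samples.temperature
    if method == "bar":
        try:
            return bar(fwd, rev, T, tolerance=tolerance)
        except ValueError as err:
            raise ValueError(f"window {samples.label}: {err}") from err
    if method == "zwanzig_forward":
        est = zwanzig(fwd, T)
        return FreeEnergyEstimate(est.value, est.stderr, "zwanzig_forward", fwd.size, 0)
    if method == "zwanzig_reverse":
        est = zwanzig(rev, T)
        return FreeEnergyEstimate(-est.value, est.stderr, "zwanzig_reverse", 0, rev.size)
    raise ValueError(f"unknown method {method!r}")


def accumulate(estimates: Iterable[FreeEnergyEstimate]) -> FreeEnergyEstimate:
    """Sum per-window estimates into a leg total.

    Windows are treated as statistically independent, so the total
    standard error is the root sum square of the per-window errors.
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("cannot accumulate an empty sequence of estimates")
    value = sum(e.value for e in ests)
    stderr = math.sqrt(sum(e.stderr**2 for e in ests))
    return FreeEnergyEstimate(
        value,
        stderr,
        ests[0].method,
        sum(e.n_effective_forward for e in ests),
        sum(e.n_effective_reverse for e in ests),
    )


def estimate_leg(
    windows: Sequence[WindowSamples],
    method: Method = "bar",
    decorrelate: bool = True,
) -> FreeEnergyEstimate:
    """Convenience: estimate every window and accumulate the leg total."""
    return accumulate(estimate_window(w, method=method, decorrelate=decorrelate) for w in windows)
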