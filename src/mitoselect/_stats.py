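"""Small resampling-statistics kernel shared by the estimator modules.

Ordinary least squares in closed form, percentile bootstrap and permutation
machinery are implemented here directly (vectorized over resamples) so the
core inferences carry no statistics-package dependence and remain exactly
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .exceptions import EstimationError


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares intercept and slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise EstimationError("need at least 2 points to fit a line")
    vx = np.var(x)
    if vx == 0.0:
        raise EstimationError("degenerate design: regressor is constant")
    slope = np.cov(x, y, bias=True)[0, 1] / vx
    return float(np.mean(y) - slope * np.mean(x)), float(slope)


def _line_from_moments(sx, sy, sxx, sxy, n):
    """Vectorized closed-form line fit from per-sample moment sums."""
    mx, my = sx / n, sy / n
    vx = sxx / n - mx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sxy / n - mx * my) / vx
    return my - slope * mx, slope


def bootstrap_lines(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Case-resampling bootstrap of a line fit; returns (intercepts, slopes)."""
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    return _line_from_moments(
        xb.sum(1), yb.sum(1), (xb * xb).sum(1), (xb * yb).sum(1), n
    )


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval, ignoring non-finite resamples."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        return (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def signflip_pvalue(
    diffs: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided sign-flip permutation p-value for a mean of paired diffs.

    Exact-zero differences are flipped like any other value (no tie
    dropping).
    """
    diffs = np.asarray(diffs, dtype=float)
    observed = abs(diffs.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = np.abs((signs * diffs).mean(axis=1))
    return float((1 + np.sum(null >= observed - 1e-15)) / (n_perm + 1))


def label_permutation_line_diffs(
    x_a, y_a, x_b, y_b, n_perm: int, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Permutation comparison of two line fits (a permutation ANCOVA).

    Returns (intercept difference, slope difference, p_intercept, p_slope),
    with the null built by reshuffling condition labels across the pooled
    observations and refitting both groups; p-values are two-sided.
    """
    x_a = np.asarray(x_a, float); y_a = np.asarray(y_a, float)
    x_b = np.asarray(x_b, float); y_b = np.asarray(y_b, float)
    a0_a, b_a = ols_line(x_a, y_a)
    a0_b, b_b = ols_line(x_b, y_b)
    d_int, d_slope = a0_a - a0_b, b_a - b_b

    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    n, n_a = x.size, x_a.size
    # membership matrix for group A across permutations
    member = np.zeros((n_perm, n), dtype=bool)
    for r in range(n_perm):
        member[r, rng.permutation(n)[:n_a]] = True
    ma = member.astype(float)
    mb = 1.0 - ma
    int_a, slope_a = _line_from_moments(
        ma @ x, ma @ y, ma @ (x * x), ma @ (x * y), n_a)
    int_b, slope_b = _line_from_moments(
        mb @ x, mb @ y, mb @ (x * x), mb @ (x * y), n - n_a)
    null_int = int_a - int_b
    null_slope = slope_a - slope_b
    p_int = float((1 + np.sum(np.abs(null_int) >= abs(d_int) - 1e-15)) / (n_perm + 1))
    p_slope = float((1 + np.sum(np.abs(null_slope) >= abs(d_slope) - 1e-15)) / (n_perm + 1))
    return d_int, d_slope, p_int, p_slope
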