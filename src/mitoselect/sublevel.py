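"""Sub-organismal (within-host) selection estimators.

Lineage-isolation tables record, for each parent maintained free of
between-host competition, the pooled progeny frequency at three
developmental stages. The headline statistic is the per-generation shift
``delta_f = adult_f - parent_f`` (adult progeny are age-matched to the
parent), regressed on parental frequency:

    delta_f = a + b * parent_f

A negative slope ``b`` is negative frequency-dependent selection; the
x-intercept ``f* = -a/b`` is the within-host equilibrium frequency at which
the mutant's proliferation advantage is exhausted. Confidence intervals come
from a percentile bootstrap resampling whole lineages; stage contrasts and
between-condition regression comparisons use seeded sign-flip and
label-permutation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import (
    bootstrap_lines,
    label_permutation_line_diffs,
    ols_line,
    percentile_ci,
    signflip_pvalue,
)
from .exceptions import EstimationError, ParameterError

__all__ = [
    "ShiftFit",
    "StageContrast",
    "FitComparison",
    "per_generation_shift",
    "fit_shift_function",
    "stage_contrast",
    "compare_shift_fits",
]

logger = logging.getLogger(__name__)

_STAGE_COLUMNS = {
    "parent": "parent_f",
    "embryo": "embryo_f",
    "l4": "l4_f",
    "adult": "adult_f",
}


@dataclass(frozen=True)
class ShiftFit:
    """Fitted within-host shift function and its equilibrium."""

    a_hat: float
    b_hat: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    f_star: float | None
    ci_f_star: tuple[float, float] | None
    n: int


@dataclass(frozen=True)
class StageContrast:
    """Paired within-lineage stage difference with a sign-flip p-value."""

    mean_diff: float
    p_value: float
    n: int
    small_sample: bool = False


@dataclass(frozen=True)
class FitComparison:
    """Coefficient differences between two shift fits, with permutation p."""

    d_intercept: float
    d_slope: float
    p_intercept: float
    p_slope: float


def per_generation_shift(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage (parent_f, delta_f) pairs, delta_f = adult_f - parent_f.

    Pairing is strictly within-lineage; rows with a missing adult value are
    skipped with a logged warning.
    """
    if len(table) == 0:
        raise ParameterError("lineage table is empty")
    missing = table["adult_f"].isna()
    if missing.any():
        logger.warning(
            "skipping %d lineage(s) with missing adult_f: rows %s",
            int(missing.sum()), list(table.index[missing]),
        )
    kept = table.loc[~missing]
    return pd.DataFrame(
        {"parent_f": kept["parent_f"].to_numpy(float),
         "delta_f": kept["adult_f"].to_numpy(float) - kept["parent_f"].to_numpy(float)}
    )


def fit_shift_function(pairs: pd.DataFrame, n_boot: int = 2000, seed=0) -> ShiftFit:
    """OLS of delta_f on parent_f with a lineage-resampling bootstrap.

    The within-host equilibrium ``f* = -a/b`` is reported when the fitted
    slope is negative; its interval collects ``f*`` over bootstrap resamples
    with negative slope.
    """
    x = np.asarray(pairs["parent_f"], dtype=float)
    y = np.asarray(pairs["delta_f"], dtype=float)
    if x.size < 3:
        raise EstimationError("need at least 3 lineages to fit the shift function")
    if np.all(x == x[0]):
        raise EstimationError("degenerate design: all parental frequencies identical")
    a_hat, b_hat = ols_line(x, y)
    rng = np.random.default_rng(seed)
    boot_a, boot_b = bootstrap_lines(x, y, n_boot, rng)
    ci_a = percentile_ci(boot_a)
    ci_b = percentile_ci(boot_b)
    f_star = ci_f = None
    if b_hat < 0:
        f_star = -a_hat / b_hat
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_f = np.where(boot_b < 0, -boot_a / boot_b, np.nan)
        ci_f = percentile_ci(boot_f)
    return ShiftFit(a_hat, b_hat, ci_a, ci_b, f_star, ci_f, n=x.size)


def stage_contrast(
    table: pd.DataFrame,
    stage_from: str,
    stage_to: str,
    n_perm: int = 1999,
    seed=0,
) -> StageContrast:
    """Paired within-lineage contrast between two stages.

    The statistic is the mean of ``f[stage_to] - f[stage_from]``; the null is
    built by random sign-flips of the paired differences (two-sided).
    """
    if n_perm < 999:
        raise ParameterError("n_perm must be >= 999")
    cols = []
    for stage in (stage_from, stage_to):
        if stage not in _STAGE_COLUMNS:
            raise ParameterError(f"unknown stage {stage!r}; one of {sorted(_STAGE_COLUMNS)}")
        cols.append(_STAGE_COLUMNS[stage])
    diffs = (table[cols[1]] - table[cols[0]]).dropna().to_numpy(float)
    if diffs.size == 0:
        raise EstimationError("no complete pairs for the requested stages")
    small = diffs.size < 5
    if small:
        logger.warning("stage contrast on %d lineages: p-value is low-resolution", diffs.size)
    rng = np.random.default_rng(seed)
    p = signflip_pvalue(diffs, n_perm, rng)
    return StageContrast(float(diffs.mean()), p, int(diffs.size), small)


def compare_shift_fits(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    n_perm: int = 999,
    seed=0,
) -> FitComparison:
    """Compare two shift regressions by label permutation.

    Coefficient differences (A minus B) are judged against a null built by
    permuting condition labels across the pooled lineages; two-sided p-values
    per coefficient.
    """
    for pairs in (pairs_a, pairs_b):
        x = np.asarray(pairs["parent_f"], float)
        if x.size < 3 or np.all(x == x[0]):
            raise EstimationError("each condition needs >= 3 lineages with varying parent_f")
    rng = np.random.default_rng(seed)
    d_int, d_slope, p_int, p_slope = label_permutation_line_diffs(
        pairs_a["parent_f"], pairs_a["delta_f"],
        pairs_b["parent_f"], pairs_b["delta_f"],
        n_perm, rng,
    )
    return FitComparison(d_int, d_slope, p_int, p_slope)
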