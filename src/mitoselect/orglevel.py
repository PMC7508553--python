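"""Organismal (between-host) selection estimators.

Competition experiments propagate replicate populations founded as a mix of
heteroplasmic and homoplasmic-wildtype animals, alongside non-competed lines
founded with heteroplasmic animals only. Because every animal in a
non-competed line carries the mutant genome, its population-wide frequency
tracks pure within-host dynamics; dividing each competed line's pooled
frequency by the per-generation mean of the non-competed lines therefore
cancels the within-host component, and whatever slope remains is
attributable to fitness differences between animals — organismal selection
in isolation.

The per-generation organismal selection coefficient ``s_org`` is defined on
the odds of the heteroplasmic fraction (haploid-selection bookkeeping for a
discrete-generation census): ``w_t = odds(p_{t+1}) / odds(p_t)`` and
``s_org = 1 - geometric mean of w_t``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import ols_line, percentile_ci
from .exceptions import EstimationError, NormalizationError, ParameterError

__all__ = [
    "OrgFit",
    "SOrgEstimate",
    "normalize_to_noncompeted",
    "fit_org_decline",
    "fraction_trajectory",
    "endpoint_contrast",
    "estimate_s_org",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrgFit:
    """Fitted organismal decline of the normalized frequency trajectory."""

    slope_hat: float
    ci_slope: tuple[float, float]
    s_org: float
    ci_s_org: tuple[float, float]
    trajectory: pd.DataFrame
    n_lines: int


@dataclass(frozen=True)
class SOrgEstimate:
    """Odds-based per-generation organismal selection coefficient."""

    s_org: float
    ci: tuple[float, float]
    n_steps: int


def normalize_to_noncompeted(
    competed: pd.DataFrame,
    noncompeted: pd.DataFrame,
    mode: str = "ratio",
) -> pd.DataFrame:
    """Normalize competed pooled frequencies to the non-competed reference.

    In ``ratio`` mode (default) each competed value is divided by the mean
    non-competed pooled frequency at the same generation; ``difference`` mode
    subtracts instead. Self-normalizing the non-competed set yields a
    per-generation mean of exactly 1 (ratio) or 0 (difference).
    """
    if mode not in ("ratio", "difference"):
        raise ParameterError("mode must be 'ratio' or 'difference'")
    ref = (
        noncompeted.dropna(subset=["pooled_f"])
        .groupby("generation")["pooled_f"]
        .mean()
    )
    gens = sorted(competed["generation"].unique())
    missing = [g for g in gens if g not in ref.index]
    if missing:
        raise NormalizationError(
            f"no non-competed reference at generation(s) {missing}"
        )
    if (ref.loc[gens] == 0).any():
        raise NormalizationError("non-competed mean frequency is zero at some generation")
    rows = competed.dropna(subset=["pooled_f"])
    ref_vals = ref.loc[rows["generation"]].to_numpy(float)
    pooled = rows["pooled_f"].to_numpy(float)
    value = pooled / ref_vals if mode == "ratio" else pooled - ref_vals
    return pd.DataFrame(
        {"line_id": rows["line_id"].to_numpy(),
         "generation": rows["generation"].to_numpy(),
         "value": value}
    )


def _bootstrap_pooled_slopes(
    trajectory: pd.DataFrame, column_y, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Slopes of pooled line fits over bootstrap resamples of whole lines."""
    stats = []
    for _, grp in trajectory.groupby("line_id"):
        x = grp["generation"].to_numpy(float)
        y = column_y(grp)
        keep = np.isfinite(y)
        x, y = x[keep], y[keep]
        stats.append((x.size, x.sum(), y.sum(), (x * x).sum(), (x * y).sum()))
    stats = np.array(stats, dtype=float)
    n_lines = stats.shape[0]
    idx = rng.integers(0, n_lines, size=(n_boot, n_lines))
    agg = stats[idx].sum(axis=1)  # (n_boot, 5)
    n, sx, sy, sxx, sxy = agg.T
    mx, my = sx / n, sy / n
    vx = sxx / n - mx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        return (sxy / n - mx * my) / vx


def fit_org_decline(trajectory: pd.DataFrame, n_boot: int = 2000, seed=0) -> OrgFit:
    """Fit the organismal decline of a normalized trajectory.

    The headline slope is a least-squares regression of the normalized value
    on generation, pooled across replicate lines (matching a best-fit
    regression across all lineages); ``s_org`` is derived from a log-linear
    fit of the same trajectory, ``s_org = 1 - exp(log-slope)``, so an exactly
    geometric decline with ratio ``r`` yields ``s_org = 1 - r``. Confidence
    intervals bootstrap whole lines.
    """
    gens = trajectory["generation"].unique()
    if gens.size < 2:
        raise EstimationError("need at least 2 generations to fit a decline")
    x = trajectory["generation"].to_numpy(float)
    y = trajectory["value"].to_numpy(float)
    _, slope = ols_line(x, y)

    positive = y > 0
    if not positive.all():
        logger.warning(
            "%d non-positive normalized values excluded from the log-linear fit",
            int((~positive).sum()),
        )
    if positive.sum() < 2 or np.unique(x[positive]).size < 2:
        raise EstimationError("too few positive values for the log-linear fit")
    _, log_slope = ols_line(x[positive], np.log(y[positive]))
    s_org = 1.0 - float(np.exp(log_slope))

    rng = np.random.default_rng(seed)
    boot_lin = _bootstrap_pooled_slopes(
        trajectory, lambda g: g["value"].to_numpy(float), n_boot, rng)
    boot_log = _bootstrap_pooled_slopes(
        trajectory,
        lambda g: np.log(np.where(g["value"].to_numpy(float) > 0,
                                  g["value"].to_numpy(float), np.nan)),
        n_boot, rng)
    return OrgFit(
        slope_hat=float(slope),
        ci_slope=percentile_ci(boot_lin),
        s_org=s_org,
        ci_s_org=percentile_ci(1.0 - np.exp(boot_log)),
        trajectory=trajectory,
        n_lines=int(trajectory["line_id"].nunique()),
    )


def fraction_trajectory(table: pd.DataFrame) -> pd.DataFrame:
    """Per-line heteroplasmic-fraction series (generations x lines).

    Accepts competed tables only (in non-competed lines the fraction is 1 by
    construction and carries no organismal signal). Generations with zero
    genotyped animals become missing values, with a logged note.
    """
    if not table["competed"].astype(bool).all():
        raise ParameterError("fraction_trajectory expects competed lines only")
    work = table.copy()
    empty = work["n_genotyped"] <= 0
    if empty.any():
        logger.warning("%d row(s) with no genotyped animals set to missing", int(empty.sum()))
        work.loc[empty, "het_fraction"] = np.nan
    return work.pivot(index="generation", columns="line_id", values="het_fraction")


def endpoint_contrast(fractions_x: pd.DataFrame, fractions_ref: pd.DataFrame) -> float:
    """Final-generation heteroplasmic fraction of X relative to a reference.

    The contrast is the mean fraction at the last common generation of the
    condition of interest divided by the reference condition's mean.
    """
    last = min(fractions_x.index.max(), fractions_ref.index.max())
    ref = float(fractions_ref.loc[last].mean())
    if ref == 0.0:
        raise NormalizationError("reference condition has zero heteroplasmic fraction")
    return float(fractions_x.loc[last].mean()) / ref


def estimate_s_org(fractions: pd.DataFrame, n_boot: int = 2000, seed=0) -> SOrgEstimate:
    """Odds-decline estimate of the organismal selection coefficient.

    For each line and each pair of consecutive generations with fractions
    strictly inside (0, 1), the per-step relative fitness is
    ``w_t = odds(p_{t+1}) / odds(p_t)``; steps touching 0 or 1 are skipped
    (odds undefined) with a logged note. ``s_org`` is one minus the geometric
    mean of all steps, with a bootstrap over lines for the interval.
    """
    per_line = []  # (sum of log w, step count) per line
    n_skipped = 0
    for col in fractions.columns:
        p = fractions[col].to_numpy(float)
        logw = []
        for t in range(p.size - 1):
            pair = p[t], p[t + 1]
            if any(not np.isfinite(v) for v in pair):
                continue
            if any(v <= 0.0 or v >= 1.0 for v in pair):
                n_skipped += 1
                continue
            odds0 = pair[0] / (1 - pair[0])
            odds1 = pair[1] / (1 - pair[1])
            logw.append(np.log(odds1 / odds0))
        if logw:
            per_line.append((float(np.sum(logw)), len(logw)))
    if n_skipped:
        logger.warning("%d step(s) skipped: fraction at 0 or 1 (odds undefined)", n_skipped)
    if not per_line:
        raise EstimationError("no usable consecutive-generation steps in (0, 1)")
    stats = np.array(per_line, dtype=float)
    total_log, total_n = stats.sum(axis=0)
    s_org = 1.0 - float(np.exp(total_log / total_n))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, stats.shape[0], size=(n_boot, stats.shape[0]))
    agg = stats[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = 1.0 - np.exp(agg[:, 0] / agg[:, 1])
    return SOrgEstimate(s_org=s_org, ci=percentile_ci(boot), n_steps=int(total_n))
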