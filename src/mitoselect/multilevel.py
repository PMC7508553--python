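"""Integration of the two selection levels into net predictions.

Within hosts the mutant genome gains frequency (favoring its spread);
between hosts it reduces fecundity and slows development (favoring its
loss). This module combines the two: a deterministic mean-field balance
point for the population mean frequency, Monte-Carlo forecasts of
non-competing trajectories normalized to their starting frequency (the net
readout), and an ordinal ranking of conditions by net selection strength.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._stats import ols_line
from .exceptions import ConvergenceError, ParameterError
from .presets import ConditionPreset
from .simulate import brood_rate, maturation_probability, simulate_competition
from .sublevel import ShiftFit

__all__ = [
    "EquilibriumResult",
    "NetPrediction",
    "equilibrium_balance",
    "predict_trajectory",
    "rank_conditions",
]


@dataclass(frozen=True)
class EquilibriumResult:
    """Stationary mean frequency of the mean-field recursion."""

    frequency: float
    converged: bool
    at_ceiling: bool


@dataclass(frozen=True)
class NetPrediction:
    """Forecast net trajectory for one condition.

    ``trajectory`` is the Monte-Carlo mean frequency per generation divided
    by the generation-0 mean, so it starts at exactly 1; ``net_slope`` is its
    least-squares slope per generation.
    """

    condition: str
    trajectory: np.ndarray
    net_slope: float
    final_mean: float
    rank: int | None = None


def _mean_field_step(
    mu: float,
    shift_fit: ShiftFit,
    preset: ConditionPreset,
    sigma: float,
    f_max: float,
) -> float:
    """One generation of the deterministic mean-field recursion.

    The population is summarized as a Gaussian of mean ``mu`` and fixed
    spread ``sigma``; each frequency maps through the fitted parent-to-adult
    shift and contributes offspring in proportion to its fecundity and
    maturation weight.
    """
    gain = lambda f: np.clip(f + shift_fit.a_hat + shift_fit.b_hat * f, 0.0, f_max)
    if sigma == 0.0:
        return float(gain(mu))  # point mass: weights cancel
    grid = np.linspace(mu - 6.0 * sigma, mu + 6.0 * sigma, 1201)
    density = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    f_eval = np.clip(grid, 0.0, 1.0)
    w = brood_rate(f_eval, preset) * maturation_probability(f_eval, preset)
    total = float(np.sum(w * density))
    if total <= 0.0:
        raise ConvergenceError("all reproduction weights vanish at this mean")
    return float(np.sum(w * density * gain(f_eval)) / total)


def equilibrium_balance(
    shift_fit: ShiftFit,
    preset: ConditionPreset,
    sigma: float = 0.065,
    f_max: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> EquilibriumResult:
    """Stationary mean frequency balancing both selection levels.

    Fixed-point iteration of the mean-field recursion; if the iteration does
    not settle, a dense grid scan (step 1e-3) with bisection locates a sign
    change of ``F(mu) - mu``. With all costs off the balance point reduces to
    the within-host equilibrium ``f* = -a/b``. When no interior fixed point
    exists, the ceiling is reported (unopposed gain) or 0 (unopposed loss),
    flagged via ``at_ceiling`` / ``converged``.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    ceiling = preset.f_max if f_max is None else f_max
    step = lambda mu: _mean_field_step(mu, shift_fit, preset, sigma, ceiling)

    mu = 0.5
    for _ in range(max_iter):
        nxt = step(mu)
        if abs(nxt - mu) < tol:
            interior = tol < nxt < ceiling - tol
            return EquilibriumResult(float(nxt), True, not interior and nxt >= ceiling - tol)
        mu = nxt

    # bisection fallback on a dense grid
    grid = np.arange(0.0, ceiling + 1e-12, 1e-3)
    resid = np.array([step(m) - m for m in grid])
    signs = np.sign(resid)
    crossings = np.nonzero(np.diff(signs) < 0)[0]
    if crossings.size:
        lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if step(mid) - mid > 0:
                lo = mid
            else:
                hi = mid
        return EquilibriumResult(0.5 * (lo + hi), True, False)
    if np.all(resid >= 0):
        return EquilibriumResult(float(ceiling), False, True)
    return EquilibriumResult(0.0, False, False)


def predict_trajectory(
    preset: ConditionPreset,
    generations: int = 8,
    n_rep: int = 6,
    carry_n: int = 200,
    seed=0,
    mean_f: float = 0.60,
    spread: float = 0.15,
) -> NetPrediction:
    """Monte-Carlo forecast of non-competing populations under a preset.

    Simulates ``n_rep`` heteroplasmic-only lines, averages the pooled
    frequency per generation, and normalizes to the generation-0 mean; the
    net selection readout is the least-squares slope of that normalized mean
    trajectory.
    """
    if generations < 1:
        raise ParameterError("generations must be >= 1")
    table = simulate_competition(
        n_lines=n_rep, generations=generations, carry_n=carry_n,
        preset=preset, competed=False, seed=seed,
        mean_f=mean_f, spread=spread,
    )
    means = table.groupby("generation")["pooled_f"].mean()
    normalized = (means / means.loc[0]).to_numpy(float)
    _, slope = ols_line(np.arange(normalized.size, dtype=float), normalized)
    return NetPrediction(
        condition=preset.name,
        trajectory=normalized,
        net_slope=float(slope),
        final_mean=float(normalized[-1]),
    )


def rank_conditions(predictions: list[NetPrediction]) -> list[NetPrediction]:
    """Order conditions by net selection against the mutant genome.

    Sorted by net slope ascending, so rank 1 is the steepest decline (the
    strongest net selection against the mutant); ties break by
    final-generation mean, then by label. The input order is irrelevant.
    """
    if len(predictions) < 1:
        raise ParameterError("need at least one prediction")
    spans = {p.trajectory.size for p in predictions}
    if len(predictions) > 1 and len(spans) > 1:
        raise ParameterError("predictions cover mismatched generation spans")
    ordered = sorted(
        predictions, key=lambda p: (p.net_slope, p.final_mean, p.condition)
    )
    return [replace(p, rank=i + 1) for i, p in enumerate(ordered)]
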