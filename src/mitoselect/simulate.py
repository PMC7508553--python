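"""Stochastic simulator of heteroplasmic nematode populations.

The model tracks the frequency ``f`` of a selfish mitochondrial deletion
genome within each animal across a discrete, non-overlapping life cycle:

1. transmission through a finite germline bottleneck with an optional
   parent-to-embryo purifying shift (``delta_embryo``),
2. frequency-dependent within-host proliferation across development,
   ``f_adult = f_embryo + a + b*f_embryo + eps`` clamped to ``[0, f_max]``,
3. host fitness costs that rise with ``f``: reduced fecundity above a
   threshold frequency and a lower probability of maturing by census time.

Two experimental designs are generated: isolated parent-progeny lineages
(pooled-lysate readout per developmental stage) and multigeneration
competition/propagation experiments with a fixed census size.

Randomness contract: every public generator takes a ``seed`` that may be an
int, a ``numpy.random.SeedSequence`` or a ``Generator``. Replicate lines and
lineages are seeded by hierarchical spawning, so simulating more lines never
perturbs the ones already simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ParameterError
from .presets import ConditionPreset, get_preset, neutral_preset  # noqa: F401

__all__ = [
    "Individual",
    "PopulationState",
    "make_stock_population",
    "stock_frequencies",
    "stock_mean",
    "transmit_bottleneck",
    "develop_within_host",
    "brood_rate",
    "maturation_probability",
    "copy_number",
    "simulate_lineages",
    "simulate_competition",
]

logger = logging.getLogger(__name__)

STAGES = ("embryo", "L2", "L3", "L4", "adult")

#: Shape parameter of the symmetric Beta stock distribution. Values just
#: above 1 give a broad unimodal distribution matching the wide 50-80%
#: frequency range of the maintained heteroplasmic stock.
STOCK_ALPHA = 1.3

#: Fraction of the developmental gain expressed by the L4 stage (the
#: remainder accrues during adult germline maturation).
L4_GAIN_FRACTION = 0.6

LINEAGE_COLUMNS = ["lineage_id", "parent_f", "embryo_f", "l4_f", "adult_f"]
COMPETITION_COLUMNS = [
    "line_id", "generation", "competed", "pooled_f",
    "het_fraction", "n_genotyped", "terminated",
]


@dataclass
class Individual:
    """One worm: mutant frequency, developmental stage and mtDNA copy counts."""

    f: float
    stage: str = "adult"
    n_wt: int = 0
    n_mut: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ParameterError("individual frequency must lie in [0, 1)")
        if self.stage not in STAGES:
            raise ParameterError(f"stage must be one of {STAGES}")


@dataclass
class PopulationState:
    """A census: generation index, members and the design flags."""

    generation: int
    members: list[Individual]
    carry_n: int
    competed: bool


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# stock population


def stock_mean(mean_f: float = 0.60, spread: float = 0.15) -> float:
    """Closed-form mean of the stock frequency distribution.

    The stock model is a symmetric scaled Beta on
    ``[mean_f - spread, mean_f + spread]``, so its mean is ``mean_f`` exactly.
    """
    _check_stock(1, mean_f, spread)
    return mean_f


def _check_stock(n: int, mean_f: float, spread: float) -> None:
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0.0 < mean_f < 1.0:
        raise ParameterError("mean_f must lie strictly inside (0, 1)")
    if spread < 0:
        raise ParameterError("spread must be >= 0")
    if mean_f - spread < 0.0 or mean_f + spread > 1.0:
        raise ParameterError("stock support [mean_f-spread, mean_f+spread] must fit in [0, 1]")


def stock_frequencies(
    n: int,
    mean_f: float = 0.60,
    spread: float = 0.15,
    seed=None,
) -> np.ndarray:
    """Draw ``n`` stock heteroplasmy frequencies as a numpy array.

    Frequencies follow a symmetric Beta(:data:`STOCK_ALPHA`,
    :data:`STOCK_ALPHA`) scaled to ``[mean_f - spread, mean_f + spread]``:
    a broad unimodal distribution with mean exactly ``mean_f``, emulating a
    stock stably maintaining the deletion in the 50-80% range.
    """
    _check_stock(n, mean_f, spread)
    if spread == 0.0:
        return np.full(n, mean_f)
    rng = _rng(seed)
    unit = rng.beta(STOCK_ALPHA, STOCK_ALPHA, size=n)
    return mean_f - spread + 2.0 * spread * unit


def make_stock_population(
    n: int,
    mean_f: float = 0.60,
    spread: float = 0.15,
    seed=None,
    wt_setpoint: int = 200000,
) -> list[Individual]:
    """Generate ``n`` heteroplasmic adults from the stock model.

    Copy numbers follow the hitchhiking model: the wildtype setpoint is
    maintained and mutant copies accumulate on top of it.
    """
    freqs = stock_frequencies(n, mean_f, spread, seed)
    out = []
    for f in freqs:
        n_wt, n_mut = copy_number(float(f), wt_setpoint)
        out.append(Individual(f=float(f), stage="adult", n_wt=n_wt, n_mut=n_mut))
    return out


# ---------------------------------------------------------------------------
# single-step operations


def transmit_bottleneck(f_parent, B: int = 200, delta_embryo: float = 0.0, seed=None):
    """Embryo frequency after the germline transmission bottleneck.

    ``B`` segregating genome units are sampled binomially at probability
    ``clamp(f_parent + delta_embryo, 0, 1)``; the embryo frequency is the
    sampled fraction. Scalar in, scalar out; array in, array out.
    """
    if B < 1:
        raise ParameterError("bottleneck size B must be >= 1")
    f = np.asarray(f_parent, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)):
        raise ParameterError("f_parent must lie in [0, 1]")
    rng = _rng(seed)
    p = np.clip(f + delta_embryo, 0.0, 1.0)
    draws = rng.binomial(B, p) / B
    return float(draws) if np.isscalar(f_parent) else draws


def develop_within_host(f_embryo, preset: ConditionPreset, seed=None, gain_fraction: float = 1.0):
    """Adult frequency after frequency-dependent within-host proliferation.

    Applies ``f + g*(a + b*f) + eps`` with ``eps ~ N(0, (g*sd)^2)`` where
    ``g`` is ``gain_fraction`` (1 for adults, less for intermediate stages),
    clamped to ``[0, f_max]``. A frequency of exactly zero stays zero: the
    deletion cannot arise de novo.
    """
    f = np.asarray(f_embryo, dtype=float)
    if np.any((f < 0.0) | (f > 1.0)):
        raise ParameterError("f_embryo must lie in [0, 1]")
    rng = _rng(seed)
    eps = rng.normal(0.0, preset.shift_sd * gain_fraction, size=f.shape)
    raw = f + gain_fraction * (preset.shift_a + preset.shift_b * f) + eps
    out = np.where(f > 0.0, np.clip(raw, 0.0, preset.f_max), 0.0)
    return float(out) if np.isscalar(f_embryo) else out


def brood_rate(f, preset: ConditionPreset):
    """Viable progeny per hour as a function of mutant frequency.

    Equal to ``fecundity_base`` up to ``fecundity_theta``, then declining
    along a logistic ramp of width ``fecundity_ramp`` toward
    ``fecundity_base * (1 - fecundity_cost)``; zero at ``f >= f_max``
    (homoplasmic-mutant adults are inviable).
    """
    f = np.asarray(f, dtype=float)
    # ramp is exactly 0 at theta and saturates at 1 a few widths above it
    excess = np.clip(f - preset.fecundity_theta, 0.0, None)
    ramp = 2.0 * expit(excess / preset.fecundity_ramp) - 1.0
    rate = preset.fecundity_base * (1.0 - preset.fecundity_cost * ramp)
    rate = np.where(f >= preset.f_max, 0.0, rate)
    return float(rate) if rate.ndim == 0 else rate


def maturation_probability(f, preset: ConditionPreset):
    """Probability that a laid embryo is an adult-competent L4 by census time.

    Linear decline with frequency: ``clamp(1 - delay_slope * f, 0, 1)``.
    """
    f = np.asarray(f, dtype=float)
    p = np.clip(1.0 - preset.delay_slope * f, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def copy_number(f: float, W: int) -> tuple[int, int]:
    """(wildtype, mutant) copy counts under the hitchhiking model.

    The host maintains the wildtype setpoint ``W`` regardless of mutant
    load; mutant copies accumulate on top, ``n_mut = round(W * f / (1-f))``,
    so the implied total ``W / (1-f)`` rises strictly with frequency.
    """
    if W <= 0:
        raise ParameterError("W must be a positive count")
    if not 0.0 <= f < 1.0:
        raise ParameterError("f must lie in [0, 1); the total diverges at f=1")
    return int(W), int(round(W * f / (1.0 - f)))


# ---------------------------------------------------------------------------
# experimental designs


def _pool_value(freqs: np.ndarray, preset: ConditionPreset, weighted: bool) -> float:
    """Pooled-lysate readout for a set of same-parent progeny.

    Arithmetic mean by default; optionally weighted by total copy number
    (ddPCR measures template fraction, so a copy-weighted mode is provided
    for sensitivity analysis).
    """
    if not weighted:
        return float(np.mean(freqs))
    totals = 1.0 / (1.0 - np.clip(freqs, 0.0, 0.999999))
    return float(np.sum(freqs * totals) / np.sum(totals))


def simulate_lineages(
    n_lineages: int,
    preset: ConditionPreset,
    pool_size: int = 3,
    mean_f: float = 0.60,
    spread: float = 0.15,
    seed=0,
    weighted_pooling: bool = False,
) -> pd.DataFrame:
    """Simulate isolated parent-progeny lineages.

    Each lineage has one parent drawn from the stock model; at each
    developmental stage (embryo, L4, adult) a fresh pool of ``pool_size``
    same-parent progeny is simulated through the bottleneck and (for later
    stages) partial or full within-host development, and the recorded value
    is the pool mean, emulating a pooled lysate. Lineages are statistically
    independent: there is no between-lineage competition by design.
    """
    if n_lineages < 1:
        raise ParameterError("n_lineages must be >= 1")
    if pool_size < 1:
        raise ParameterError("pool_size must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for i, child_seq in enumerate(root.spawn(n_lineages)):
        rng = np.random.default_rng(child_seq)
        parent_f = float(stock_frequencies(1, mean_f, spread, rng)[0])
        stage_vals = {}
        for stage, gain in (("embryo", 0.0), ("l4", L4_GAIN_FRACTION), ("adult", 1.0)):
            emb = transmit_bottleneck(
                np.full(pool_size, parent_f), preset.bottleneck_b,
                preset.delta_embryo, rng,
            )
            freqs = emb if gain == 0.0 else develop_within_host(emb, preset, rng, gain)
            stage_vals[stage] = _pool_value(np.asarray(freqs), preset, weighted_pooling)
        rows.append(
            dict(lineage_id=i, parent_f=parent_f,
                 embryo_f=stage_vals["embryo"], l4_f=stage_vals["l4"],
                 adult_f=stage_vals["adult"])
        )
    table = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    table.attrs.update(preset=preset.name, pool_size=pool_size)
    return table


def _next_generation(
    f: np.ndarray,
    preset: ConditionPreset,
    carry_n: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """One propagation step; ``None`` signals line termination."""
    weights = brood_rate(f, preset) * maturation_probability(f, preset)
    total = float(np.sum(weights))
    if total <= 0.0 or f.size == 0:
        return None
    parents = rng.choice(f.size, size=carry_n, p=weights / total)
    f_par = f[parents]
    embryos = transmit_bottleneck(f_par, preset.bottleneck_b, preset.delta_embryo, rng)
    return develop_within_host(embryos, preset, rng)


def simulate_competition(
    n_lines: int = 8,
    generations: int = 10,
    carry_n: int = 500,
    init_het_fraction: float = 0.5,
    preset: ConditionPreset | None = None,
    competed: bool = True,
    genotype_sample: int = 48,
    seed=0,
    mean_f: float = 0.60,
    spread: float = 0.15,
) -> pd.DataFrame:
    """Simulate replicate competition (or propagation-only) lines.

    Competed lines are founded with a ``init_het_fraction`` mix of
    heteroplasmic and homoplasmic-wildtype animals; non-competed lines are
    founded with heteroplasmic animals only. Each generation, adults
    reproduce in proportion to ``brood_rate(f) * maturation_probability(f)``,
    offspring pass through the transmission bottleneck and within-host
    development, and ``carry_n`` offspring found the next generation.

    Recorded per line x generation: the pooled frequency (individual
    mean of ``f``, emulating the pooled mixed-age lysate) and the
    heteroplasmic fraction among ``genotype_sample`` randomly drawn animals.
    A line whose reproductive output hits zero is terminated and flagged.
    """
    if preset is None:
        preset = get_preset("wt_live")
    if carry_n < 10:
        raise ParameterError("carry_n must be >= 10")
    if generations < 1:
        raise ParameterError("generations must be >= 1")
    if not 0.0 <= init_het_fraction <= 1.0:
        raise ParameterError("init_het_fraction must lie in [0, 1]")

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for line_id, child_seq in enumerate(root.spawn(n_lines)):
        rng = np.random.default_rng(child_seq)
        n_het = carry_n if not competed else int(round(init_het_fraction * carry_n))
        f = np.zeros(carry_n)
        f[:n_het] = stock_frequencies(n_het, mean_f, spread, rng)
        for t in range(generations + 1):
            k = min(genotype_sample, f.size)
            sampled = rng.choice(f, size=k, replace=False)
            rows.append(
                dict(line_id=line_id, generation=t, competed=competed,
                     pooled_f=float(np.mean(f)),
                     het_fraction=float(np.mean(sampled > 0.0)),
                     n_genotyped=k, terminated=False)
            )
            if t == generations:
                break
            nxt = _next_generation(f, preset, carry_n, rng)
            if nxt is None:
                # reproductive output hit zero: the line ends here and its
                # last observed census is flagged
                rows[-1]["terminated"] = True
                logger.warning("line %d terminated after generation %d", line_id, t)
                break
            f = nxt
    table = pd.DataFrame(rows, columns=COMPETITION_COLUMNS)
    table.attrs.update(preset=preset.name, carry_n=carry_n)
    return table
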