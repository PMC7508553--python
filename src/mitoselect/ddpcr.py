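"""Duplex droplet digital PCR: forward measurement model and quantification.

A reaction partitions a diluted lysate into ~20,000 nanoliter droplets.
Wildtype and mutant template molecules land in droplets independently
(Poisson), and each droplet is scored for presence/absence of each template,
yielding four classes: double-negative, wildtype-only, mutant-only and
double-positive. Concentrations are recovered from the fraction of droplets
negative for each channel via the Poisson zero-class,
``lambda = -ln(P(negative))``, and the heteroplasmy frequency is the mutant
share of total template, ``lambda_mut / (lambda_wt + lambda_mut)`` —
invariant to dilution and volume bookkeeping, which cancel in the ratio.

The amplitude-clustering step of the bench assay is replaced by exact class
labels from the forward model; an optional symmetric misclassification rate
is available for robustness experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, SaturationError

__all__ = [
    "DropletCounts",
    "QuantResult",
    "DEFAULT_DROPLET_VOL_UL",
    "DEFAULT_N_DROPLETS",
    "simulate_droplets",
    "quantify",
    "call_heteroplasmic",
    "measure_pool",
]

#: Industry-standard droplet volume (0.85 nL, expressed in microliters).
DEFAULT_DROPLET_VOL_UL = 0.00085
#: Typical accepted-droplet count per reaction.
DEFAULT_N_DROPLETS = 20000


@dataclass(frozen=True)
class DropletCounts:
    """Classified droplet counts for one duplex reaction."""

    n_total: int
    n_neg: int
    n_wt_only: int
    n_mut_only: int
    n_double: int

    def __post_init__(self) -> None:
        counts = (self.n_neg, self.n_wt_only, self.n_mut_only, self.n_double)
        if self.n_total < 1 or any(c < 0 for c in counts):
            raise ParameterError("droplet counts must be non-negative with n_total >= 1")
        if sum(counts) != self.n_total:
            raise ParameterError("droplet classes must partition n_total")


@dataclass(frozen=True)
class QuantResult:
    """Concentrations and per-individual copy numbers for one reaction."""

    lambda_wt: float
    lambda_mut: float
    freq: float
    copies_per_individual_wt: float
    copies_per_individual_mut: float


def simulate_droplets(
    conc_wt: float,
    conc_mut: float,
    n_droplets: int = DEFAULT_N_DROPLETS,
    droplet_vol: float = DEFAULT_DROPLET_VOL_UL,
    seed=None,
    misclassification: float = 0.0,
) -> DropletCounts:
    """Forward model: partition templates into droplets and classify.

    Per droplet, wildtype and mutant template counts are independent
    Poisson(concentration * droplet volume); classification is by
    presence/absence of each template. ``misclassification`` swaps each
    single-positive droplet's channel with the given probability.
    """
    if conc_wt < 0 or conc_mut < 0:
        raise ParameterError("concentrations must be >= 0")
    if n_droplets < 1:
        raise ParameterError("n_droplets must be >= 1")
    if droplet_vol <= 0:
        raise ParameterError("droplet_vol must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_wt = -math.expm1(-conc_wt * droplet_vol)   # 1 - e^-lambda
    p_mut = -math.expm1(-conc_mut * droplet_vol)
    probs = np.array([
        (1 - p_wt) * (1 - p_mut),  # negative
        p_wt * (1 - p_mut),        # wildtype only
        (1 - p_wt) * p_mut,        # mutant only
        p_wt * p_mut,              # double positive
    ])
    n_neg, n_wt, n_mut, n_double = rng.multinomial(n_droplets, probs)
    if misclassification > 0.0:
        wt_to_mut = rng.binomial(n_wt, misclassification)
        mut_to_wt = rng.binomial(n_mut, misclassification)
        n_wt += mut_to_wt - wt_to_mut
        n_mut += wt_to_mut - mut_to_wt
    return DropletCounts(int(n_droplets), int(n_neg), int(n_wt), int(n_mut), int(n_double))


def quantify(
    counts: DropletCounts,
    droplet_vol: float = DEFAULT_DROPLET_VOL_UL,
    dilution: float = 1.0,
    lysis_vol: float = 10.0,
    n_individuals: int = 1,
) -> QuantResult:
    """Poisson-corrected concentrations, frequency and per-individual copies.

    A droplet is negative for the wildtype channel iff it is in the
    double-negative or mutant-only class (and symmetrically for the mutant
    channel), so ``lambda_wt = -ln((n_neg + n_mut_only)/n_total)``. Double
    positives therefore contribute to both channels, the standard treatment
    for duplex reactions. Per-individual copies scale lambda back through
    dilution, lysis volume and worm count.
    """
    if n_individuals < 1:
        raise ParameterError("n_individuals must be >= 1")
    if droplet_vol <= 0 or dilution <= 0 or lysis_vol <= 0:
        raise ParameterError("droplet_vol, dilution and lysis_vol must be > 0")
    neg_wt = counts.n_neg + counts.n_mut_only
    neg_mut = counts.n_neg + counts.n_wt_only
    if neg_wt == 0 or neg_mut == 0:
        raise SaturationError(
            "a channel has no negative droplets; concentration unbounded "
            "(increase the dilution factor)"
        )
    lam_wt = -math.log(neg_wt / counts.n_total)
    lam_mut = -math.log(neg_mut / counts.n_total)
    total = lam_wt + lam_mut
    freq = lam_mut / total if total > 0 else 0.0
    scale = dilution * lysis_vol / droplet_vol / n_individuals
    return QuantResult(
        lambda_wt=lam_wt,
        lambda_mut=lam_mut,
        freq=freq,
        copies_per_individual_wt=lam_wt * scale,
        copies_per_individual_mut=lam_mut * scale,
    )


def call_heteroplasmic(counts: DropletCounts, min_mut_droplets: int = 3) -> bool:
    """Score a single-animal reaction as heteroplasmic.

    True iff the number of mutant-positive droplets (mutant-only plus
    double-positive) reaches ``min_mut_droplets``. The default threshold of 3
    keeps the false-positive rate far below the 1/48 resolution of the
    genotyping sample.
    """
    return (counts.n_mut_only + counts.n_double) >= min_mut_droplets


def measure_pool(
    freq: float,
    total_copies: float,
    lysis_vol: float,
    dilution: float,
    n_individuals: int = 1,
    n_droplets: int = DEFAULT_N_DROPLETS,
    droplet_vol: float = DEFAULT_DROPLET_VOL_UL,
    seed=None,
) -> QuantResult:
    """Measure a lysate of known composition through the full assay.

    Convenience wrapper for the pipeline's optional measurement layer:
    converts a true frequency and per-lysate total copy count into channel
    concentrations, simulates one reaction, and quantifies it.
    """
    if not 0.0 <= freq <= 1.0:
        raise ParameterError("freq must lie in [0, 1]")
    if total_copies < 0:
        raise ParameterError("total_copies must be >= 0")
    conc_total = total_copies / (lysis_vol * dilution)
    counts = simulate_droplets(
        conc_total * (1.0 - freq), conc_total * freq, n_droplets, droplet_vol, seed
    )
    return quantify(counts, droplet_vol, dilution, lysis_vol, n_individuals)
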