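"""End-to-end pipeline: simulate -> (optional ddPCR measurement) ->
sub-organismal and organismal estimation -> net multilevel prediction.

Every run is fully reproducible from (configuration, root seed): per-stage
random streams are spawned hierarchically from the root seed, all
intermediate tables are written as CSV, and a metadata record (config hash,
seed, package version) accompanies the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._stats import ols_line
from .config import RunConfig
from .ddpcr import measure_pool
from .exceptions import MitoselectError
from .multilevel import NetPrediction, rank_conditions
from .orglevel import (
    estimate_s_org,
    fit_org_decline,
    fraction_trajectory,
    normalize_to_noncompeted,
)
from .presets import builtin_presets, load_preset_file
from .simulate import simulate_competition, simulate_lineages
from .sublevel import fit_shift_function, per_generation_shift
from .tables import write_table

__all__ = ["PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(MitoselectError):
    """Wraps a stage failure with the stage name; partial outputs remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _measure_lineages(table: pd.DataFrame, preset, pool_size: int, rng) -> pd.DataFrame:
    """Replace true lineage frequencies with duplex ddPCR measurements."""
    out = table.copy()
    plans = {  # column -> (n individuals, per-individual copies, dilution)
        "parent_f": (1, preset.wt_setpoint, 200.0),
        "embryo_f": (pool_size, preset.wt_setpoint / 8.0, 20.0),
        "l4_f": (pool_size, preset.wt_setpoint / 2.0, 200.0),
        "adult_f": (pool_size, preset.wt_setpoint, 1000.0),
    }
    for col, (n_ind, copies, dilution) in plans.items():
        measured = []
        for f in out[col].to_numpy(float):
            total = n_ind * copies / max(1.0 - f, 0.05)
            res = measure_pool(f, total, lysis_vol=10.0, dilution=dilution,
                               n_individuals=n_ind, seed=rng)
            measured.append(res.freq)
        out[col] = measured
    return out


def _measure_competition(table: pd.DataFrame, preset, carry_n: int, rng) -> pd.DataFrame:
    """Replace true pooled frequencies with ddPCR measurements of the lysate."""
    out = table.copy()
    measured = []
    for f in out["pooled_f"].to_numpy(float):
        total = carry_n * preset.wt_setpoint / max(1.0 - f, 0.05)
        res = measure_pool(f, total, lysis_vol=50.0, dilution=20000.0,
                           n_individuals=carry_n, seed=rng)
        measured.append(res.freq)
    out["pooled_f"] = measured
    return out


def _prediction_from_table(table: pd.DataFrame, condition: str) -> NetPrediction:
    """Net trajectory of an already-simulated non-competing table."""
    means = table.groupby("generation")["pooled_f"].mean()
    normalized = (means / means.loc[0]).to_numpy(float)
    _, slope = ols_line(np.arange(normalized.size, dtype=float), normalized)
    return NetPrediction(condition=condition, trajectory=normalized,
                         net_slope=float(slope), final_mean=float(normalized[-1]))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return a result bundle.

    Returns a dict with per-condition tables and fits, the ranked net
    predictions, and the paths of everything written under
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bank = builtin_presets()
    if config.preset_file:
        bank.update(load_preset_file(config.preset_file))
    root = np.random.SeedSequence(config.seed)
    results: dict = {"conditions": {}, "paths": [], "seed": config.seed}

    predictions = []
    for i, name in enumerate(config.presets):
        stage = f"simulate[{name}]"
        try:
            preset = bank[name] if name in bank else None
            if preset is None:
                raise MitoselectError(f"preset {name!r} not found")
            seq_lin, seq_comp, seq_non, seq_meas = np.random.SeedSequence(
                config.seed, spawn_key=(i,)).spawn(4)
            lineages = simulate_lineages(
                config.n_lineages, preset, seed=seq_lin,
                weighted_pooling=config.weighted_pooling)
            competed = simulate_competition(
                n_lines=config.n_lines, generations=config.generations,
                carry_n=config.carry_n, preset=preset, competed=True,
                genotype_sample=config.genotype_sample, seed=seq_comp)
            noncompeted = simulate_competition(
                n_lines=config.n_lines, generations=config.generations,
                carry_n=config.carry_n, preset=preset, competed=False,
                genotype_sample=config.genotype_sample, seed=seq_non)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc

        if config.measurement:
            stage = f"measure[{name}]"
            try:
                rng = np.random.default_rng(seq_meas)
                lineages = _measure_lineages(lineages, preset, 3, rng)
                competed = _measure_competition(competed, preset, config.carry_n, rng)
                noncompeted = _measure_competition(noncompeted, preset, config.carry_n, rng)
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(stage, exc) from exc

        for label, tab, schema in (
            ("lineages", lineages, "lineage"),
            ("competed", competed, "competition"),
            ("noncompeted", noncompeted, "competition"),
        ):
            path = write_table(tab, outdir / f"{name}_{label}.csv", schema)
            results["paths"].append(str(path))

        stage = f"estimate[{name}]"
        try:
            shift = fit_shift_function(
                per_generation_shift(lineages), n_boot=config.n_boot, seed=config.seed)
            normalized = normalize_to_noncompeted(
                competed, noncompeted, mode=config.normalization_mode)
            org = fit_org_decline(normalized, n_boot=config.n_boot, seed=config.seed)
            fractions = fraction_trajectory(competed)
            s_org = estimate_s_org(fractions, n_boot=config.n_boot, seed=config.seed)
            prediction = _prediction_from_table(noncompeted, name)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc

        predictions.append(prediction)
        results["conditions"][name] = {
            "lineages": lineages, "competed": competed, "noncompeted": noncompeted,
            "shift_fit": shift, "org_fit": org, "s_org": s_org,
        }

    try:
        ranked = rank_conditions(predictions)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("rank", exc) from exc
    results["ranked"] = ranked

    rank_rows = pd.DataFrame(
        [{"rank": p.rank, "condition": p.condition,
          "net_slope": p.net_slope, "final_mean": p.final_mean} for p in ranked]
    )
    rank_path = outdir / "condition_ranks.csv"
    rank_rows.to_csv(rank_path, index=False, float_format="%.10g")
    results["paths"].append(str(rank_path))

    summary = {
        name: {
            "a_hat": cond["shift_fit"].a_hat,
            "b_hat": cond["shift_fit"].b_hat,
            "f_star": cond["shift_fit"].f_star,
            "org_slope": cond["org_fit"].slope_hat,
            "s_org_fit": cond["org_fit"].s_org,
            "s_org_odds": cond["s_org"].s_org,
        }
        for name, cond in results["conditions"].items()
    }
    summary["ranks"] = {p.condition: p.rank for p in ranked}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    results["paths"].append(str(outdir / "summary.json"))

    metadata = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    results["paths"].append(str(outdir / "run_metadata.json"))
    logger.info("pipeline complete: %d condition(s), outputs in %s",
                len(config.presets), outdir)
    return results
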