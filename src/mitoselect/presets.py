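"""Condition presets: named parameter bundles for diet x host-genotype
combinations.

A :class:`ConditionPreset` collects everything the life-cycle simulator needs
to know about one experimental condition: the parent-to-embryo purifying
shift, the affine within-host gain of the mutant genome across development,
the wildtype copy-number setpoint, and the host fitness costs (fecundity and
maturation delay) of carrying the mutant at a given frequency.

Built-in presets ship with the package as ``presets.yaml`` and are loaded
lazily; custom presets can be constructed directly or loaded from a user
YAML file of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from importlib import resources

import yaml

from .exceptions import ParameterError

__all__ = [
    "ConditionPreset",
    "builtin_presets",
    "get_preset",
    "load_preset_file",
    "diet_concentrations",
    "diet_dilution_factor",
    "ddpcr_dilution",
]

PRESET_NAMES = (
    "wt_live",
    "wt_control",
    "wt_restricted",
    "daf16_control",
    "daf16_restricted",
    "daf2",
    "daf2_daf16",
)


@dataclass(frozen=True)
class ConditionPreset:
    """Parameter bundle for one experimental condition.

    Parameters
    ----------
    name:
        Condition label (e.g. ``wt_live``, ``daf16_restricted``).
    delta_embryo:
        Signed parent-to-embryo frequency shift (purifying selection in the
        germline; <= 0 on plentiful diets, 0 under diet restriction).
    shift_a, shift_b:
        Intercept and slope of the affine within-host frequency gain across
        development, ``delta = shift_a + shift_b * f``. ``shift_b <= 0``
        (negative frequency dependence).
    shift_sd:
        Between-individual Gaussian noise on the developmental gain.
    wt_setpoint:
        Wildtype mtDNA copies per adult; the host maintains this setpoint
        while mutant copies accumulate on top of it.
    fecundity_base:
        Viable progeny per hour at low mutant frequency.
    fecundity_theta:
        Frequency above which fecundity starts to decline.
    fecundity_cost:
        Proportional fecundity reduction reached well above the threshold.
    fecundity_ramp:
        Width (in frequency units) of the logistic ramp over which the
        fecundity cost is expressed.
    delay_slope:
        Decline per unit frequency of the probability that a laid embryo
        matures by census time.
    f_max:
        Heteroplasmy ceiling: homoplasmic-mutant adults are inviable, so
        adult frequencies are clamped below this value.
    bottleneck_b:
        Number of segregating mtDNA units sampled at the germline
        transmission bottleneck.
    """

    name: str
    delta_embryo: float
    shift_a: float
    shift_b: float
    shift_sd: float
    wt_setpoint: int
    fecundity_base: float
    fecundity_theta: float
    fecundity_cost: float
    fecundity_ramp: float = 0.06
    delay_slope: float = 0.5
    f_max: float = 0.90
    bottleneck_b: int = 200

    def __post_init__(self) -> None:
        if self.shift_b > 0:
            raise ParameterError("shift_b must be <= 0 (negative frequency dependence)")
        if self.shift_sd < 0:
            raise ParameterError("shift_sd must be >= 0")
        if self.wt_setpoint <= 0:
            raise ParameterError("wt_setpoint must be a positive count")
        if not 0.0 < self.f_max < 1.0:
            raise ParameterError("f_max must lie strictly inside (0, 1)")
        if not 0.0 <= self.fecundity_theta <= 1.0:
            raise ParameterError("fecundity_theta must lie in [0, 1]")
        if not 0.0 <= self.fecundity_cost <= 1.0:
            raise ParameterError("fecundity_cost must lie in [0, 1]")
        if self.fecundity_ramp <= 0:
            raise ParameterError("fecundity_ramp must be > 0")
        if self.fecundity_base < 0 or self.delay_slope < 0:
            raise ParameterError("fecundity_base and delay_slope must be >= 0")
        if self.bottleneck_b < 1:
            raise ParameterError("bottleneck_b must be >= 1")

    def with_overrides(self, **kwargs) -> "ConditionPreset":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


def neutral_preset(name: str = "neutral", **overrides) -> ConditionPreset:
    """A preset with all shifts and costs switched off (drift only).

    Used as the null model in calibration tests; not a built-in condition.
    """
    base = dict(
        name=name,
        delta_embryo=0.0,
        shift_a=0.0,
        shift_b=0.0,
        shift_sd=0.0,
        wt_setpoint=200000,
        fecundity_base=5.0,
        fecundity_theta=1.0,
        fecundity_cost=0.0,
        fecundity_ramp=0.06,
        delay_slope=0.0,
        f_max=0.90,
        bottleneck_b=200,
    )
    base.update(overrides)
    return ConditionPreset(**base)


_FIELD_NAMES = {f.name for f in fields(ConditionPreset)} - {"name"}
_cache: dict | None = None


def _load_packaged() -> dict:
    global _cache
    if _cache is None:
        text = resources.files("mitoselect").joinpath("presets.yaml").read_text()
        _cache = yaml.safe_load(text)
    return _cache


def _build(name: str, record: dict) -> ConditionPreset:
    unknown = set(record) - _FIELD_NAMES
    if unknown:
        raise ParameterError(f"unknown preset keys for {name!r}: {sorted(unknown)}")
    missing = {"delta_embryo", "shift_a", "shift_b", "shift_sd", "wt_setpoint",
               "fecundity_base", "fecundity_theta", "fecundity_cost"} - set(record)
    if missing:
        raise ParameterError(f"preset {name!r} missing keys: {sorted(missing)}")
    return ConditionPreset(name=name, **record)


def builtin_presets() -> dict[str, ConditionPreset]:
    """All packaged presets, keyed by name."""
    data = _load_packaged()
    return {name: _build(name, rec) for name, rec in data["presets"].items()}


def get_preset(name: str) -> ConditionPreset:
    """Look up a built-in preset by name."""
    presets = builtin_presets()
    if name not in presets:
        raise ParameterError(
            f"unknown preset {name!r}; built-ins are {sorted(presets)}"
        )
    return presets[name]


def load_preset_file(path) -> dict[str, ConditionPreset]:
    """Load user-defined presets from a YAML file shaped like presets.yaml."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "presets" not in data:
        raise ParameterError("preset file must contain a top-level 'presets' map")
    return {name: _build(name, rec) for name, rec in data["presets"].items()}


def diet_concentrations() -> tuple[float, float]:
    """(control, restricted) bacterial lawn concentrations in cells/mL."""
    diet = _load_packaged()["diet"]
    return float(diet["control_cells_per_ml"]), float(diet["restricted_cells_per_ml"])


def diet_dilution_factor() -> float:
    """Fold-dilution of the control lawn that defines the restricted diet."""
    control, restricted = diet_concentrations()
    return control / restricted


def ddpcr_dilution(sample_type: str) -> float:
    """Lysate dilution factor used ahead of droplet generation."""
    table = _load_packaged()["ddpcr_dilutions"]
    if sample_type not in table:
        raise ParameterError(
            f"unknown sample type {sample_type!r}; known: {sorted(table)}"
        )
    return float(table[sample_type])
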