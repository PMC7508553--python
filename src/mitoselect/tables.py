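"""Validated CSV readers and writers for the pipeline's table formats.

Fixed dialect: header row, UTF-8, '.' decimal, no index column; floats are
written with 10 significant digits so round-trips are format-stable and
integers are bit-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = ["SCHEMAS", "read_table", "write_table"]

logger = logging.getLogger(__name__)

#: column name -> (dtype kind, is_frequency) per schema
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "lineage": {
        "lineage_id": ("int", False),
        "parent_f": ("float", True),
        "embryo_f": ("float", True),
        "l4_f": ("float", True),
        "adult_f": ("float", True),
    },
    "competition": {
        "line_id": ("int", False),
        "generation": ("int", False),
        "competed": ("bool", False),
        "pooled_f": ("float", True),
        "het_fraction": ("float", True),
        "n_genotyped": ("int", False),
        "terminated": ("bool", False),
    },
    "droplets": {
        "reaction_id": ("int", False),
        "n_total": ("int", False),
        "n_neg": ("int", False),
        "n_wt_only": ("int", False),
        "n_mut_only": ("int", False),
        "n_double": ("int", False),
    },
}

_CASTS = {"int": "int64", "float": "float64", "bool": "bool"}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` citing the first out-of-range row.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    table = pd.read_csv(path)
    missing = [c for c in spec if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    table = table[list(spec)]
    for col, (kind, is_freq) in spec.items():
        try:
            table[col] = table[col].astype(_CASTS[kind])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: column {col!r} is not {kind}: {exc}") from None
        if is_freq:
            vals = table[col].to_numpy(float)
            bad = np.nonzero(~np.isnan(vals) & ((vals < 0.0) | (vals > 1.0)))[0]
            if bad.size:
                raise ValidationError(
                    f"{path}: {col}={vals[bad[0]]} out of [0, 1] at row {int(bad[0])}"
                )
    logger.info("read %d row(s) from %s (schema %s)", len(table), path, schema)
    return table


def write_table(table: pd.DataFrame, path, schema: str) -> Path:
    """Write a table in the fixed CSV dialect after schema validation."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in table.columns]
    if missing:
        raise SchemaError(f"cannot write: missing column(s) {missing} for schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[list(spec)].to_csv(path, index=False, float_format="%.10g")
    logger.info("wrote %d row(s) to %s (schema %s)", len(table), path, schema)
    return path
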