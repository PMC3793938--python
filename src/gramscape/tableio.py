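"""Schema-checked delimited-text tables and YAML run configuration.

CSV with unit-annotated column names is the interchange format for species
tables, climate drivers and landscape tables; YAML holds run configurations.
Floats round-trip at full double precision (%.17g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "TableSchema",
    "SchemaError",
    "read_table",
    "write_table",
    "SPECIES_SCHEMA",
    "CLIMATE_SCHEMA",
    "LANDSCAPE_SCHEMA",
    "RunConfig",
    "load_config",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Declared column set of a delimited table.

    ``required`` columns must be present; ``optional`` ones may be; any
    other column is an error.  Column names carry their units.
    """

    name: str
    required: tuple
    optional: tuple = ()

    def validate(self, df: pd.DataFrame) -> None:
        cols = list(df.columns)
        missing = [c for c in self.required if c not in cols]
        extra = [c for c in cols if c not in self.required + self.optional]
        if missing:
            raise SchemaError(f"{self.name}: missing column(s) {missing}")
        if extra:
            raise SchemaError(f"{self.name}: unexpected column(s) {extra}")


SPECIES_SCHEMA = TableSchema(
    name="species",
    required=("species", "sla_cm2_g", "h_cm", "lls_Cday", "td_m2"),
    optional=("code", "cn_opt_gC_gN", "amax_protein", "umax", "r_maint",
              "cn_target", "sra"),
)

CLIMATE_SCHEMA = TableSchema(
    name="climate",
    required=("day", "par_MJ_m2", "temp_C"),
)

LANDSCAPE_SCHEMA = TableSchema(
    name="landscape",
    required=("species", "n_level", "sla", "h", "lls", "td0",
              "i_sla", "i_h", "i_lls", "i_td0",
              "performance", "mean_cn", "status"),
    optional=("mean_f_int", "mean_net_photo", "mean_su", "nue", "rue",
              "mean_p", "mean_q", "sra"),
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a CSV table and validate it against the schema."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    schema.validate(df)
    return df


def write_table(df: pd.DataFrame, path, schema: TableSchema | None = None) -> None:
    """Write a CSV table (full double precision) after schema validation."""
    if schema is not None:
        schema.validate(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    species_table: str | None = None    # path; None -> synthesise archetypes
    n_species: int = 2
    n_levels: tuple = (360.0, 120.0)
    fraction: float = 0.30
    steps: int = 5
    years: int = 2
    spin_tol: float = 1e-3
    spin_max_cycles: int = 20
    climate: dict = field(default_factory=dict)
    management: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    _KNOWN = ("out_dir", "species_table", "n_species", "n_levels", "fraction",
              "steps", "years", "spin_tol", "spin_max_cycles", "climate",
              "management", "seed", "log_level")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("run config must be a mapping")
    unknown = [k for k in raw if k not in RunConfig._KNOWN]
    if unknown:
        raise SchemaError(f"unknown config key(s) {unknown}")
    if "out_dir" not in raw:
        raise SchemaError("config requires out_dir")
    if "n_levels" in raw:
        raw["n_levels"] = tuple(float(x) for x in raw["n_levels"])
    return RunConfig(**raw)
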