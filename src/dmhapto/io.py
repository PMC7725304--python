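"""Delimited-text readers/writers, schema validation, and run configuration.

All tabular artifacts are plain TSV with a header row and '.' decimal
separator, locale-independent.  Each record type has a declared schema;
violations raise :class:`~dmhapto.exceptions.SchemaError` naming the
offending row/column.  Run configuration is a JSON file mirroring the
module parameter names; omitted keys resolve to the model defaults and
unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import __version__
from .ap_model import ModelParams
from .exceptions import ConfigError, SchemaError

__all__ = [
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "RunConfig",
    "load_config",
    "save_config",
    "write_provenance",
]


def _nonneg(col: str) -> Callable[[pd.Series], pd.Series]:
    def check(s: pd.Series) -> pd.Series:
        return s < 0

    check.message = f"{col} must be >= 0"  # type: ignore[attr-defined]
    return check


def _in_unit_interval(col: str) -> Callable[[pd.Series], pd.Series]:
    def check(s: pd.Series) -> pd.Series:
        return (s < 0) | (s > 1)

    check.message = f"{col} must lie in [0, 1]"  # type: ignore[attr-defined]
    return check


#: Declared schemas: fixed numeric columns and per-column validity checks.
TABLE_SCHEMAS: dict[str, dict[str, Any]] = {
    "trajectory": {
        "columns": ["t", "K_cell", "K_apo", "A_cell", "A_apo", "dP", "rel_dP", "trigger"],
        "checks": {
            "K_cell": _nonneg("K_cell"),
            "K_apo": _nonneg("K_apo"),
            "A_cell": _nonneg("A_cell"),
            "A_apo": _nonneg("A_apo"),
        },
    },
    "ap_events": {
        "columns": ["stimulus_time", "fired", "rel_dP_at_stimulus", "skipped"],
        "checks": {},
    },
    "activation_curve": {
        "columns": ["cell_id", "V_mV", "rel_po"],
        "checks": {},
    },
    "iv_dataset": {
        "columns": ["cell_id", "condition", "V_mV", "I"],
        "checks": {},
        "string_columns": ["condition"],
    },
    "vhalf_by_ph": {
        "columns": ["pH", "V_half_mV"],
        "checks": {},
    },
    "de_table": {
        "columns": ["gene_id", "log2fc", "padj", "focal_counts"],
        "checks": {
            "padj": _in_unit_interval("padj"),
            "focal_counts": _nonneg("focal_counts"),
        },
        "string_columns": ["gene_id"],
    },
}


def _validate_numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} "
            f"in column {col!r}, data row {row + 1}"
        )
    return coerced


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV against a declared schema.

    Raises :class:`SchemaError` for missing/extra columns, non-numeric
    cells, or values violating a column check, with row/column location.
    """
    path = Path(path)
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t")
    expected = spec["columns"]
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise SchemaError(
            f"{path}: columns {list(df.columns)} do not match schema "
            f"{schema!r} {expected} (missing {missing}, extra {extra})"
        )
    strings = set(spec.get("string_columns", []))
    for col in expected:
        if col in strings:
            continue
        df[col] = _validate_numeric(df, col, path)
    for col, check in spec["checks"].items():
        bad = check(df[col].dropna())
        if bad.any():
            row = int(bad[bad].index[0])
            raise SchemaError(
                f"{path}: {check.message} (column {col!r}, data row {row + 1}, "
                f"value {df[col].iloc[row]!r})"
            )
    return df


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue expression TSV (first column gene id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: need a gene id column plus >= 2 tissues")
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicated gene id {dup!r}")
    df = df.set_index(gene_col)
    for col in df.columns:
        df[col] = _validate_numeric(df.reset_index(), col, path).values
    if (df.values < 0).any():
        gene = df.index[np.where(df.values < 0)[0][0]]
        raise SchemaError(f"{path}: negative expression value for gene {gene!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a TSV with header; round-trips finite values losslessly."""
    path = Path(path)
    if schema is not None:
        expected = TABLE_SCHEMAS[schema]["columns"]
        if list(df.columns) != expected:
            raise SchemaError(
                f"refusing to write {path}: columns {list(df.columns)} "
                f"do not match schema {schema!r} {expected}"
            )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


_GATING_DEFAULTS: dict[str, float] = {"a": 0.6, "rt_over_f": 25.2}
_SPECIFICITY_DEFAULTS: dict[str, Any] = {
    "q_threshold": 3.9,
    "tail_area": 0.01,
    "lfc_min": 1.0,
    "padj_max": 0.001,
    "min_counts": 50.0,
    "expr_min": 20.0,
    "pseudocount": 1e-3,
    "focal": "hair",
}
_SYNTHETIC_DEFAULTS: dict[str, Any] = {
    "n_genes": 2000,
    "n_planted": 100,
    "fold": 16.0,
    "n_replicates": 3,
    "dispersion": 0.1,
    "log_mean": 3.0,
    "log_sigma": 1.0,
}


@dataclasses.dataclass
class RunConfig:
    """Fully-resolved configuration for a reproducible run."""

    hapto_model: ModelParams = dataclasses.field(default_factory=ModelParams)
    channel_gating: dict = dataclasses.field(
        default_factory=lambda: dict(_GATING_DEFAULTS)
    )
    tissue_specificity: dict = dataclasses.field(
        default_factory=lambda: dict(_SPECIFICITY_DEFAULTS)
    )
    synthetic_data: dict = dataclasses.field(
        default_factory=lambda: dict(_SYNTHETIC_DEFAULTS)
    )
    seed: int = 0
    log_level: str = "info"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.hapto_model)
        return {
            "hapto_model": d,
            "channel_gating": dict(self.channel_gating),
            "tissue_specificity": dict(self.tissue_specificity),
            "synthetic_data": dict(self.synthetic_data),
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _merged(defaults: dict, block: dict, name: str) -> dict:
    unknown = set(block) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(block)
    return out


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON run configuration; omitted keys take the model defaults.

    Unknown keys raise :class:`ConfigError` naming the offending key; model
    invariants (e.g. 0 < beta <= 1) are enforced at construction.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text().strip()
        if text:
            try:
                raw = json.loads(text)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a JSON object")

    known_top = {
        "hapto_model", "channel_gating", "tissue_specificity",
        "synthetic_data", "seed", "log_level",
    }
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    model_block = raw.get("hapto_model", {})
    model_fields = {f.name for f in dataclasses.fields(ModelParams)}
    bad = set(model_block) - model_fields
    if bad:
        raise ConfigError(f"unknown key(s) in 'hapto_model': {sorted(bad)}")
    try:
        model = ModelParams(**model_block)
    except ValueError as exc:
        raise ConfigError(f"invalid 'hapto_model' parameter: {exc}") from exc

    return RunConfig(
        hapto_model=model,
        channel_gating=_merged(_GATING_DEFAULTS, raw.get("channel_gating", {}),
                               "channel_gating"),
        tissue_specificity=_merged(_SPECIFICITY_DEFAULTS,
                                   raw.get("tissue_specificity", {}),
                                   "tissue_specificity"),
        synthetic_data=_merged(_SYNTHETIC_DEFAULTS, raw.get("synthetic_data", {}),
                               "synthetic_data"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "info")),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_provenance(
    out_path: str | Path,
    config: RunConfig,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
) -> None:
    """Echo the resolved config, input digests, tool version, and seed.

    Written next to every CLI run's outputs so deterministic paths can be
    reproduced bitwise and stochastic ones distributionally.
    """
    record = {
        "tool": "dmhapto",
        "version": __version__,
        "seed": config.seed if seed is None else seed,
        "config": config.to_dict(),
        "inputs": {
            str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    Path(out_path).write_text(json.dumps(record, indent=2) + "\n")
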