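"""File formats, configuration and reporting.

Concentration–time data travel as tidy CSV with the columns
``compound, analyte, compartment, time_h, conc_uM, replicate, cells,
mesh`` (plus optional ``dose_uM``); times in hours, concentrations in µM.
Run configurations are YAML validated by a pydantic schema that rejects
unknown keys, so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from pydantic import ValidationError as PydanticValidationError

from .exceptions import ValidationError

__all__ = ["REQUIRED_COLUMNS", "read_concentration_csv",
           "write_concentration_csv", "RunConfig", "load_run_config",
           "report_table", "render_report_text"]

REQUIRED_COLUMNS = ["compound", "analyte", "compartment", "time_h",
                    "conc_uM", "replicate", "cells", "mesh"]

_ANALYTES = {"parent", "metabolite"}
_COMPARTMENTS = {"media", "insert"}


def read_concentration_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a tidy concentration–time CSV.

    Checks the header, value domains (non-negative times and
    concentrations, known analyte/compartment labels) and uniqueness of
    the (compound, analyte, compartment, cells, mesh, dose, time,
    replicate) key.  Raises :class:`ValidationError` naming the offending
    column or rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if (df["time_h"] < 0).any():
        raise ValidationError("column time_h contains negative values")
    if (df["conc_uM"] < 0).any():
        raise ValidationError("column conc_uM contains negative values")
    bad = set(df["analyte"]) - _ANALYTES
    if bad:
        raise ValidationError(f"column analyte has unknown labels: "
                              f"{sorted(bad)}")
    bad = set(df["compartment"]) - _COMPARTMENTS
    if bad:
        raise ValidationError(f"column compartment has unknown labels: "
                              f"{sorted(bad)}")
    key = [c for c in ("compound", "analyte", "compartment", "cells",
                       "mesh", "dose_uM", "time_h", "replicate")
           if c in df.columns]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValidationError(
            f"{int(dup.sum())} duplicate observation keys on {key}")
    return df


def write_concentration_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a tidy concentration table (stable column order, no index)."""
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    """Metabolism-model point values with free/fixed split for fitting."""

    parent_a_max: float = 0.01
    metabolite_a_max: float = 0.0
    alpha: float
    beta: float
    cl_per_cell: float = 0.0
    metabolite_fraction: float = 0.0
    scaling_exponent: float = 0.0
    free: List[str] = []


class ExperimentBlock(_Strict):
    name: str                       # rosiglitazone | diclofenac | testosterone
    noise_cv: float = 0.10
    replicates: int = 3


class IviveBlock(_Strict):
    cl_per_cell: float
    activity_ratio: float
    f_u: Union[float, List[float]]
    f_u_inc: Optional[float] = None
    log_pd: Optional[float] = None
    v_r: float = 0.0025
    v_insert: float = 1.0
    hpgl: float = 99.0
    liver_per_kg: float = 25.7
    q_hepatic: float = 20.7
    compound: Optional[str] = None


class RunConfig(_Strict):
    """Top-level YAML schema; unknown keys are rejected."""

    seed: int = 0
    experiment: Optional[ExperimentBlock] = None
    model: Optional[ModelBlock] = None
    ivive: Optional[IviveBlock] = None
    output: Optional[str] = None
    verbosity: str = "info"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: Union[str, Path]) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
        return RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        raise ValidationError(f"invalid run config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed YAML {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_table(results: Dict[str, dict],
                 display_decimals: int = 4) -> dict:
    """Machine-readable report: full-precision values plus a display
    rendering rounded the way the benchmark tables print."""
    report = {"sections": {}}
    for section, values in results.items():
        rows = {}
        for key, value in values.items():
            if isinstance(value, float):
                rows[key] = {"value": value,
                             "display": round(value, display_decimals)}
            else:
                rows[key] = {"value": value, "display": value}
        report["sections"][section] = rows
    return report


def render_report_text(report: dict) -> str:
    """Aligned plain-text rendering of :func:`report_table` output."""
    lines = []
    for section, rows in report.get("sections", {}).items():
        lines.append(section)
        lines.append("-" * len(section))
        if rows:
            width = max(len(k) for k in rows)
            for key, cell in rows.items():
                lines.append(f"{key.ljust(width)}  {cell['display']}")
        lines.append("")
    return "\n".join(lines)
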