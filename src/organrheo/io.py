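"""Delimited-table readers/writers, run configuration and stage logging.

Tables are plain comma- or tab-separated text with a header row naming the
columns (``frequency_hz`` / ``strain_pct`` / ``time_s`` for the abscissa and
``storage_pa`` / ``loss_pa`` / ``stress_pa`` for the measurements; ``_kpa``
variants are accepted and converted).  An optional units row directly under
the header is skipped.  All values are normalised to Pa internally; kPa
appears only in written reports.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .preprocess import FrequencySweep, StrainSweep
from .relaxation import RelaxationTrace

__all__ = [
    "RunConfig",
    "SweepParseError",
    "read_sweep_table",
    "write_sweep_table",
    "write_report",
    "stage_log",
]

logger = logging.getLogger("organrheo")
if not logger.handlers:  # one structured line per stage, to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class RunConfig(BaseModel):
    """Validated knobs of one analysis run; embedded in every report."""

    convention: Literal["hz", "rad"] = "hz"
    lve_tolerance: float = Field(0.05, gt=0, lt=0.5)
    inertial_drop_tolerance: float = Field(0.05, gt=0, lt=1)
    nominal_rounding: bool = True
    rounding_decimals: int = Field(2, ge=0)
    seed: int = Field(0, ge=0)
    organ: Optional[str] = None
    input_path: Optional[str] = None
    output_path: Optional[str] = None


class SweepParseError(ValueError):
    """Malformed sweep table; message names the offending row/column."""


_X_COLUMN = {"frequency": "frequency_hz", "strain": "strain_pct", "relaxation": "time_s"}
_Y_COLUMNS = {
    "frequency": ("storage_pa", "loss_pa"),
    "strain": ("storage_pa", "loss_pa"),
    "relaxation": ("stress_pa",),
}


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in list(df.columns):
        if col.endswith("_kpa"):
            base = col[:-4] + "_pa"
            df[base] = pd.to_numeric(df[col], errors="coerce") * 1e3
            df = df.drop(columns=[col])
    return df


def read_sweep_table(path, kind: str, strain_step: float = 0.001):
    """Parse a sweep/trace table into its validated domain object.

    kind: ``"frequency"`` -> :class:`FrequencySweep`, ``"strain"`` ->
    :class:`StrainSweep`, ``"relaxation"`` -> :class:`RelaxationTrace`
    (measured stress divided by ``strain_step``).
    """
    if kind not in _X_COLUMN:
        raise ValueError(f"kind must be one of {sorted(_X_COLUMN)}, got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df = _normalise_columns(df)
    # optional units row: every cell non-numeric directly under the header
    if len(df) and df.iloc[0].map(lambda v: pd.to_numeric(v, errors="coerce")).isna().all():
        df = df.iloc[1:].reset_index(drop=True)

    xcol = _X_COLUMN[kind]
    needed = (xcol, *_Y_COLUMNS[kind])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SweepParseError(f"{path.name}: missing column(s) {missing} (kind={kind})")
    for col in needed:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SweepParseError(
                f"{path.name}: non-numeric value {df[col][row]!r} in column {col!r}, data row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise SweepParseError(f"{path.name}: empty cell in column {col!r}, data row {row}")
        df[col] = numeric
    if df[xcol].duplicated().any():
        dup = df[xcol][df[xcol].duplicated()].iloc[0]
        raise SweepParseError(f"{path.name}: duplicated {xcol} value {dup}")
    df = df.sort_values(xcol).reset_index(drop=True)

    try:
        if kind == "frequency":
            kwargs = {}
            for opt in ("strain_amplitude", "contact_force", "axial_strain"):
                if opt in df.columns:
                    kwargs[opt] = float(df[opt].iloc[0])
            return FrequencySweep(
                frequencies=df[xcol].to_numpy(),
                storage=df["storage_pa"].to_numpy(),
                loss=df["loss_pa"].to_numpy(),
                **kwargs,
            )
        if kind == "strain":
            kwargs = {"frequency": float(df["frequency_hz"].iloc[0])} if "frequency_hz" in df.columns else {}
            return StrainSweep(
                strain_amplitudes=df[xcol].to_numpy(),
                storage=df["storage_pa"].to_numpy(),
                loss=df["loss_pa"].to_numpy(),
                **kwargs,
            )
        return RelaxationTrace(
            times=df[xcol].to_numpy(),
            relaxation_modulus=df["stress_pa"].to_numpy() / strain_step,
            strain_step=strain_step,
        )
    except ValueError as exc:
        raise SweepParseError(f"{path.name}: {exc}") from exc


def write_sweep_table(obj, path, sep: str = ",") -> None:
    """Write a sweep/trace object as a delimited table readable by read_sweep_table."""
    path = Path(path)
    if isinstance(obj, FrequencySweep):
        df = pd.DataFrame(
            {"frequency_hz": obj.frequencies, "storage_pa": obj.storage, "loss_pa": obj.loss}
        )
        df["strain_amplitude"] = obj.strain_amplitude
        if obj.contact_force is not None:
            df["contact_force"] = obj.contact_force
        if obj.axial_strain is not None:
            df["axial_strain"] = obj.axial_strain
    elif isinstance(obj, StrainSweep):
        df = pd.DataFrame(
            {
                "strain_pct": obj.strain_amplitudes,
                "storage_pa": obj.storage,
                "loss_pa": obj.loss,
                "frequency_hz": obj.frequency,
            }
        )
    elif isinstance(obj, RelaxationTrace):
        df = pd.DataFrame(
            {"time_s": obj.times, "stress_pa": obj.relaxation_modulus * obj.strain_step}
        )
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def _metadata(config: Optional[RunConfig]) -> dict:
    cfg = (config or RunConfig()).model_dump()
    return {"version": __version__, "config": cfg, "convention": cfg["convention"], "seed": cfg["seed"]}


def write_report(results, path, format: str = "json", config: Optional[RunConfig] = None) -> None:
    """Write analysis results with a metadata block (config, seed, version).

    ``results`` may be a DataFrame, a mapping, or a list of mappings; columns
    keep their given order.  JSON nests the metadata; CSV carries it as
    leading ``#`` comment lines so the numeric payload is identical in both.
    """
    path = Path(path)
    meta = _metadata(config)
    if isinstance(results, pd.DataFrame):
        table = results
    elif isinstance(results, dict):
        table = pd.DataFrame([results]) if results else pd.DataFrame()
    else:
        table = pd.DataFrame(list(results))
    if format == "json":
        payload = {"metadata": meta, "results": table.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    elif format == "csv":
        with open(path, "w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}: {json.dumps(value, default=float)}\n")
            table.to_csv(fh, index=False)
    else:
        raise ValueError("format must be 'csv' or 'json'")


def stage_log(stage: str, **info) -> None:
    """One structured log line per pipeline stage, to stderr."""
    logger.info("%s %s", stage, json.dumps(info, default=str, sort_keys=True))


def input_digest(arrays) -> str:
    """Short deterministic hash of numeric inputs, for provenance logs."""
    import hashlib

    h = hashlib.sha256()
    for arr in arrays:
        h.update(np.ascontiguousarray(np.asarray(arr, float)).tobytes())
    return h.hexdigest()[:12]
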