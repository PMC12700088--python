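"""Delimited-table readers/writers, run configuration and output manifest.

All tabular IO is tab-separated with a required header (comma-separated
accepted via ``sep=","``).  Values are written with 4 decimal places; a
full-precision sidecar can be requested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .network import SPECIES, ModelDefinition, ParameterSet, SpeciesState

TIME_COLUMN = "time (hours)"


@dataclass
class TimeSeriesData:
    """Observed or synthetic relative concentrations on a time grid.

    The frame has a time column plus one column per observed species;
    blanks are NaN.  Times are strictly increasing and include 0 h.
    """

    frame: pd.DataFrame
    time_column: str = TIME_COLUMN

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, time_column: str = TIME_COLUMN
    ) -> "TimeSeriesData":
        if time_column not in frame.columns:
            raise ParseError(f"missing time column {time_column!r}")
        if frame.empty:
            raise ParseError("table contains a header but no data rows")
        frame = frame.sort_values(time_column).reset_index(drop=True)
        times = frame[time_column].to_numpy(float)
        if np.unique(times).size != times.size:
            dupes = sorted(set(times[pd.Series(times).duplicated().to_numpy()]))
            raise ParseError(f"duplicate times: {dupes}")
        if not np.any(np.isclose(times, 0.0)):
            raise ParseError("0 h row is required")
        return cls(frame=frame, time_column=time_column)

    @property
    def times(self) -> np.ndarray:
        return self.frame[self.time_column].to_numpy(float)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != self.time_column)

    def values(self, column: str) -> np.ndarray:
        if column not in self.frame.columns:
            raise ValidationError(f"missing column {column!r}")
        return self.frame[column].to_numpy(float)


def read_timeseries(path, sep: str = "\t") -> TimeSeriesData:
    """Parse a time-series table with descriptive, row-numbered errors."""
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.columns.size < 2:
        raise ParseError(f"{path}: expected a delimited header with >= 2 columns")
    parsed = {}
    for column in raw.columns:
        values = []
        for row_number, cell in enumerate(raw[column], start=2):  # 1 = header
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                values.append(np.nan)
                continue
            cell = str(cell).strip()
            if cell == "":
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} in column "
                    f"{column!r}, row {row_number}"
                ) from None
        parsed[column] = values
    frame = pd.DataFrame(parsed)
    try:
        return TimeSeriesData.from_frame(frame)
    except ParseError as err:
        raise ParseError(f"{path}: {err}") from None


@dataclass
class InitialConditions:
    """Parsed initial-condition table: state, HRE totals, boundary O2."""

    state: SpeciesState
    hre1: int
    hre2: int
    o2: float = 1.0


#: Species whose initial value must be given explicitly.
_REQUIRED_INITIAL = (
    "HIF1A_mrna",
    "HIF2A_mrna",
    "HIF1A_protein",
    "HIF2A_protein",
    "PHD_protein",
    "HIF1B",
    "Gene_mRNA",
    "HRE1",
    "HRE2",
)

#: Accepted but ignored rows: totals are derived, never initialized.
_DERIVED_ROWS = ("HIF1A_protein_total", "HIF2A_protein_total")
_O2_ALIASES = ("O2", "O_2")


def read_initial_conditions(path, sep: str = "\t") -> InitialConditions:
    """Parse a two-column species/value table (final-model layout)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.columns.size < 2:
        raise ParseError(f"{path}: expected two columns (species, value)")
    state = SpeciesState({name: 0.0 for name in SPECIES})
    seen: set[str] = set()
    o2 = 1.0
    for row_number, (name, value) in enumerate(
        zip(raw.iloc[:, 0], raw.iloc[:, 1]), start=2
    ):
        name = str(name).strip()
        try:
            value = float(value)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric value {value!r} for {name!r}, row {row_number}"
            ) from None
        if name in _O2_ALIASES:
            o2 = value
        elif name in _DERIVED_ROWS:
            pass  # derived by algebraic rule, not independently initialized
        elif name in SPECIES:
            state[name] = value
            seen.add(name)
        else:
            raise ParseError(f"{path}: unknown species {name!r}, row {row_number}")
    missing = [name for name in _REQUIRED_INITIAL if name not in seen]
    if missing:
        raise ParseError(f"{path}: missing required species {missing}")
    state.validate(SPECIES)
    return InitialConditions(
        state=state,
        hre1=int(round(state["HRE1"])),
        hre2=int(round(state["HRE2"])),
        o2=o2,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(
    frame: pd.DataFrame,
    path,
    sep: str = "\t",
    precision: int = 4,
    sidecar: bool = False,
) -> Path:
    """Write a table at fixed precision; optionally also a full-precision
    ``<stem>.full.tsv`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=False, float_format=f"%.{precision}f")
    if sidecar:
        frame.to_csv(
            path.with_suffix(".full.tsv"), sep=sep, index=False, float_format="%.17g"
        )
    return path


def write_params(
    params: Mapping[str, float], path, free: Sequence[str] = (), sep: str = "\t"
) -> Path:
    frame = pd.DataFrame(
        {
            "name": list(params),
            "value": [params[n] for n in params],
            "status": ["free" if n in set(free) else "frozen" for n in params],
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def read_params(path, sep: str = "\t") -> ParameterSet:
    frame = pd.read_csv(path, sep=sep)
    if "name" not in frame.columns or "value" not in frame.columns:
        raise ParseError(f"{path}: parameter table needs 'name' and 'value' columns")
    return ParameterSet(zip(frame["name"], frame["value"].astype(float)))


def model_to_yaml(model: ModelDefinition, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))
    return path


def model_from_yaml(path) -> ModelDefinition:
    return ModelDefinition.from_dict(yaml.safe_load(Path(path).read_text()))


def write_outputs(results: Mapping[str, object], out_dir) -> pd.DataFrame:
    """Write every result (DataFrame -> TSV, mapping -> JSON) under
    ``out_dir`` with deterministic names; return the checksum manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            target = out_dir / f"{name}.tsv"
            write_table(obj, target)
        elif isinstance(obj, Mapping):
            target = out_dir / f"{name}.json"
            target.write_text(json.dumps(dict(obj), indent=2, sort_keys=True))
        else:
            raise ValidationError(f"cannot serialize result {name!r}: {type(obj)}")
        digest = hashlib.sha256(target.read_bytes()).hexdigest()
        entries.append(
            {"artifact": target.name, "sha256": digest, "bytes": target.stat().st_size}
        )
    manifest = pd.DataFrame(entries)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_RUNCONFIG_KEYS = {"paths", "scenario", "fit", "logging_level", "seed"}


@dataclass
class RunConfig:
    """Structured run configuration loaded from YAML.

    Unknown top-level keys are rejected by name; referenced input files
    must exist at load time.
    """

    paths: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    logging_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        for key, value in config.paths.items():
            if key.startswith("out"):
                continue
            if not Path(value).exists():
                raise ValidationError(f"config path {key!r} does not exist: {value}")
        return config
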