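"""Reading and writing assay tables, configs and reports.

All assay inputs are plain CSV (comma-separated, UTF-8, header row, "."
decimal).  Assay-level metadata (host density, MOI, phage id, reference
titer) travels in a JSON sidecar named ``<table>.meta.json`` next to the
table rather than in magic header rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SchemaError
from .series import KineticSeries

#: Required (and optional) columns per assay kind.
TABLE_SCHEMAS = {
    "hostrange": {
        "required": ["isolate_id", "group", "phage_id", "spot", "pfu_test", "pfu_host"],
        "optional": [],
        "numeric": ["spot", "pfu_test", "pfu_host"],
    },
    "adsorption": {
        "required": ["time", "value"],
        "optional": ["replicate"],
        "numeric": ["time", "value"],
    },
    "onestep": {
        "required": ["time", "value"],
        "optional": ["replicate"],
        "numeric": ["time", "value"],
    },
    "killing": {
        "required": ["time", "value"],
        "optional": ["replicate"],
        "numeric": ["time", "value"],
    },
    "stability": {
        "required": ["condition", "titer"],
        "optional": ["replicate"],
        "numeric": ["condition", "titer"],
    },
}


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def read_assay_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one assay table; sidecar metadata lands in ``df.attrs``.

    Raises :class:`~phagechar.errors.SchemaError` naming the file, row and
    column for missing columns or non-numeric cells.
    """
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown assay kind {kind!r}; expected one of {tuple(TABLE_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise SchemaError("input table not found", path=path)
    schema = TABLE_SCHEMAS[kind]
    df = pd.read_csv(path)
    for col in schema["required"]:
        if col not in df.columns:
            raise SchemaError("missing required column", path=path, column=col)
    for col in schema["numeric"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"non-numeric cell {df[col].iloc[row]!r}", path=path, row=row, column=col
            )
        df[col] = coerced
    meta = sidecar_path(path)
    df.attrs["metadata"] = json.loads(meta.read_text()) if meta.exists() else {}
    df.attrs["kind"] = kind
    return df


def write_assay_table(df: pd.DataFrame, path, kind: str, metadata: dict | None = None) -> Path:
    """Write a table (and optional sidecar metadata); round-trip stable."""
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown assay kind {kind!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    metadata = metadata if metadata is not None else df.attrs.get("metadata")
    if metadata:
        sidecar_path(path).write_text(json.dumps(metadata, indent=1, sort_keys=True))
    return path


def kinetic_series_from_frame(df: pd.DataFrame, kind: str) -> list[KineticSeries]:
    """Split a long-format kinetic table into one series per replicate."""
    metadata = dict(df.attrs.get("metadata", {}))
    groups = df.groupby("replicate") if "replicate" in df.columns else [(0, df)]
    out = []
    for rep, block in groups:
        block = block.sort_values("time")
        md = dict(metadata)
        md["replicate"] = rep
        out.append(
            KineticSeries(
                assay_kind=kind,
                times=block["time"].to_numpy(),
                values=block["value"].to_numpy(),
                metadata=md,
            )
        )
    return out


def frame_from_kinetic_series(series_list) -> pd.DataFrame:
    """Long-format frame (time, value, replicate) from one or more series."""
    rows = []
    for i, s in enumerate(series_list):
        rep = s.metadata.get("replicate", i)
        for t, v in zip(s.times, s.values):
            rows.append({"time": t, "value": v, "replicate": rep})
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``inputs`` maps stage names (``hostrange``, ``adsorption``, ``onestep``,
    ``stability_pH``, ``stability_temperature``) to CSV paths.  In demo mode
    every input is generated synthetically from the built-in presets instead.
    """

    inputs: dict = field(default_factory=dict)
    seed: int = 1
    outdir: str | None = None
    demo: bool = False
    scenario_variant: str = "normalized"
    overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.demo and not self.inputs:
            raise InvalidParameterError(
                "empty config: give input tables or set demo=true to run on synthetic fixtures"
            )
        for stage, path in self.inputs.items():
            if not Path(path).exists():
                raise SchemaError(f"input for stage {stage!r} not found", path=path)

    def canonical_json(self) -> str:
        return json.dumps(
            {
                "inputs": {k: str(v) for k, v in sorted(self.inputs.items())},
                "seed": self.seed,
                "demo": self.demo,
                "scenario_variant": self.scenario_variant,
                "overrides": self.overrides,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {"inputs", "seed", "outdir", "demo", "scenario_variant", "overrides"}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)}", path=path)
        return cls(**raw)
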