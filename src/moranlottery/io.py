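"""Configuration files, run manifests and tabular output.

Plain JSON/YAML for configuration and summaries, CSV for series — there is
no standard binary format for these objects and plain text keeps seeded
runs byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Type

import pandas as pd
import yaml

from .config import CommunityConfig, TwoSpeciesConfig

__all__ = ["RunManifest", "load_config", "write_outputs", "write_table", "write_json"]

_FLOAT_FMT = "%.12g"


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output file set."""

    subcommand: str
    parameters: dict[str, Any]
    seed: int
    version: str
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    def start(self) -> None:
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def finish(self) -> None:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _known_fields(cls: Type) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def load_config(
    path: str | Path,
    kind: Type[TwoSpeciesConfig] | Type[CommunityConfig] = TwoSpeciesConfig,
    overrides: dict[str, Any] | None = None,
) -> TwoSpeciesConfig | CommunityConfig:
    """Load and validate a parameter file (JSON or YAML).

    Unknown keys raise with the offending names; constraint violations
    (N < 2, delta <= 0, nu outside [0, 1], Q < 1 ...) raise naming the
    field, via the config classes' own validation.  ``overrides`` (e.g.
    CLI flags) take precedence over file values.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:  # sniff: JSON is a YAML subset, so YAML handles both
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameters")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    known = _known_fields(kind)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(
            f"{path}: unknown parameter(s) {', '.join(unknown)}; "
            f"known: {', '.join(sorted(known))}"
        )
    return kind(**raw)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with 12 significant digits and stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(o: Any):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_outputs(
    tables: dict[str, pd.DataFrame],
    summaries: dict[str, Any],
    manifest: RunManifest,
    out_dir: str | Path,
) -> list[Path]:
    """Write CSV tables and JSON summaries plus the manifest; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        written.append(write_table(df, out_dir / f"{name}.csv"))
    for name, obj in summaries.items():
        written.append(write_json(obj, out_dir / f"{name}.json"))
    manifest.outputs = [str(p) for p in written]
    manifest.finish()
    written.append(write_json(manifest.to_dict(), out_dir / "manifest.json"))
    return written
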