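"""Run configuration and delimited-table output shared by the CLI commands.

Configs are flat key-value mappings (YAML files or command-line flags).
Every output table carries '# key = value' header comment lines echoing the
configuration and seeds that produced it, so any published file can be
regenerated from its own header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

__all__ = ["RunConfig", "parse_config", "write_table", "read_table"]


@dataclass
class RunConfig:
    """A validated flat configuration with provenance per key."""

    subcommand: str
    values: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # flag|file|default

    def get(self, key: str, default: Any = None) -> Any:
        return self.values.get(key, default)

    def to_header(self) -> dict[str, Any]:
        out = {"subcommand": self.subcommand}
        out.update(self.values)
        return out


def parse_config(
    subcommand: str,
    defaults: Mapping[str, Any],
    config_file: Optional[str] = None,
    flags: Optional[Mapping[str, Any]] = None,
    validators: Optional[Mapping[str, Any]] = None,
) -> RunConfig:
    """Merge defaults < config file < explicit flags into a RunConfig.

    Unknown keys in the config file are rejected.  ``validators`` maps key
    names to callables raising ValueError with the violated constraint.
    """
    values = dict(defaults)
    provenance = {k: "default" for k in values}
    if config_file:
        loaded = yaml.safe_load(Path(config_file).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a flat key-value mapping")
        unknown = set(loaded) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in loaded.items():
            values[k] = v
            provenance[k] = "file"
    if flags:
        for k, v in flags.items():
            if v is None:
                continue
            if k not in values:
                raise ValueError(f"unknown flag {k!r}")
            values[k] = v
            provenance[k] = "flag"
    if validators:
        for k, check in validators.items():
            check(values.get(k), values)
    return RunConfig(subcommand, values, provenance)


def write_table(
    records, path, header: Optional[Mapping[str, Any]] = None
) -> None:
    """Write records as delimited text with a '#'-commented config header.

    Floats are serialised at 17 significant digits so a read-back is
    bit-faithful.  An empty record list produces a header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key} = {val}\n")
        if df.shape[1] or df.shape[0]:
            df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a table written by ``write_table``; returns (frame, header dict)."""
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if " = " in body:
                k, v = body.split(" = ", 1)
                header[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
    return df, header
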