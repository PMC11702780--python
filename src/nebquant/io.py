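"""Tabular I/O and run provenance shared by all analysis stages.

CSV/TSV are the interchange formats (delimiter inferred from the file
extension); every table carries a header and readers fail loudly, naming the
columns a schema requires but the file lacks.  Each CLI run writes a JSON
manifest recording the configuration, seed, input checksums and package
version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SCHEMAS: dict[str, list[str]] = {
    "force_frequency": ["frequency_hz", "force_mn"],
    "fatigue": ["tetanus_index", "force_mn"],
    "physiology": ["mass_g", "optimal_length_cm"],
    "profile": ["profile_id", "position_um", "intensity"],
    "polygons": ["fiber_id", "vertex_index", "x", "y"],
    "fiber_types": ["sample_id", "fiber_id", "type"],
    "dilution": ["sample_id", "protein", "loading_volume_ul", "od"],
}


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV with a mandatory header, checking schema columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path))
    if schema is not None:
        required = SCHEMAS[schema]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=False)
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    config: dict
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    version: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path
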