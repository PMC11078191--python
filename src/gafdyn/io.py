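"""Table and config readers/writers.

Measurement tables are TSV with a declared column map; configs round-trip
through YAML.  Floats are written at 9 significant digits so that
write(read(x)) is stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .datamodel import (
    OBSERVABLE_COLUMNS,
    FormatError,
    MeasurementTable,
    RunConfig,
)

#: canonical column names; a dialect maps file columns onto these
CANONICAL_COLUMNS = ["residue_number", "residue_name", "segment_id"] + [
    c for pair in OBSERVABLE_COLUMNS.values() for c in pair
]


def read_measurement_table(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> MeasurementTable:
    """Read a per-residue observable table from TSV/CSV.

    Parameters
    ----------
    path:
        File with a header row naming at least the residue column and one
        observable.
    dialect:
        Optional map ``{file_column: canonical_column}`` translating the
        file's headers onto the canonical schema.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if dialect:
        df = df.rename(columns=dict(dialect))
    if "residue_number" not in df.columns:
        raise FormatError(f"{path}: no residue_number column (after dialect mapping)")
    df["residue_number"] = df["residue_number"].astype(int)
    return MeasurementTable(df)


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = table.frame.reset_index()
    df.to_csv(path, sep=sep, index=False, float_format="%.9g")


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
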