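"""Deterministic CSV I/O for the pipeline's table schemas.

All writers use a fixed float format so that rerunning with the same seed
produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError

FLOAT_FORMAT = "%.12g"


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_table(path: str | Path, required: set[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input table not found: {path}")
    frame = pd.read_csv(path)
    if required:
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"{path} lacks columns {sorted(missing)}")
    return frame


def read_effort(path: str | Path) -> pd.DataFrame:
    return read_table(path, {"gear", "year", "bin_lat", "bin_lon", "effort"})


def read_abundance(path: str | Path) -> pd.DataFrame:
    return read_table(path, {"species", "year", "bin_lat", "bin_lon", "t_p"})


def read_bycatch(path: str | Path) -> pd.DataFrame:
    return read_table(path, {"species", "gear", "year", "count"})


def read_observer_series(path: str | Path) -> pd.DataFrame:
    return read_table(
        path, {"species", "year", "basin", "net_class", "median", "ci_low", "ci_high"}
    )
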