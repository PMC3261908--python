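"""Delimited-text file formats for grids, tables, and parameter sets.

Tables are tab-delimited with a header row; ``#``-prefixed metadata lines
(units, seeds, config digests) precede the header.  Parameter sets use flat
``key = value`` files (see :mod:`quorumlogic.params`).
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ConfigurationError
from .synthetic import GRID_COLUMNS, PLFGrid


class SchemaError(ValueError):
    """Raised when a table file does not match the expected schema."""


def config_digest(config: dict) -> str:
    """Short deterministic digest of a configuration mapping."""
    blob = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None,
                force: bool = True) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, meta


def write_grid(grid: PLFGrid, path: str | Path, metadata: dict | None = None,
               force: bool = True) -> None:
    meta = {
        "units": "aTc ng/ml; IPTG uM; fluorescence a.u.",
        "aTc_levels": ",".join(f"{v:g}" for v in grid.aTc_levels),
        "IPTG_levels": ",".join(f"{v:g}" for v in grid.IPTG_levels),
    }
    meta.update(metadata or {})
    write_table(grid.data, path, metadata=meta, force=force)


def read_grid(path: str | Path) -> PLFGrid:
    """Read and validate a promoter-logic grid table.

    Schema errors (missing columns, malformed numbers, negative
    fluorescence, duplicated replicate keys) name the offending row or
    column; an incomplete grid (fewer combinations than the level lists
    imply) loads with a completeness warning.
    """
    raw, meta = read_table(path)
    missing = [c for c in GRID_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in GRID_COLUMNS[:2] + GRID_COLUMNS[3:]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & raw[col].notna().to_numpy())[0]
        if raw[col].isna().any():
            bad = np.concatenate([bad, np.nonzero(raw[col].isna().to_numpy())[0]])
        if bad.size:
            raise SchemaError(
                f"{path}: malformed numeric value in column {col!r}, row {int(bad[0])}"
            )
        raw[col] = vals
    for col in ("luxI_cfp", "luxR_yfp", "output_cfp"):
        neg = np.nonzero((raw[col] < 0).to_numpy())[0]
        if neg.size:
            raise SchemaError(
                f"{path}: negative fluorescence in column {col!r}, row {int(neg[0])}"
            )
    dup = raw[["aTc_ng_ml", "IPTG_uM", "replicate"]].duplicated()
    if dup.any():
        raise SchemaError(
            f"{path}: duplicated replicate key at row {int(np.nonzero(dup.to_numpy())[0][0])}"
        )
    if "aTc_levels" in meta:
        aTc = tuple(float(v) for v in meta["aTc_levels"].split(","))
        iptg = tuple(float(v) for v in meta["IPTG_levels"].split(","))
    else:
        aTc = tuple(sorted(raw["aTc_ng_ml"].unique()))
        iptg = tuple(sorted(raw["IPTG_uM"].unique()))
    n_combo = raw[["aTc_ng_ml", "IPTG_uM"]].drop_duplicates().shape[0]
    if n_combo < len(aTc) * len(iptg):
        warnings.warn(
            f"{path}: grid has {n_combo} of {len(aTc) * len(iptg)} combinations",
            stacklevel=2,
        )
    return PLFGrid(raw, aTc, iptg)
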