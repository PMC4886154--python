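"""CSV / YAML input-output for twin item-response tables and artifacts.

The on-disk table is a long-format RFC-4180 CSV, UTF-8, one row per twin:

    family_id,zygosity,twin,item_1,...,item_k

with zygosity MZ or DZ, twin 1 or 2, responses coded 0 ("no"), 1 ("?"),
2 ("yes"), and blank cells marking missing data.  Files using the 1/2/3
survey coding are mapped on ingest via ``dialect="123"``; the coding is
always declared, never guessed.  Artifact CSVs written by the pipeline carry
a leading ``#`` comment line embedding the seed and a config hash, which the
readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TwinDataError",
    "UnknownZygosityError",
    "FamilySizeError",
    "ResponseRangeError",
    "read_twin_csv",
    "write_twin_csv",
    "read_score_csv",
    "config_hash",
    "write_yaml_sidecar",
    "write_artifact_csv",
]


class TwinDataError(ValueError):
    """Base class for malformed twin-table input."""


class UnknownZygosityError(TwinDataError):
    """Zygosity code other than MZ / DZ."""


class FamilySizeError(TwinDataError):
    """A family with a number of twin rows other than two."""


class ResponseRangeError(TwinDataError):
    """Item response outside the declared coding."""


_REQUIRED = ("family_id", "zygosity", "twin")


def _validate(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    for col in _REQUIRED:
        if col not in df.columns:
            raise TwinDataError(f"missing required column {col!r}")
    item_cols = [c for c in df.columns if str(c).startswith("item_")]
    zyg = df["zygosity"].astype(str).str.strip().str.upper()
    bad = ~zyg.isin(["MZ", "DZ"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise UnknownZygosityError(
            f"unknown zygosity {df['zygosity'].iloc[i]!r} in row {i}")
    df = df.assign(zygosity=zyg)

    twin_rows = df if "role" not in df.columns else df[df["role"] == "twin"]
    sizes = twin_rows.groupby("family_id").size()
    wrong = sizes[sizes != 2]
    if len(wrong):
        fam = wrong.index[0]
        raise FamilySizeError(
            f"family {fam!r} has {int(wrong.iloc[0])} twin rows, expected 2")

    lo, hi = (0, 2) if dialect == "012" else (1, 3)
    for c in item_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        raw_na = df[c].isna() | (df[c].astype(str).str.strip() == "")
        bad_val = (vals.notna() & ((vals < lo) | (vals > hi) | (vals % 1 != 0))
                   ) | (vals.isna() & ~raw_na)
        if bad_val.any():
            i = int(np.flatnonzero(bad_val.to_numpy())[0])
            raise ResponseRangeError(
                f"response {df[c].iloc[i]!r} in column {c!r}, row {i} is "
                f"outside the {dialect} coding")
        if dialect == "123":
            vals = vals - 1
        df[c] = pd.array(vals, dtype="Int64")
    return df


def read_twin_csv(path, dialect: str = "012") -> pd.DataFrame:
    """Read and validate a twin item-response CSV.

    ``dialect`` is "012" (internal no/?/yes coding) or "123" (survey coding,
    mapped to 0/1/2 on ingest).  Blank or NA cells become missing.  Raises
    :class:`UnknownZygosityError`, :class:`FamilySizeError` or
    :class:`ResponseRangeError` naming the offending row.
    """
    if dialect not in ("012", "123"):
        raise ValueError(f"dialect must be '012' or '123', got {dialect!r}")
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    return _validate(df, dialect)


def write_twin_csv(data: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a twin table in the package CSV dialect (0/1/2, blanks missing)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        data.to_csv(fh, index=False)


def read_score_csv(path) -> pd.DataFrame:
    """Read a per-twin score CSV (family_id, zygosity, twin, score)."""
    df = pd.read_csv(path, comment="#")
    for col in (*_REQUIRED, "score"):
        if col not in df.columns:
            raise TwinDataError(f"missing required column {col!r}")
    return _validate(df, "012")


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_yaml_sidecar(path, payload: dict) -> None:
    """Echo a configuration (plus seed / hash provenance) to a YAML sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def write_artifact_csv(df: pd.DataFrame, path, seed, cfg_hash: str,
                       index: bool = False) -> None:
    """Write an artifact table with an embedded provenance comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={seed} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)
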