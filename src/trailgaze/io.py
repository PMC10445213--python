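"""Delimited-text file I/O with metadata headers and schema validation.

All data files are comma-separated with an initial block of ``# key = value``
metadata lines (version, seed, parameter hash); report tables are
tab-separated.  Gzip-compressed files are accepted transparently (by
extension).  Coordinates in samples/clicks files are stored in pixels;
conversion to degrees happens once at detection time.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd

from ._version import __version__

__all__ = [
    "write_table",
    "read_table",
    "read_samples",
    "read_clicks",
    "read_layout",
    "read_events",
    "read_scores",
    "SchemaError",
    "DataError",
]

SAMPLES_COLUMNS = ["subject", "session", "part", "instruction", "trial", "t_ms", "x_px", "y_px", "valid"]
CLICKS_COLUMNS = ["subject", "session", "part", "instruction", "trial", "t_ms", "x_px", "y_px"]
LAYOUT_COLUMNS = ["subject", "part", "instruction", "trial", "label", "seq_index", "x_deg", "y_deg", "radius_deg"]
EVENTS_COLUMNS = [
    "subject", "session", "part", "instruction", "trial",
    "kind", "onset_ms", "offset_ms", "x_deg", "y_deg", "amplitude_deg",
]


class SchemaError(ValueError):
    """A file does not conform to its documented column schema."""


class DataError(ValueError):
    """A file parses but violates a data invariant (e.g. non-monotone time)."""


def parameter_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _opener(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None, sep: str = ",") -> None:
    """Write a frame with a ``# key = value`` metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__}
    meta.update(metadata or {})
    with _opener(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False, sep=sep)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a frame written by :func:`write_table`; metadata goes to attrs."""
    path = Path(path)
    meta = {}
    with _opener(path, "r") as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                if "=" in line:
                    k, _, v = line[1:].partition("=")
                    meta[k.strip()] = v.strip()
                continue
            lines.append(line)
        df = pd.read_csv(_io.StringIO("".join(lines)), sep=sep)
    df.attrs["metadata"] = meta
    return df


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_monotone(df: pd.DataFrame, path) -> None:
    for key, chunk in df.groupby(["subject", "session", "part", "instruction", "trial"], sort=False):
        t = chunk["t_ms"].to_numpy()
        if len(t) > 1 and (t[1:] <= t[:-1]).any():
            raise DataError(f"{path}: non-monotone timestamps within trial {key}")


def read_samples(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, SAMPLES_COLUMNS, path)
    _check_monotone(df, path)
    df.attrs["unit"] = "px"
    return df


def read_clicks(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, CLICKS_COLUMNS, path)
    _check_monotone(df, path)
    df.attrs["unit"] = "px"
    return df


def read_layout(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, LAYOUT_COLUMNS, path)
    for key, chunk in df.groupby(["subject", "part", "instruction", "trial"], sort=False):
        seqs = sorted(chunk["seq_index"].tolist())
        if seqs != list(range(1, len(seqs) + 1)):
            raise DataError(f"{path}: layout {key} has non-contiguous seq_index")
    return df


def read_events(path) -> pd.DataFrame:
    df = read_table(path)
    _require(df, EVENTS_COLUMNS, path)
    bad = ~df["kind"].isin(["fix", "sacc", "blink"])
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise DataError(f"{path}: unknown event kind at rows {rows}")
    return df


def read_scores(path) -> pd.DataFrame:
    from .scores import SCORE_NAMES

    df = read_table(path)
    _require(df, ["subject", "session", "part", "instruction", "trial"] + SCORE_NAMES, path)
    return df
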