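"""Shared I/O: TIFF stacks, delimited tables, force curves, result tables.

Conventions: TIFF frames in acquisition order with pixel (0, 0) top-left;
tables are comma- or tab-delimited text with a header row; result tables
embed the fully resolved parameter set as ``# key=value`` header comments so
any output can be reproduced from the file alone.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve

__all__ = [
    "SchemaError",
    "read_image_stack",
    "write_image_stack",
    "read_table",
    "write_table",
    "read_force_curve",
    "write_force_curve",
    "tracks_to_table",
    "table_to_tracks",
]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def read_image_stack(path) -> np.ndarray:
    """Read a single-channel TIFF stack as a (frames, y, x) array."""
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface a format error
        raise OSError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[-2]:
        raise OSError("single-channel required; split channels first")
    if arr.ndim != 3:
        raise OSError(f"expected a 2D/3D single-channel TIFF, got shape {arr.shape}")
    return arr


def write_image_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_table(path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a delimited table (comma or tab autodetected) with a header row.

    ``schema`` maps required column names to numeric types; a missing column
    or a non-numeric cell in a numeric column raises SchemaError naming the
    offender.
    """
    text = Path(path).read_text()
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    df = pd.read_csv(_io.StringIO(body), sep=sep)
    if schema:
        for col, typ in schema.items():
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise SchemaError(
                    f"non-numeric value in column {col!r} at row {row}")
            df[col] = coerced.astype(typ)
    return df


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a table as CSV, embedding ``params`` as '# key=value' header lines."""
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_header_params(path) -> dict[str, str]:
    out = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.startswith("#"):
            break
        k, _, v = ln.lstrip("# ").partition("=")
        out[k] = v
    return out


_FORCE_SCHEMA = {"z_um": float, "force_nN": float}


def read_force_curve(path) -> ForceCurve:
    """Read a two-column force curve (z_um, force_nN)."""
    df = read_table(path, _FORCE_SCHEMA)
    return ForceCurve(z=df["z_um"].to_numpy(), force=df["force_nN"].to_numpy())


def write_force_curve(curve: ForceCurve, path, params: dict | None = None) -> None:
    write_table(pd.DataFrame({"z_um": curve.z, "force_nN": curve.force}),
                path, params)


_TRACK_SCHEMA = {"particle_id": int, "frame": int, "x": float, "y": float}


def tracks_to_table(tracks) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.particle_id, int(f), x, y))
    return pd.DataFrame(rows, columns=["particle_id", "frame", "x", "y"])


def table_to_tracks(df: pd.DataFrame, frame_interval: float):
    from .spt import Track

    tracks = []
    for pid, grp in df.groupby("particle_id"):
        grp = grp.sort_values("frame")
        tracks.append(Track(int(pid), grp["frame"].to_numpy(),
                            grp[["x", "y"]].to_numpy(), frame_interval))
    return tracks
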