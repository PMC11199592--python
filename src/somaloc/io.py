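"""Readers and writers for volumes (multi-page TIFF, Zarr) and marker CSVs.

Marker CSVs use the ``x,y,z[,label]`` column order of common annotation
tools; internally everything is ``(z, y, x)``.  Conversion happens at the
file boundary and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import zarr

from .core import CellCenters, Volume

_META_KEY = "voxel_size_um"
_ZARR_CHUNK_PLANES = 64  # one chunk = one z-slab of at most 64 planes


def write_volume(vol: Volume, path) -> None:
    """Write a volume to multi-page TIFF (``.tif``/``.tiff``) or Zarr.

    Voxel size is stored in the TIFF ImageDescription / Zarr attributes so a
    round trip reproduces both data and metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            vol.data,
            metadata={_META_KEY: list(vol.voxel_size_um)},
        )
    elif path.suffix.lower() == ".zarr":
        chunks = (min(_ZARR_CHUNK_PLANES, vol.shape[0]), vol.shape[1], vol.shape[2])
        arr = zarr.open_array(
            str(path), mode="w", shape=vol.shape, chunks=chunks, dtype=vol.data.dtype
        )
        arr[:] = vol.data
        arr.attrs[_META_KEY] = list(vol.voxel_size_um)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r} (use .tif or .zarr)")


def read_volume(path) -> Volume:
    """Read a multi-page TIFF or Zarr volume written by :func:`write_volume`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        if not path.exists():
            raise FileNotFoundError(f"volume file not found: {path}")
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            voxel = None
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta:
                m = meta[0] if isinstance(meta, (list, tuple)) else meta
                voxel = m.get(_META_KEY)
        return Volume(data, voxel) if voxel is not None else Volume(data)
    if path.suffix.lower() == ".zarr":
        arr = zarr.open_array(str(path), mode="r")
        voxel = arr.attrs.get(_META_KEY)
        data = arr[:]
        return Volume(data, voxel) if voxel is not None else Volume(data)
    raise ValueError(f"unsupported volume format: {path.suffix!r} (use .tif or .zarr)")


def write_markers(centers: CellCenters, path) -> None:
    """Write soma centers to CSV with header ``x,y,z[,label]`` (voxel units)."""
    pts = centers.points
    df = pd.DataFrame({"x": pts[:, 2], "y": pts[:, 1], "z": pts[:, 0]})
    if centers.labels is not None:
        df["label"] = centers.labels
    df.to_csv(path, index=False)


def read_markers(path, space: str = "voxel") -> CellCenters:
    """Read a marker CSV (header ``x,y,z[,label]``) into ``(z, y, x)`` points.

    Raises a parse error naming the offending data row on malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse marker CSV {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("x", "y", "z"):
        if required not in cols:
            raise ValueError(
                f"marker CSV {path} is missing column {required!r}; header must be x,y,z[,label]"
            )
    coords = np.empty((len(df), 3), dtype=float)
    for axis, name in enumerate(("z", "y", "x")):
        col = pd.to_numeric(df[cols[name]], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"non-numeric {name!r} value in {path} at line {bad[0] + 2}: "
                f"{df[cols[name]].iloc[bad[0]]!r}"
            )
        coords[:, axis] = col.to_numpy()
    labels = df[cols["label"]].to_numpy() if "label" in cols else None
    return CellCenters(coords, space=space, labels=labels)


def write_sidecar(path, **fields) -> None:
    """Write a small JSON sidecar (thresholds, kappa, bounds) next to a mask."""
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
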