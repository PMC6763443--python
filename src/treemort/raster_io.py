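"""Minimal raster I/O: TIFF via tifffile with a JSON georeference sidecar,
plus a headered ``.npy`` fallback for environments without TIFF support.

The sidecar (``<raster>.json``) records pixel size and the map coordinates
of the top-left corner so rasters round-trip with their geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def write_raster(path, array, resolution_m: float, origin=(0.0, 0.0)) -> None:
    path = Path(path)
    arr = np.asarray(array)
    meta = {"resolution_m": float(resolution_m),
            "origin_x": float(origin[0]), "origin_y": float(origin[1]),
            "shape": list(arr.shape), "dtype": str(arr.dtype)}
    if path.suffix.lower() in (".tif", ".tiff"):
        kwargs = {}
        if arr.ndim == 3:  # band-sequential multiband
            kwargs = {"photometric": "minisblack", "planarconfig": "separate"}
        tifffile.imwrite(path, arr, description=json.dumps(meta), **kwargs)
    elif path.suffix.lower() == ".npy":
        np.save(path, arr)
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path):
    """Returns (array, metadata dict)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        raise ValueError(f"unsupported raster format {path.suffix!r}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta
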