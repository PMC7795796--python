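"""Sinogram file I/O.

Sinograms travel as 32-bit float TIFF (the working format) or as raw
binary with a JSON sidecar describing shape and dtype.  Integer TIFFs
(e.g. 16-bit detector frames) are promoted to float without rescaling,
so a saturated 65535 column stays 65535.0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_sinogram", "write_sinogram"]


def read_sinogram(path) -> np.ndarray:
    """Read a sinogram (angle rows x detector columns) as float64.

    Accepts single-page TIFF (float or integer) or ``.raw`` binary with
    a ``<path>.json`` sidecar containing ``{"shape": [M, N], "dtype":
    "<numpy dtype>"}``.  Truncated or mis-shaped files raise without
    returning a partial array.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw sinogram requires sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(int(s) for s in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        data = np.fromfile(path, dtype=dtype)
        if data.size != shape[0] * shape[1]:
            raise ValueError(
                f"raw file holds {data.size} values, expected "
                f"{shape[0]}x{shape[1]} (angle rows x detector columns)"
            )
        arr = data.reshape(shape)
    else:
        arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"expected a 2-D sinogram (angle rows x detector columns), "
            f"got shape {arr.shape}"
        )
    return arr.astype(np.float64)


def write_sinogram(path, sino: np.ndarray) -> None:
    """Write a sinogram as 32-bit float TIFF."""
    sino = np.asarray(sino)
    if sino.ndim != 2:
        raise ValueError("expected a 2-D sinogram")
    tifffile.imwrite(str(path), sino.astype(np.float32))
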