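"""Format adapters: TIFF rasters, polygon JSON, versioned CSV tables.

Conventions (stated in every file header where the format allows):
coordinates are 0-based, x = column, y = row, pixel-center.  Images travel
as 8-bit RGB TIFF, label masks as 16-bit single-channel TIFF (PNG also
accepted on read), polygons as ``[{"label": k, "vertices": [[x, y], ...]}]``
JSON.  Every CSV written here carries a schema-version header line;
loaders reject versions they do not understand.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.io import imread as sk_imread

CSV_SCHEMA = "nucmorph-csv v1"
_COORD_NOTE = "coordinates 0-based, x=column, y=row, pixel-center"


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(str(p))
    return sk_imread(str(p))


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    lm = np.asarray(labels)
    if lm.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot be stored as 16-bit")
    tifffile.imwrite(str(path), lm.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return np.asarray(read_image(path))


def write_polygons(path: str | Path, polygons: list[dict]) -> None:
    payload = {"format": "nucmorph-polygons v1", "coordinates": _COORD_NOTE,
               "annotations": polygons}
    Path(path).write_text(json.dumps(payload))


def read_polygons(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, list):  # bare list accepted
        return payload
    if payload.get("format") != "nucmorph-polygons v1":
        raise ValueError(f"unknown polygon file format in {path}")
    return payload["annotations"]


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {CSV_SCHEMA}; {_COORD_NOTE}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing schema header line")
        if CSV_SCHEMA not in header:
            raise ValueError(f"{path}: unsupported schema version: {header.strip()}")
        return pd.read_csv(fh)
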