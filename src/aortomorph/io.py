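"""Image and table I/O with sidecar metadata.

Images travel as PNG/TIFF plus a ``<name>.json`` sidecar carrying
pixel_size, stain_kind, seed and any truth payload; tables are headered
CSV. Round trips are lossless for integer counts and labels; floats are
written at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .segmentation import StainImage
from .stats import ContingencyTable


def sidecar_path(image_path) -> Path:
    p = Path(image_path)
    return p.with_suffix(p.suffix + ".json")


def write_image(path, image: StainImage, extra: dict | None = None) -> None:
    """Write an image and its JSON sidecar (pixel_size, stain_kind, extras)."""
    path = Path(path)
    iio.imwrite(path, image.pixels)
    meta = {"pixel_size": image.pixel_size, "stain_kind": image.stain_kind}
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=1, default=_jsonable))


def read_image(path) -> tuple[StainImage, dict]:
    """Read an image plus sidecar; errors name the missing sidecar key."""
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar {sc} for image {path}")
    meta = json.loads(sc.read_text())
    for key in ("pixel_size", "stain_kind"):
        if key not in meta:
            raise ValueError(f"sidecar {sc} missing required key {key!r}")
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    img = StainImage(
        pixels=pixels.astype(np.uint8),
        stain_kind=meta["stain_kind"],
        pixel_size=float(meta["pixel_size"]),
    )
    return img, meta


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_table(path, df: pd.DataFrame) -> None:
    # pandas' default float repr round-trips exactly; do not truncate
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def read_contingency(path) -> ContingencyTable:
    """Read an r×c contingency table from a CSV matrix.

    First column holds row labels, header holds column labels; cells must
    be nonnegative integers.
    """
    path = Path(path)
    df = read_table(path)
    row_labels = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    arr = body.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr != arr.astype(int)).any():
        raise ValueError(f"contingency CSV {path}: cells must be integers")
    if (arr < 0).any():
        raise ValueError(f"contingency CSV {path}: negative cell count")
    return ContingencyTable.from_array(
        arr.astype(np.int64), row_labels=row_labels,
        col_labels=[str(c) for c in body.columns],
    )


def write_contingency(path, table: ContingencyTable) -> None:
    arr = table.to_array()
    cols = table.col_labels or [f"c{i}" for i in range(arr.shape[1])]
    rows = table.row_labels or [f"r{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, columns=list(cols))
    df.insert(0, "label", list(rows))
    df.to_csv(path, index=False)
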