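"""Image reading/writing, label manifests and the CSV feature store.

The feature store is one CSV per database: an ``image_id`` column followed
by one column per descriptor bin, named ``s{r}_{T|I|F}_{ms|nr}_{p}_{q}``
(scale, neutrosophic channel, joint block, primary label, RiTxP label).  A
sidecar JSON (same path + ``.json``) records the window ``w``, the scales,
the normalization flag and the code version, so a store is self-describing.
Floats are written with shortest round-trip repr, so write -> read -> write
is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .descriptor import feature_names

_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray(path: str | Path, to_gray: bool = False) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF, 8/16-bit; DICOM via pydicom).

    Multi-channel inputs are rejected unless ``to_gray`` is set, in which
    case the standard luminance weighting is applied.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("reading DICOM requires the pydicom package") from exc
        arr = pydicom.dcmread(str(path)).pixel_array
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if not to_gray:
            raise ValueError(
                f"{path} is multi-channel; pass to_gray=True for luminance conversion"
            )
        arr = arr[:, :, :3].astype(np.float64) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_gray_png(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 255] float image as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a label manifest CSV with columns ``image_id`` and ``class``."""
    df = pd.read_csv(path, dtype=str)
    missing = {"image_id", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    if df["image_id"].duplicated().any():
        raise ValueError(f"manifest {path} has duplicate image ids")
    return df


def write_manifest(path: str | Path, ids: Sequence[str], labels: Sequence[str]) -> None:
    pd.DataFrame({"image_id": ids, "class": labels}).to_csv(path, index=False)


def _sidecar_path(store: Path) -> Path:
    return store.with_suffix(store.suffix + ".json")


def write_feature_store(
    path: str | Path,
    ids: Sequence[str],
    X: np.ndarray,
    scales: Sequence[int],
    w: int,
    normalize: bool,
) -> None:
    """Write descriptors to CSV plus a sidecar JSON with the run parameters."""
    from . import __version__

    path = Path(path)
    cols = feature_names(scales)
    if X.shape != (len(ids), len(cols)):
        raise ValueError(
            f"descriptor matrix {X.shape} does not match {len(ids)} ids x "
            f"{len(cols)} bins for scales {list(scales)}"
        )
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "image_id", list(ids))
    df.to_csv(path, index=False)
    meta = {
        "w": int(w),
        "scales": [int(r) for r in scales],
        "normalize": bool(normalize),
        "version": __version__,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_feature_store(path: str | Path) -> Tuple[List[str], np.ndarray, Dict]:
    """Read a feature store; returns (ids, descriptor matrix, sidecar meta)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    ids = df["image_id"].astype(str).tolist()
    X = df.drop(columns=["image_id"]).to_numpy(dtype=np.float64)
    meta: Dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ids, X, meta
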