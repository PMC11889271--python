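"""Dataset readers/writers: image/mask pairs, manifests, config files.

On disk, images are 8-bit RGB PNG/JPEG and masks are single-channel PNG with
values {0, 255} (or already {0, 1}); in memory masks are {0, 1} uint8 and the
compute layout is channel-first.  These converters are the only place layout
or value conventions change.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["read_image", "read_mask", "read_image_mask_pair", "write_mask",
           "load_manifest", "load_dataset", "load_config_file"]


def read_image(path) -> np.ndarray:
    """Load an RGB image as HxWx3 uint8.

    RGBA inputs drop their alpha channel and grayscale inputs are replicated
    to three channels, each with a warning.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        logger.warning("%s is grayscale; replicating to 3 channels", path)
        arr = np.repeat(arr[..., None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("%s has an alpha channel; dropping it", path)
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: unsupported image shape {arr.shape}")
    return arr.astype(np.uint8)


def read_mask(path) -> np.ndarray:
    """Load a binary mask, normalising {0, 255} (or any 0/positive coding) to {0, 1}."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(f"{path}: mask values {vals[:6]} are not binary (0/1 or 0/255)")
    return (arr > 0).astype(np.uint8)


def read_image_mask_pair(image_path, mask_path) -> Tuple[np.ndarray, np.ndarray]:
    image = read_image(image_path)
    mask = read_mask(mask_path)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"misaligned pair: {image_path} is {image.shape[:2]} but "
            f"{mask_path} is {mask.shape}")
    return image, mask


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def load_manifest(manifest_path) -> pd.DataFrame:
    """Read a dataset manifest CSV, validating uniqueness and file existence."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"id", "image_path", "mask_path", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
        raise ValueError(f"{manifest_path}: duplicate ids {dupes}")
    root = manifest_path.parent
    for col in ("image_path", "mask_path"):
        for rel in df[col]:
            if not (root / rel).exists():
                raise FileNotFoundError(f"{manifest_path}: missing file {root / rel}")
    return df


def load_dataset(manifest_path, split: Optional[str] = None
                 ) -> Tuple[List[np.ndarray], List[np.ndarray], List[str]]:
    """Load (images, masks, ids) for one split (or all rows if split is None)."""
    manifest_path = Path(manifest_path)
    df = load_manifest(manifest_path)
    if split is not None:
        df = df[df["split"] == split]
        if df.empty:
            raise ValueError(f"no rows with split={split!r} in {manifest_path}")
    root = manifest_path.parent
    images, masks, ids = [], [], []
    for _, row in df.iterrows():
        image, mask = read_image_mask_pair(root / row["image_path"],
                                           root / row["mask_path"])
        images.append(image)
        masks.append(mask)
        ids.append(str(row["id"]))
    return images, masks, ids


def load_config_file(path) -> dict:
    """Parse a YAML config with optional ``model:`` and ``train:`` sections."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return data
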