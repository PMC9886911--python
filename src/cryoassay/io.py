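"""On-disk formats: multi-page TIFF volumes with JSON geometry sidecars,
integer TIFF masks with a label map, and CSV tables for ground truth and
detections.  Coordinates in every table are 0-based voxel indices in
(z, y, x) order; intensity is on the 0-255 scale.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    CHANNELS,
    GroundTruth,
    ImageVolume,
    MetadataError,
    OrganMask,
)
from .detection import CellDetection

DETECTION_COLUMNS = (
    "cell_id",
    "z",
    "y",
    "x",
    "channel",
    "scale_sigma_um",
    "component_voxels",
    "intensity",
    "region_label",
)


def _sidecar_path(stem: Path) -> Path:
    return stem.with_suffix(".json")


def write_volume(volume: ImageVolume, stem: str | Path) -> Path:
    """Write one multi-page TIFF per channel plus a JSON geometry sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    for name in volume.channels:
        tifffile.imwrite(stem.parent / f"{stem.name}_{name}.tif", volume.channel(name))
    meta = {
        "voxel_size_um": list(volume.voxel_size_um),
        "channels": list(volume.channels),
        "grid_shape": list(volume.grid_shape),
        "dtype": str(volume.data.dtype),
    }
    _sidecar_path(stem).write_text(json.dumps(meta, indent=2))
    return stem


def read_volume(stem: str | Path) -> ImageVolume:
    """Read a volume written by :func:`write_volume`.

    A missing sidecar is a hard error: without voxel geometry every volume
    measurement would be silently wrong.  16-bit inputs are rescaled to the
    0-255 scale with a warning.
    """
    stem = Path(stem)
    sidecar = _sidecar_path(stem)
    if not sidecar.exists():
        raise MetadataError(f"missing geometry sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta or "channels" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks voxel_size_um/channels")
    planes = []
    for name in meta["channels"]:
        path = stem.parent / f"{stem.name}_{name}.tif"
        try:
            plane = tifffile.imread(path)
        except Exception as exc:  # corrupt page / truncated file
            raise MetadataError(f"cannot read channel page {path}: {exc}") from exc
        if plane.dtype == np.uint16:
            warnings.warn(f"{path} is 16-bit; rescaling to the 0-255 scale")
            plane = (plane.astype(np.float64) / 257.0).round().astype(np.uint8)
        expected = tuple(meta.get("grid_shape", plane.shape))
        if tuple(plane.shape) != expected:
            raise MetadataError(
                f"channel page {path} has shape {plane.shape}, expected {expected}"
            )
        planes.append(plane.astype(np.uint8))
    return ImageVolume(
        np.stack(planes),
        tuple(meta["channels"]),
        tuple(meta["voxel_size_um"]),
    )


def write_mask(mask: OrganMask, stem: str | Path) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(stem.parent / f"{stem.name}_mask.tif", mask.labels.astype(np.int32))
    meta = {
        "voxel_size_um": list(mask.voxel_size_um),
        "label_map": mask.label_map,
    }
    _sidecar_path(stem).write_text(json.dumps(meta, indent=2))
    return stem


def read_mask(stem: str | Path) -> OrganMask:
    stem = Path(stem)
    sidecar = _sidecar_path(stem)
    if not sidecar.exists():
        raise MetadataError(f"missing mask sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    labels = tifffile.imread(stem.parent / f"{stem.name}_mask.tif")
    return OrganMask(
        labels.astype(np.int32),
        {str(k): int(v) for k, v in meta["label_map"].items()},
        tuple(meta["voxel_size_um"]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth(pd.read_csv(path))


def write_detections(detections: list[CellDetection], path: str | Path) -> Path:
    """CSV with one row per detection; empty lists give a header-only file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, det in enumerate(detections):
        rows.append(
            {
                "cell_id": i,
                "z": det.centroid[0],
                "y": det.centroid[1],
                "x": det.centroid[2],
                "channel": det.channel,
                "scale_sigma_um": "x".join(f"{s:g}" for s in det.scale_sigma_um),
                "component_voxels": det.component_voxels,
                "intensity": det.intensity,
                "region_label": det.region_label or "other",
            }
        )
    pd.DataFrame(rows, columns=list(DETECTION_COLUMNS)).to_csv(path, index=False)
    return path


def read_detections(path: str | Path) -> list[CellDetection]:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise MetadataError(f"malformed detection CSV {path}: {exc}") from exc
    missing = set(DETECTION_COLUMNS) - set(table.columns)
    if missing:
        raise MetadataError(f"{path} lacks columns {sorted(missing)}")
    detections = []
    for line, row in enumerate(table.itertuples(index=False), start=2):
        try:
            sigma = tuple(float(s) for s in str(row.scale_sigma_um).split("x"))
            detections.append(
                CellDetection(
                    centroid=(float(row.z), float(row.y), float(row.x)),
                    channel=str(row.channel),
                    scale_sigma_um=sigma,
                    component_voxels=int(row.component_voxels),
                    intensity=float(row.intensity),
                    region_label=str(row.region_label),
                )
            )
        except (TypeError, ValueError) as exc:
            raise MetadataError(f"malformed row at {path}:{line}: {exc}") from exc
    return detections
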