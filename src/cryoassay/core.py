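"""Core containers and error types shared by every pipeline stage.

Coordinate convention: 0-based voxel indices in ``(z, y, x)`` order, where
``z`` is the sectioning axis.  Physical sizes are always carried as
``voxel_size_um = (dz, dy, dx)`` in micrometres; every conversion between
voxel counts and physical volume goes through this triple.  Intensities are
on the 0-255 (8-bit) scale end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Channel order used by the phantom generator and the readers.
CHANNELS = ("brightfield", "green", "red")

#: Default cryo-sectioning geometry: 40 um sections, 10.5 um in-plane pixels.
DEFAULT_VOXEL_SIZE_UM = (40.0, 10.5, 10.5)


class CryoAssayError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(CryoAssayError, ValueError):
    """A numeric parameter is outside its documented domain."""


class GeometryError(CryoAssayError, ValueError):
    """Region geometry cannot be realised on the requested grid."""


class CapacityError(CryoAssayError, ValueError):
    """A region does not contain enough candidate voxels for a population."""


class InvalidDesignError(CryoAssayError, ValueError):
    """A cohort design is empty or internally inconsistent."""


class ConfigError(CryoAssayError, ValueError):
    """A detection / assay configuration value is invalid."""


class ResolutionError(ConfigError):
    """A filter scale is below what the voxel grid can represent."""


class AlignmentError(CryoAssayError, ValueError):
    """Two grids that must share a shape do not."""


class LabelError(CryoAssayError, KeyError):
    """A region label is absent from a mask's label map."""


class DegenerateTrainingError(CryoAssayError, ValueError):
    """Classifier training data contains a single class."""


class DegenerateVarianceError(CryoAssayError, ValueError):
    """Both samples have zero variance but different means."""


class EmptySampleError(CryoAssayError, ValueError):
    """An intensity selection produced no observations."""


class InsufficientSampleError(CryoAssayError, ValueError):
    """Too few observations for a density estimate."""


class SegmentationFailedError(CryoAssayError, RuntimeError):
    """The stand-in white-pulp segmenter found no bimodal contrast."""


class MetadataError(CryoAssayError, ValueError):
    """A volume on disk is missing its geometry sidecar."""


@dataclass
class ImageVolume:
    """A 3D multi-channel 8-bit intensity grid with physical voxel geometry.

    ``data`` has shape ``(n_channels, nz, ny, nx)`` and dtype uint8.
    """

    data: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InvalidParameterError("ImageVolume data must be (C, Z, Y, X)")
        if self.data.shape[0] != len(self.channels):
            raise InvalidParameterError(
                f"{self.data.shape[0]} planes for {len(self.channels)} channels"
            )
        if any(d <= 0 for d in self.voxel_size_um):
            raise InvalidParameterError("voxel sizes must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (Z, Y, X) array."""
        try:
            idx = self.channels.index(name)
        except ValueError as exc:
            raise LabelError(f"no channel named {name!r}") from exc
        return self.data[idx]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx * 1e-9


@dataclass
class OrganMask:
    """Integer-labelled 3D grid aligned to an :class:`ImageVolume`.

    ``label_map`` maps region names to positive integer labels; voxels
    labelled 0 are outside every region.
    """

    labels: np.ndarray
    label_map: dict[str, int]
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidParameterError("OrganMask labels must be (Z, Y, X)")

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of one named region."""
        if name not in self.label_map:
            raise LabelError(f"unknown region {name!r}")
        return self.labels == self.label_map[name]

    def region_name_at(self, z: int, y: int, x: int) -> str:
        """Region name at a voxel; ``"other"`` outside every region."""
        value = int(self.labels[z, y, x])
        for name, label in self.label_map.items():
            if label == value:
                return name
        return "other"

    def voxel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel())
        return {
            name: int(counts[label]) if label < counts.size else 0
            for name, label in self.label_map.items()
        }


@dataclass
class GroundTruth:
    """Oracle record of every simulated cell plus region voxel counts.

    ``cells`` columns: cell_id, z, y, x, channel, generation, intensity,
    region.  Subsurface echoes are rendering artefacts, never rows here.
    """

    cells: pd.DataFrame
    region_voxel_counts: dict[str, int] = field(default_factory=dict)

    COLUMNS = ("cell_id", "z", "y", "x", "channel", "generation", "intensity", "region")

    def __post_init__(self) -> None:
        if self.cells is None or len(self.cells) == 0:
            self.cells = pd.DataFrame(columns=list(self.COLUMNS))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def for_channel(self, channel: str) -> pd.DataFrame:
        return self.cells[self.cells["channel"] == channel]


def concat_ground_truths(parts: list[GroundTruth]) -> GroundTruth:
    """Merge ground truths from several populations, reassigning cell ids."""
    frames = [p.cells for p in parts if len(p.cells)]
    counts = parts[0].region_voxel_counts if parts else {}
    if not frames:
        return GroundTruth(pd.DataFrame(), dict(counts))
    cells = pd.concat(frames, ignore_index=True)
    cells["cell_id"] = np.arange(len(cells))
    return GroundTruth(cells, dict(counts))
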