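"""Single-cell detection in 3D multispectral volumes.

T-cells (green channel) are found with a matched band-pass filter: the
"Mexican hat", i.e. the negated, scale-normalised Laplacian of Gaussian,
whose response peaks on bright blobs of the matched physical size.  Filter
scales are given in micrometres per axis and converted to voxels through
the voxel geometry, so the strong z-anisotropy of cryo-sectioned data
(40 um sections vs 10.5 um pixels) is handled explicitly.  A threshold
``T_isolated`` on the filtered image marks candidate voxels, 3D connected
components group marks belonging to one cell — including the attenuated
subsurface echo a cell leaves in the next section, which would otherwise be
double counted — and the procedure repeats over an ascending scale list to
pick up larger cell clusters.  Per-cell intensity is read from the
morphological white top-hat of the raw channel, which strips the smooth
autofluorescent background.

MSCs (red channel) are found by a voxelwise classifier: each voxel carries
four features (top-hat and Mexican-hat responses of the red and green
channels) and a bagged ensemble of decision trees votes on whether the
voxel is MSC signal; positive voxels are grouped by the same 3D connected
component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import (
    AlignmentError,
    ConfigError,
    CryoAssayError,
    DegenerateTrainingError,
    ImageVolume,
    OrganMask,
    ResolutionError,
)

_STRUCTURES = {6: 1, 18: 2, 26: 3}

#: In-plane/axial scales (um) matched to single cells and small clusters.
DEFAULT_SIGMA_LIST_UM = ((20.0, 6.0, 6.0), (20.0, 9.0, 9.0), (20.0, 13.0, 13.0))

MSC_FEATURE_NAMES = ("tophat_red", "tophat_green", "log_red", "log_green")


@dataclass
class DetectionConfig:
    """Knobs of the detection pipeline.

    ``t_isolated`` may be a single threshold reused at every scale or one
    value per scale; it is usually produced by :func:`calibrate_t_isolated`
    on an unlabeled control volume so that autofluorescence is minimally
    marked.  ``gamma`` is the scale-normalisation exponent of the filter
    (response multiplied by sigma**(2*gamma)); 1.25 makes the response of a
    3D Gaussian blob peak at the matched scale.
    """

    sigma_list_um: tuple = DEFAULT_SIGMA_LIST_UM
    t_isolated: float | tuple = 1.0
    connectivity: int = 26
    tophat_radius_um: float = 32.0
    min_component_voxels: int = 1
    max_component_voxels: int = 125
    gamma: float = 1.25
    msc_candidate_min_tophat: float = 2.0

    def __post_init__(self) -> None:
        if len(self.sigma_list_um) == 0:
            raise ConfigError("sigma_list_um must not be empty")
        sigmas = [np.atleast_1d(s) for s in self.sigma_list_um]
        means = [float(np.exp(np.mean(np.log(s)))) for s in sigmas]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ConfigError("sigma_list_um must be sorted ascending")
        if self.connectivity not in _STRUCTURES:
            raise ConfigError("connectivity must be one of 6, 18, 26")
        if self.tophat_radius_um <= 0:
            raise ConfigError("tophat_radius_um must be positive")
        for t in np.atleast_1d(self.t_isolated):
            if t <= 0:
                raise ConfigError("t_isolated must be positive")

    def thresholds(self) -> list[float]:
        t = np.atleast_1d(self.t_isolated).astype(float)
        if t.size == 1:
            return [float(t[0])] * len(self.sigma_list_um)
        if t.size != len(self.sigma_list_um):
            raise ConfigError("one t_isolated per scale required")
        return [float(v) for v in t]


@dataclass
class CellDetection:
    """One detected cell."""

    centroid: tuple[float, float, float]  # (z, y, x) voxel coordinates
    channel: str
    scale_sigma_um: tuple[float, float, float]
    component_voxels: int
    intensity: float = float("nan")  # background-subtracted, 0-255 scale
    region_label: str | None = None
    peak_voxel: tuple[int, int, int] | None = None


def _gaussian_kernel1d(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian (order 0) or its second derivative (order 2).

    The order-0 kernel is normalised to unit sum; the order-2 kernel is the
    analytic second derivative of that normalised Gaussian with its residual
    DC component removed, so a constant image gives exactly zero response.
    """
    radius = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 2:
        dd = phi * (x * x - sigma * sigma) / sigma**4
        return dd - dd.mean()
    raise ValueError("order must be 0 or 2")


def mexican_hat_filter(
    channel: np.ndarray,
    sigma_um: float | tuple[float, float, float],
    voxel_size_um: tuple[float, float, float],
    gamma: float = 1.25,
) -> np.ndarray:
    """Negated scale-normalised LoG response in physical units.

    The Laplacian is taken with respect to physical coordinates (each axis
    second derivative divided by the squared voxel pitch) and the response is
    multiplied by ``-sigma_bar**(2*gamma)`` where ``sigma_bar`` is the
    geometric-mean scale in um.  Bright blobs of matched size give positive
    peaks; a constant image maps to (numerically) zero.
    """
    sigma_um = np.broadcast_to(np.atleast_1d(np.asarray(sigma_um, float)), (3,))
    if np.any(sigma_um <= 0):
        raise ConfigError("sigma must be positive")
    voxel = np.asarray(voxel_size_um, dtype=float)
    sigma_vox = sigma_um / voxel
    if np.any(sigma_vox < 0.5):
        raise ResolutionError(
            f"sigma {tuple(sigma_um)} um is below half a voxel on some axis"
        )
    img = np.asarray(channel, dtype=np.float64)
    response = np.zeros_like(img)
    for deriv_axis in range(3):
        part = img
        for axis in range(3):
            order = 2 if axis == deriv_axis else 0
            part = ndi.correlate1d(
                part,
                _gaussian_kernel1d(sigma_vox[axis], order),
                axis=axis,
                mode="reflect",
            )
        response += part / voxel[deriv_axis] ** 2
    sigma_bar = float(np.exp(np.mean(np.log(sigma_um))))
    return -(sigma_bar ** (2.0 * gamma)) * response


def threshold_detect(filtered: np.ndarray, t_isolated: float) -> np.ndarray:
    """Mark voxels whose filter response exceeds ``T_isolated``."""
    if t_isolated <= 0:
        raise ConfigError("t_isolated must be positive")
    return np.asarray(filtered) > t_isolated


def calibrate_t_isolated(
    control_volume: ImageVolume,
    config: DetectionConfig,
    channel: str = "green",
    target_fraction: float = 1e-6,
    safety: float = 1.15,
) -> tuple[float, ...]:
    """Per-scale thresholds from an autofluorescence-only control volume.

    Each threshold is the ``1 - target_fraction`` quantile of the filtered
    control times a safety margin, so autofluorescent voxels are minimally
    marked: on the control itself the false-mark fraction is at most
    ``target_fraction``, and the margin absorbs the noise fluctuations of
    the strongest autofluorescence structure (organ rims, compartment
    interfaces) on comparable volumes.
    """
    if not 0 < target_fraction < 1:
        raise ConfigError("target_fraction must be in (0, 1)")
    if safety < 1.0:
        raise ConfigError("safety factor must be >= 1")
    img = control_volume.channel(channel)
    thresholds = []
    for sigma in config.sigma_list_um:
        resp = mexican_hat_filter(
            img, sigma, control_volume.voxel_size_um, config.gamma
        )
        thresholds.append(float(np.quantile(resp, 1.0 - target_fraction)) * safety)
    return tuple(thresholds)


def connected_components_3d(
    mask: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Label maximal connected sets of marked voxels.

    Returns the labelled array and the component count.  With 26-connectivity
    a cell and its subsurface echo in the adjacent section share a component,
    which is the point: one cell, one detection.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigError("connectivity must be one of 6, 18, 26")
    structure = ndi.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n = ndi.label(mask, structure=structure)
    return labels, int(n)


def _tophat_footprint(
    radius_um: float, voxel_size_um: tuple[float, float, float]
) -> np.ndarray:
    """Flat ellipsoidal footprint with the given physical radius."""
    half = [int(radius_um / d) for d in voxel_size_um]
    grids = np.ix_(
        *[
            ((np.arange(-h, h + 1) * d / radius_um) ** 2)
            for h, d in zip(half, voxel_size_um)
        ]
    )
    return (grids[0] + grids[1] + grids[2]) <= 1.0


def white_tophat(
    channel: np.ndarray,
    tophat_radius_um: float,
    voxel_size_um: tuple[float, float, float],
) -> np.ndarray:
    """Morphological white top-hat: image minus its grey opening.

    Removes background structure smoother than the footprint while keeping
    small bright cells at full contrast.
    """
    if tophat_radius_um <= 0:
        raise ConfigError("tophat_radius_um must be positive")
    img = np.asarray(channel, dtype=np.float64)
    footprint = _tophat_footprint(tophat_radius_um, voxel_size_um)
    return ndi.white_tophat(img, footprint=footprint)


def tophat_intensity(
    channel: np.ndarray,
    detections: list[CellDetection],
    tophat_radius_um: float,
    voxel_size_um: tuple[float, float, float],
) -> list[CellDetection]:
    """Assign each detection the top-hat value at its peak voxel."""
    if not detections:
        return detections
    tophat = white_tophat(channel, tophat_radius_um, voxel_size_um)
    for det in detections:
        voxel = det.peak_voxel
        if voxel is None:
            voxel = tuple(int(round(c)) for c in det.centroid)
        det.intensity = float(tophat[voxel])
    return detections


def _components_at_scale(
    response: np.ndarray,
    t_isolated: float,
    config: DetectionConfig,
    accepted: np.ndarray,
) -> tuple[np.ndarray, list[tuple[tuple, int, tuple]]]:
    """Threshold + group one scale; drop components touching earlier scales."""
    marked = threshold_detect(response, t_isolated)
    labels, n = connected_components_3d(marked, config.connectivity)
    if n == 0:
        return labels, []
    sizes = np.bincount(labels.ravel())
    overlapping = set(np.unique(labels[accepted])) - {0}
    ids = [
        i
        for i in range(1, n + 1)
        if i not in overlapping
        and config.min_component_voxels <= sizes[i] <= config.max_component_voxels
    ]
    if not ids:
        return labels, []
    centroids = ndi.center_of_mass(marked, labels, ids)
    peaks = ndi.maximum_position(response, labels, ids)
    out = []
    for i, centroid, peak in zip(ids, centroids, peaks):
        out.append((tuple(float(c) for c in centroid), int(sizes[i]), tuple(int(p) for p in peak)))
        accepted |= labels == i
    return labels, out


def detect_tcells(
    volume: ImageVolume,
    config: DetectionConfig,
    channel: str = "green",
    mask: OrganMask | None = None,
) -> list[CellDetection]:
    """Full T-cell detection pipeline on one channel.

    Filter, threshold and group at each scale in ascending order; a
    component overlapping a detection already accepted at a finer scale is
    discarded so a single cell is never re-counted at coarse scales.  Each
    surviving component yields one detection carrying its top-hat intensity.
    If a mask is given, detections are assigned region labels and those
    outside every labelled region are dropped (implausible-location filter).
    """
    img = volume.channel(channel).astype(np.float64)
    accepted = np.zeros(img.shape, dtype=bool)
    detections: list[CellDetection] = []
    for sigma, threshold in zip(config.sigma_list_um, config.thresholds()):
        response = mexican_hat_filter(img, sigma, volume.voxel_size_um, config.gamma)
        _, found = _components_at_scale(response, threshold, config, accepted)
        sigma3 = tuple(np.broadcast_to(np.atleast_1d(np.asarray(sigma, float)), (3,)))
        for centroid, size, peak in found:
            detections.append(
                CellDetection(
                    centroid=centroid,
                    channel=channel,
                    scale_sigma_um=sigma3,
                    component_voxels=size,
                    peak_voxel=peak,
                )
            )
    detections = tophat_intensity(
        img, detections, config.tophat_radius_um, volume.voxel_size_um
    )
    if mask is not None:
        detections = assign_regions(detections, mask, drop_outside=True)
    return detections


def assign_regions(
    detections: list[CellDetection],
    mask: OrganMask,
    drop_outside: bool = False,
) -> list[CellDetection]:
    """Label each detection with the mask region at its centroid."""
    kept = []
    for det in detections:
        z, y, x = (int(round(c)) for c in det.centroid)
        det.region_label = mask.region_name_at(z, y, x)
        if drop_outside and det.region_label == "other":
            continue
        kept.append(det)
    return kept


def count_cells_by_region(
    detections: list[CellDetection], mask: OrganMask
) -> dict[str, int]:
    """Count detections per mask region; unlabelled voxels count as "other"."""
    counts = {name: 0 for name in mask.label_map}
    counts["other"] = 0
    for det in detections:
        z, y, x = (int(round(c)) for c in det.centroid)
        counts[mask.region_name_at(z, y, x)] += 1
    return counts


# ---------------------------------------------------------------------------
# MSC classifier


def extract_msc_features(
    red: np.ndarray,
    green: np.ndarray,
    config: DetectionConfig,
    voxel_size_um: tuple[float, float, float],
) -> np.ndarray:
    """Per-voxel 4-feature map, shape (Z, Y, X, 4).

    Feature order is fixed: top-hat(red), top-hat(green), Mexican-hat(red),
    Mexican-hat(green), all at the finest configured scale.
    """
    red = np.asarray(red, dtype=np.float64)
    green = np.asarray(green, dtype=np.float64)
    if red.shape != green.shape:
        raise AlignmentError("red and green channels must share a shape")
    sigma = config.sigma_list_um[0]
    features = np.stack(
        [
            white_tophat(red, config.tophat_radius_um, voxel_size_um),
            white_tophat(green, config.tophat_radius_um, voxel_size_um),
            mexican_hat_filter(red, sigma, voxel_size_um, config.gamma),
            mexican_hat_filter(green, sigma, voxel_size_um, config.gamma),
        ],
        axis=-1,
    )
    return features.astype(np.float32)


@dataclass
class MscClassifier:
    """Bagged decision-tree ensemble over the 4 voxel features."""

    model: BaggingClassifier
    feature_names: tuple[str, ...] = MSC_FEATURE_NAMES
    n_trees: int = 0
    oob_accuracy: float = float("nan")
    n_per_class: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """MSC probability per feature vector (rows of length 4)."""
        features = np.asarray(features)
        if features.shape[-1] != len(self.feature_names):
            raise ConfigError(
                f"feature vectors must have length {len(self.feature_names)}"
            )
        return self.model.predict_proba(features.reshape(-1, features.shape[-1]))[:, 1]


def train_msc_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 50,
    rng_seed: int = 0,
) -> MscClassifier:
    """Fit the bagged-tree voxel classifier.

    Each tree is fit on a bootstrap resample; out-of-bag votes give an
    unbiased accuracy estimate without a held-out set.  Deterministic for a
    fixed seed.
    """
    features = np.asarray(features, dtype=np.float64).reshape(-1, len(MSC_FEATURE_NAMES))
    labels = np.asarray(labels).astype(int).ravel()
    if features.shape[0] != labels.shape[0]:
        raise AlignmentError("features and labels disagree in length")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    if n_trees < 1:
        raise ConfigError("n_trees must be >= 1")
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=rng_seed),
        n_estimators=n_trees,
        oob_score=True,
        random_state=rng_seed,
        n_jobs=1,
    )
    model.fit(features, labels)
    return MscClassifier(
        model=model,
        n_trees=n_trees,
        oob_accuracy=float(model.oob_score_),
        n_per_class={int(c): int(n) for c, n in zip(classes, counts)},
    )


def detect_mscs(
    volume: ImageVolume,
    classifier: MscClassifier,
    config: DetectionConfig,
    mask: OrganMask | None = None,
) -> list[CellDetection]:
    """Classify voxels, group positives in 3D, one detection per component.

    Only voxels whose red top-hat exceeds ``msc_candidate_min_tophat`` are
    sent to the ensemble (everything dimmer cannot be a labelled cell);
    probability > 0.5 marks a voxel, so an even split votes non-MSC.
    """
    if classifier is None or getattr(classifier, "model", None) is None:
        raise CryoAssayError("MSC classifier is not trained")
    red = volume.channel("red").astype(np.float64)
    green = volume.channel("green").astype(np.float64)
    features = extract_msc_features(red, green, config, volume.voxel_size_um)
    candidates = features[..., 0] > config.msc_candidate_min_tophat
    marked = np.zeros(red.shape, dtype=bool)
    if candidates.any():
        proba = classifier.predict_proba(features[candidates])
        marked[candidates] = proba > 0.5
    labels, n = connected_components_3d(marked, config.connectivity)
    detections: list[CellDetection] = []
    if n:
        sizes = np.bincount(labels.ravel())
        ids = [
            i
            for i in range(1, n + 1)
            if config.min_component_voxels <= sizes[i] <= config.max_component_voxels
        ]
        if ids:
            centroids = ndi.center_of_mass(marked, labels, ids)
            peaks = ndi.maximum_position(features[..., 0], labels, ids)
            sigma0 = tuple(
                np.broadcast_to(
                    np.atleast_1d(np.asarray(config.sigma_list_um[0], float)), (3,)
                )
            )
            for i, centroid, peak in zip(ids, centroids, peaks):
                detections.append(
                    CellDetection(
                        centroid=tuple(float(c) for c in centroid),
                        channel="red",
                        scale_sigma_um=sigma0,
                        component_voxels=int(sizes[i]),
                        peak_voxel=tuple(int(p) for p in peak),
                    )
                )
    detections = tophat_intensity(
        red, detections, config.tophat_radius_um, volume.voxel_size_um
    )
    if mask is not None:
        detections = assign_regions(detections, mask, drop_outside=True)
    return detections


def make_msc_training_set(
    volume: ImageVolume,
    truth,
    config: DetectionConfig,
    n_negatives_per_positive: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a labelled voxel sample from a phantom with known red cells.

    Positives are the ground-truth MSC centroid voxels only.  The voxels
    around each cell — the PSF halo and the possible subsurface-echo voxel
    one section deeper — are ambiguous (signal present but attenuated), so
    they are excluded from both classes rather than mislabelled.  Negatives
    are random voxels outside every exclusion zone; the phantom's green
    T-cells are left in place so the classifier sees (and learns to reject)
    cross-channel signal.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    features = extract_msc_features(
        volume.channel("red"), volume.channel("green"), config, volume.voxel_size_um
    )
    red_cells = truth.for_channel("red")
    shape = volume.grid_shape
    positive = np.zeros(shape, dtype=bool)
    ambiguous = np.zeros(shape, dtype=bool)
    for _, row in red_cells.iterrows():
        z, y, x = int(row["z"]), int(row["y"]), int(row["x"])
        positive[z, y, x] = True
        if z + 1 < shape[0]:
            ambiguous[z + 1, y, x] = True
    exclusion = ndi.binary_dilation(positive | ambiguous, iterations=2)
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise DegenerateTrainingError("phantom contains no red cells")
    neg_candidates = np.argwhere(~exclusion)
    neg_idx = rng.choice(
        len(neg_candidates), size=n_negatives_per_positive * n_pos, replace=False
    )
    pos_coords = np.argwhere(positive)
    coords = np.vstack([pos_coords, neg_candidates[neg_idx]])
    labels = np.concatenate(
        [np.ones(len(pos_coords), dtype=int), np.zeros(len(neg_idx), dtype=int)]
    )
    feats = features[coords[:, 0], coords[:, 1], coords[:, 2]]
    return feats, labels
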