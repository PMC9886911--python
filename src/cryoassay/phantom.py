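"""Synthetic cryo-imaging phantoms with exact ground truth.

The generator emulates the statistical structure of block-face cryo-imaging
volumes: an autofluorescent organ on a dark background, point-like labelled
cells (about one voxel across in-plane), strongly anisotropic voxels
(40 um sections vs 10.5 um in-plane pixels), CFSE label intensity halving
with each cell division, and "subsurface" echoes where a cell below the
block face re-appears, attenuated, in the next section.

Every stochastic step draws from an explicit :class:`numpy.random.Generator`;
identical spec + seed reproduce volumes, masks and ground truth bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import (
    DEFAULT_VOXEL_SIZE_UM,
    CapacityError,
    GeometryError,
    GroundTruth,
    ImageVolume,
    InvalidParameterError,
    OrganMask,
    concat_ground_truths,
)

SPLEEN_LABELS = {"red_pulp": 1, "white_pulp": 2, "marginal_zone": 3}
NODE_LABELS = {"cortex": 1, "paracortex": 2}

#: Autofluorescence means per channel per region, 0-255 scale.  Red pulp is
#: the most autofluorescent splenic compartment in the green band.
DEFAULT_BACKGROUND = {
    "brightfield": {"background": 20.0, "default": 110.0},
    "green": {
        "background": 2.0,
        "red_pulp": 12.0,
        "white_pulp": 8.0,
        "marginal_zone": 10.0,
        "cortex": 10.0,
        "paracortex": 8.0,
        "default": 10.0,
    },
    "red": {
        "background": 2.0,
        "red_pulp": 6.0,
        "white_pulp": 5.0,
        "marginal_zone": 6.0,
        "cortex": 6.0,
        "paracortex": 5.0,
        "default": 6.0,
    },
}

DEFAULT_NOISE_SD = {"brightfield": 4.0, "green": 2.0, "red": 2.0}


@dataclass
class RegionGeometry:
    """Nested ellipsoidal region layout, all radii in micrometres.

    For a spleen the envelope holds ``n_wp_nodules`` spherical white-pulp
    nodules of radius ``wp_radius_um``; the marginal zone is a
    ``mz_shell_voxels``-thick shell of red pulp hugging each nodule.  For a
    lymph node the envelope is cortex and a concentric core (scaled by
    ``paracortex_fraction`` per axis) is paracortex.
    """

    envelope_radii_um: tuple[float, float, float] = (240.0, 250.0, 250.0)
    n_wp_nodules: int = 2
    wp_radius_um: float = 100.0
    mz_shell_voxels: int = 1
    paracortex_fraction: float = 0.6


@dataclass
class PhantomSpec:
    """Everything needed to build one phantom organ deterministically."""

    grid_shape: tuple[int, int, int] = (18, 72, 72)
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    organ: Literal["spleen", "lymph_node"] = "spleen"
    region_geometry: RegionGeometry = field(default_factory=RegionGeometry)
    background_levels: dict = field(default_factory=lambda: DEFAULT_BACKGROUND)
    noise_sd: dict = field(default_factory=lambda: DEFAULT_NOISE_SD)
    psf_sigma_um: tuple[float, float, float] = (12.0, 6.0, 6.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise InvalidParameterError("grid_shape axes must all be >= 8")
        if any(d <= 0 for d in self.voxel_size_um):
            raise InvalidParameterError("voxel sizes must be positive")
        if self.organ not in ("spleen", "lymph_node"):
            raise InvalidParameterError(f"unknown organ {self.organ!r}")


@dataclass
class CellPopulationSpec:
    """One homed cell population: where, which channel, how bright, how divided.

    ``generation_model`` is ``("fixed", g)`` for exactly g divisions per cell,
    ``("poisson", lam)`` for g ~ Poisson(lam), or ``("none", 0)`` for
    undivided cells.
    """

    n_cells: int
    region_label: str
    channel: Literal["green", "red"] = "green"
    base_intensity_I0: float = 200.0
    generation_model: tuple[str, float] = ("none", 0.0)
    intensity_noise_cv: float = 0.1
    subsurface_fraction: float = 0.3
    subsurface_attenuation: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise InvalidParameterError("n_cells must be >= 0")
        if not 0.0 < self.base_intensity_I0 <= 255.0:
            raise InvalidParameterError("base_intensity_I0 must be in (0, 255]")
        if not 0.0 <= self.subsurface_fraction <= 1.0:
            raise InvalidParameterError("subsurface_fraction must be in [0, 1]")
        if not 0.0 < self.subsurface_attenuation < 1.0:
            raise InvalidParameterError("subsurface_attenuation must be in (0, 1)")
        kind = self.generation_model[0]
        if kind not in ("fixed", "poisson", "none"):
            raise InvalidParameterError(f"unknown generation model {kind!r}")


def cfse_generation_intensity(
    I0: float, g: int, noise_cv: float, rng: np.random.Generator
) -> float:
    """Emitted CFSE intensity after ``g`` divisions.

    The covalently bound dye is split between daughters at each division, so
    intensity halves per generation: ``I0 * 2**-g * (1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)``, clipped to [0, 255].
    """
    if not 0.0 < I0 <= 255.0:
        raise InvalidParameterError("I0 must be in (0, 255]")
    if g < 0 or int(g) != g:
        raise InvalidParameterError("division count g must be a non-negative integer")
    value = I0 * 2.0 ** (-int(g))
    if noise_cv > 0.0:
        value *= 1.0 + rng.normal(0.0, noise_cv)
    return float(np.clip(value, 0.0, 255.0))


def _ellipsoid(shape, voxel_size_um, center_um, radii_um) -> np.ndarray:
    """Boolean ellipsoid on an anisotropic grid, everything in um."""
    axes = []
    for n, d, c, r in zip(shape, voxel_size_um, center_um, radii_um):
        coords = (np.arange(n) + 0.5) * d
        axes.append(((coords - c) / r) ** 2)
    zz, yy, xx = np.ix_(axes[0], axes[1], axes[2])
    return (zz + yy + xx) <= 1.0


def build_organ_mask(spec: PhantomSpec) -> OrganMask:
    """Build the labelled region mask for one phantom organ.

    Spleen: red pulp fills the envelope, white-pulp nodules are placed by
    rejection sampling (pairwise separated where the envelope allows it),
    and the marginal zone is carved from red pulp as a thin dilation shell
    around white pulp — the white-pulp/red-pulp interface.
    """
    geo = spec.region_geometry
    shape = spec.grid_shape
    extent_um = [n * d for n, d in zip(shape, spec.voxel_size_um)]
    center_um = [e / 2.0 for e in extent_um]
    for r, e in zip(geo.envelope_radii_um, extent_um):
        if 2 * r > e:
            raise GeometryError("organ envelope exceeds the grid extent")

    envelope = _ellipsoid(shape, spec.voxel_size_um, center_um, geo.envelope_radii_um)
    labels = np.zeros(shape, dtype=np.int32)

    if spec.organ == "lymph_node":
        core_radii = [r * geo.paracortex_fraction for r in geo.envelope_radii_um]
        core = _ellipsoid(shape, spec.voxel_size_um, center_um, core_radii)
        labels[envelope] = NODE_LABELS["cortex"]
        labels[core & envelope] = NODE_LABELS["paracortex"]
        return OrganMask(labels, dict(NODE_LABELS), spec.voxel_size_um)

    labels[envelope] = SPLEEN_LABELS["red_pulp"]
    rng = np.random.default_rng(spec.rng_seed)
    r_wp = geo.wp_radius_um
    if geo.n_wp_nodules > 0 and r_wp >= min(geo.envelope_radii_um):
        raise GeometryError("white-pulp nodule radius exceeds the envelope")

    centers: list[np.ndarray] = []
    wp = np.zeros(shape, dtype=bool)
    for _ in range(geo.n_wp_nodules):
        placed = False
        # first insist on non-overlapping nodules, then progressively relax
        # the separation so that enlarged (inflamed) white pulp may merge
        for min_sep in (2.0 * r_wp, 1.0 * r_wp, 0.0):
            for _try in range(400):
                u = rng.uniform(-1.0, 1.0, size=3)
                cand = np.array(
                    [
                        c + u_i * max(r_env - r_wp, 0.0)
                        for c, u_i, r_env in zip(center_um, u, geo.envelope_radii_um)
                    ]
                )
                # nodule must sit fully inside the envelope
                if sum(
                    ((cand[i] - center_um[i]) / max(geo.envelope_radii_um[i] - r_wp, 1e-9))
                    ** 2
                    for i in range(3)
                ) > 1.0:
                    continue
                if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                    centers.append(cand)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise GeometryError("could not place white-pulp nodules inside envelope")
        wp |= _ellipsoid(shape, spec.voxel_size_um, centers[-1], (r_wp, r_wp, r_wp))

    wp &= envelope
    labels[wp] = SPLEEN_LABELS["white_pulp"]
    if geo.mz_shell_voxels > 0 and wp.any():
        shell = ndi.binary_dilation(
            wp,
            structure=ndi.generate_binary_structure(3, 1),
            iterations=geo.mz_shell_voxels,
        )
        mz = shell & envelope & ~wp
        labels[mz] = SPLEEN_LABELS["marginal_zone"]
    return OrganMask(labels, dict(SPLEEN_LABELS), spec.voxel_size_um)


def _peak_normalized_psf_sigmas(spec: PhantomSpec) -> np.ndarray:
    return np.array(
        [s / d for s, d in zip(spec.psf_sigma_um, spec.voxel_size_um)], dtype=float
    )


def _psf_peak_factor(sigmas_vox: np.ndarray) -> float:
    """Central value of the unit-mass separable Gaussian smoothing kernel."""
    peak = 1.0
    for s in sigmas_vox:
        radius = max(int(4.0 * s + 0.5), 1)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        peak *= (k / k.sum())[radius]
    return float(peak)


def place_cells(
    mask: OrganMask,
    pop: CellPopulationSpec,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """Place one population and return its channel increment plus ground truth.

    Each cell is a point source at a voxel of the target region, blurred by
    the anisotropic Gaussian PSF; the blur kernel is peak-normalised so the
    centroid voxel carries the cell's emitted intensity.  With probability
    ``subsurface_fraction`` an attenuated echo is added one section deeper;
    echoes are rendering artefacts and never appear in the ground truth.
    """
    region = mask.region(pop.region_label)
    candidates = np.argwhere(region)
    if pop.n_cells > len(candidates):
        raise CapacityError(
            f"region {pop.region_label!r} has {len(candidates)} voxels "
            f"for {pop.n_cells} cells"
        )
    increment = np.zeros(mask.labels.shape, dtype=np.float64)
    if pop.n_cells == 0:
        return increment, GroundTruth(pd.DataFrame(), mask.voxel_counts())

    picks = candidates[rng.choice(len(candidates), size=pop.n_cells, replace=False)]
    kind, value = pop.generation_model
    if kind == "fixed":
        gens = np.full(pop.n_cells, int(value), dtype=int)
    elif kind == "poisson":
        gens = rng.poisson(float(value), size=pop.n_cells)
    else:
        gens = np.zeros(pop.n_cells, dtype=int)

    nz = mask.labels.shape[0]
    rows = []
    for i, ((z, y, x), g) in enumerate(zip(picks, gens)):
        intensity = cfse_generation_intensity(
            pop.base_intensity_I0, int(g), pop.intensity_noise_cv, rng
        )
        increment[z, y, x] += intensity
        if rng.random() < pop.subsurface_fraction and z + 1 < nz:
            increment[z + 1, y, x] += pop.subsurface_attenuation * intensity
        rows.append(
            {
                "cell_id": i,
                "z": int(z),
                "y": int(y),
                "x": int(x),
                "channel": pop.channel,
                "generation": int(g),
                "intensity": intensity,
                "region": pop.region_label,
            }
        )

    sigmas = _peak_normalized_psf_sigmas(spec)
    blurred = ndi.gaussian_filter(increment, sigma=sigmas, mode="constant")
    blurred /= _psf_peak_factor(sigmas)
    truth = GroundTruth(pd.DataFrame(rows), mask.voxel_counts())
    return blurred, truth


def render_volume(
    mask: OrganMask,
    increments: dict[str, np.ndarray],
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> ImageVolume:
    """Compose backgrounds, cell increments and sensor noise into 8-bit data.

    Per channel: region autofluorescence + sum of population increments +
    Normal(0, noise_sd), clipped to [0, 255] and quantised.
    """
    from .core import CHANNELS

    shape = mask.labels.shape
    planes = []
    inv_map = {v: k for k, v in mask.label_map.items()}
    for channel in CHANNELS:
        levels = spec.background_levels.get(channel, {})
        default = levels.get("default", 0.0)
        bg = np.full(shape, levels.get("background", 0.0), dtype=np.float64)
        for label_value, name in inv_map.items():
            bg[mask.labels == label_value] = levels.get(name, default)
        plane = bg
        if channel in increments:
            if increments[channel].shape != shape:
                raise InvalidParameterError("increment shape does not match mask")
            plane = plane + increments[channel]
        sd = spec.noise_sd.get(channel, 0.0)
        if sd > 0:
            plane = plane + rng.normal(0.0, sd, size=shape)
        planes.append(np.clip(np.round(plane), 0, 255).astype(np.uint8))
    return ImageVolume(np.stack(planes), CHANNELS, spec.voxel_size_um)


def generate_phantom(
    spec: PhantomSpec,
    populations: list[CellPopulationSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume, OrganMask, GroundTruth]:
    """Build mask, place all populations, render: one phantom end to end."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    mask = build_organ_mask(spec)
    increments: dict[str, np.ndarray] = {}
    truths = []
    for pop in populations or []:
        inc, truth = place_cells(mask, pop, spec, rng)
        increments[pop.channel] = increments.get(pop.channel, 0.0) + inc
        truths.append(truth)
    volume = render_volume(mask, increments, spec, rng)
    truth = (
        concat_ground_truths(truths)
        if truths
        else GroundTruth(pd.DataFrame(), mask.voxel_counts())
    )
    return volume, mask, truth
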