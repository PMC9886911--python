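"""Shared fixtures and the greedy ground-truth matching oracle."""

from __future__ import annotations

import numpy as np
import pytest

from cryoassay.phantom import (
    CellPopulationSpec,
    PhantomSpec,
    RegionGeometry,
    generate_phantom,
)


def greedy_match(detections, truth, channel="green", max_dz=1.0, max_dxy=2.0):
    """Greedy bipartite matching of detections to ground-truth centroids.

    A detection matches an unused true cell within 1 section in z and
    2 voxels in-plane; returns (precision, recall).
    """
    gt = truth.for_channel(channel)[["z", "y", "x"]].to_numpy(float)
    if len(gt) == 0:
        return (0.0 if detections else 1.0), 1.0
    used = np.zeros(len(gt), dtype=bool)
    tp = 0
    for det in detections:
        c = np.asarray(det.centroid, dtype=float)
        dz = np.abs(gt[:, 0] - c[0])
        dxy = np.hypot(gt[:, 1] - c[1], gt[:, 2] - c[2])
        ok = np.flatnonzero((dz <= max_dz) & (dxy <= max_dxy) & ~used)
        if len(ok):
            used[ok[np.argmin(dxy[ok])]] = True
            tp += 1
    precision = tp / len(detections) if detections else 1.0
    recall = tp / len(gt)
    return precision, recall


SMALL_GEOMETRY = RegionGeometry(
    envelope_radii_um=(520.0, 560.0, 560.0),
    n_wp_nodules=2,
    wp_radius_um=130.0,
    mz_shell_voxels=2,
)
SMALL_SHAPE = (32, 112, 112)


def small_spleen(seed, populations=()):
    """A compact spleen phantom used across the detection/cfse tests."""
    spec = PhantomSpec(
        grid_shape=SMALL_SHAPE, region_geometry=SMALL_GEOMETRY, rng_seed=seed
    )
    return generate_phantom(spec, list(populations))


def tcell_pop(n, **kwargs):
    defaults = dict(
        n_cells=n,
        region_label="white_pulp",
        channel="green",
        base_intensity_I0=200.0,
        generation_model=("none", 0.0),
        intensity_noise_cv=0.1,
        subsurface_fraction=0.3,
        subsurface_attenuation=0.5,
    )
    defaults.update(kwargs)
    return CellPopulationSpec(**defaults)


def msc_pop(n, **kwargs):
    defaults = dict(
        n_cells=n,
        region_label="marginal_zone",
        channel="red",
        base_intensity_I0=220.0,
        generation_model=("none", 0.0),
        intensity_noise_cv=0.1,
        subsurface_fraction=0.3,
        subsurface_attenuation=0.5,
    )
    defaults.update(kwargs)
    return CellPopulationSpec(**defaults)


@pytest.fixture(scope="session")
def empty_small_spleen():
    return small_spleen(101)


@pytest.fixture(scope="session")
def seeded_small_spleen():
    """150 bright undivided T-cells in the white pulp."""
    return small_spleen(102, [tcell_pop(150)])
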