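"""Detection pipeline: filter oracles, thresholding, grouping, classifiers."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from cryoassay.core import ConfigError, CryoAssayError, DegenerateTrainingError, ResolutionError
from cryoassay.detection import (
    DetectionConfig,
    calibrate_t_isolated,
    connected_components_3d,
    count_cells_by_region,
    detect_mscs,
    detect_tcells,
    extract_msc_features,
    make_msc_training_set,
    mexican_hat_filter,
    threshold_detect,
    tophat_intensity,
    train_msc_classifier,
    white_tophat,
    CellDetection,
)
from cryoassay.phantom import (
    PhantomSpec,
    RegionGeometry,
    generate_phantom,
)
from conftest import greedy_match, msc_pop, small_spleen, tcell_pop

ISO = (1.0, 1.0, 1.0)  # isotropic unit voxels for the synthetic filter tests


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_log_kernel(sigma_vox, voxel_size, gamma=1.25):
    """Full 3D negated scale-normalised LoG kernel, assembled from analytic
    1D Gaussian / second-derivative samples (truncate 4 sigma)."""
    ks = []
    for order_axis in range(3):
        term = None
        for axis in range(3):
            s = sigma_vox[axis]
            radius = max(int(4.0 * s + 0.5), 1)
            x = np.arange(-radius, radius + 1, dtype=float)
            g = np.exp(-0.5 * (x / s) ** 2)
            g /= g.sum()
            if axis == order_axis:
                k1 = g * (x * x - s * s) / s**4
                k1 = (k1 - k1.mean()) / voxel_size[axis] ** 2
            else:
                k1 = g
            shape = [1, 1, 1]
            shape[axis] = k1.size
            k1 = k1.reshape(shape)
            term = k1 if term is None else term * k1
        ks.append(term)
    shape = np.max([k.shape for k in ks], axis=0)
    kernel = np.zeros(shape)
    for k in ks:
        pad = [((s - ks_) // 2, (s - ks_) // 2) for s, ks_ in zip(shape, k.shape)]
        kernel += np.pad(k, pad)
    sigma_um = np.asarray(sigma_vox) * np.asarray(voxel_size)
    sigma_bar = float(np.exp(np.mean(np.log(sigma_um))))
    return -(sigma_bar ** (2.0 * gamma)) * kernel


def brute_force_correlate(image, kernel):
    """Direct spatial correlation with reflect padding, no separability."""
    rz, ry, rx = (s // 2 for s in kernel.shape)
    padded = np.pad(image, ((rz, rz), (ry, ry), (rx, rx)), mode="symmetric")
    out = np.zeros_like(image, dtype=float)
    for dz in range(kernel.shape[0]):
        for dy in range(kernel.shape[1]):
            for dx in range(kernel.shape[2]):
                w = kernel[dz, dy, dx]
                if w == 0.0:
                    continue
                out += w * padded[
                    dz : dz + image.shape[0],
                    dy : dy + image.shape[1],
                    dx : dx + image.shape[2],
                ]
    return out


def brute_force_tophat(image, footprint):
    """White top-hat via explicit min-then-max over footprint offsets."""
    offs = np.argwhere(footprint) - np.array(footprint.shape) // 2
    pad = np.abs(offs).max(axis=0)
    padded = np.pad(image.astype(float), [(p, p) for p in pad], mode="symmetric")
    sl = lambda o: padded[
        pad[0] + o[0] : pad[0] + o[0] + image.shape[0],
        pad[1] + o[1] : pad[1] + o[1] + image.shape[1],
        pad[2] + o[2] : pad[2] + o[2] + image.shape[2],
    ]
    eroded = np.min([sl(o) for o in offs], axis=0)
    pad_e = np.pad(eroded, [(p, p) for p in pad], mode="symmetric")
    sl_e = lambda o: pad_e[
        pad[0] + o[0] : pad[0] + o[0] + image.shape[0],
        pad[1] + o[1] : pad[1] + o[1] + image.shape[1],
        pad[2] + o[2] : pad[2] + o[2] + image.shape[2],
    ]
    opened = np.max([sl_e(-o) for o in offs], axis=0)
    return image.astype(float) - opened


def brute_force_components(mask, connectivity):
    """Flood-fill connected components; returns a canonical partition."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            voxel = stack.pop()
            comp.append(voxel)
            for off in offsets:
                nb = tuple(v + o for v, o in zip(voxel, off))
                if any(n < 0 or n >= s for n, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        components.append(frozenset(comp))
    return set(components)


def gaussian_blob(shape, center, sigma, peak=1.0):
    sigma = np.broadcast_to(np.atleast_1d(np.asarray(sigma, float)), (3,))
    zz, yy, xx = np.indices(shape, dtype=float)
    r2 = sum(
        ((a - c) / s) ** 2 for a, c, s in zip((zz, yy, xx), center, sigma)
    )
    return peak * np.exp(-0.5 * r2)


# ---------------------------------------------------------------------------
# Mexican hat filter


class TestMexicanHatFilter:
    def test_constant_volume_gives_zero_response(self):
        img = np.full((12, 12, 12), 37.0)
        resp = mexican_hat_filter(img, 2.0, ISO)
        assert np.max(np.abs(resp)) < 1e-9

    def test_matches_brute_force_direct_convolution(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, size=(16, 16, 16))
        for sigma_vox in ((1.0, 1.0, 1.0), (0.6, 1.5, 1.5)):
            fast = mexican_hat_filter(img, sigma_vox, ISO)
            kernel = brute_force_log_kernel(sigma_vox, ISO)
            slow = brute_force_correlate(img, kernel)
            assert np.max(np.abs(fast - slow)) < 1e-6

    def test_scale_selection_peaks_at_matched_sigma(self):
        # a Gaussian blob of width sigma0 maximises the normalised response
        # over the scale list at sigma = sigma0
        sigma0 = 2.0
        img = gaussian_blob((32, 32, 32), (16, 16, 16), sigma0, peak=100.0)
        scales = [1.0, 1.4, 2.0, 2.8, 4.0]
        center_resp = [
            mexican_hat_filter(img, s, ISO)[16, 16, 16] for s in scales
        ]
        assert int(np.argmax(center_resp)) == scales.index(sigma0)

    def test_two_separated_blobs_give_two_maxima(self):
        sigma0 = 1.5
        img = gaussian_blob((16, 48, 16), (8, 14, 8), sigma0, 100.0) + gaussian_blob(
            (16, 48, 16), (8, 34, 8), sigma0, 100.0
        )
        resp = mexican_hat_filter(img, sigma0, ISO)
        # exhaustive local-maximum scan above half the peak response
        peak = resp.max()
        local_max = (resp == ndi.maximum_filter(resp, size=3)) & (resp > 0.5 * peak)
        assert int(local_max.sum()) == 2

    def test_subvoxel_sigma_rejected(self):
        with pytest.raises(ResolutionError):
            mexican_hat_filter(np.zeros((8, 8, 8)), (10.0, 6.0, 6.0), (40.0, 10.5, 10.5))


# ---------------------------------------------------------------------------
# threshold + components


class TestThresholdDetect:
    def test_zero_volume_empty_mask(self):
        assert not threshold_detect(np.zeros((4, 4, 4)), 5.0).any()

    def test_single_voxel_above_threshold(self):
        img = np.zeros((4, 4, 4))
        img[1, 2, 3] = 6.0
        mask = threshold_detect(img, 5.0)
        assert mask.sum() == 1 and mask[1, 2, 3]

    def test_calibrated_threshold_minimally_marks_autofluorescence(
        self, empty_small_spleen
    ):
        control, _, _ = empty_small_spleen
        config = DetectionConfig()
        thresholds = calibrate_t_isolated(control, config)
        # check on an independent unlabeled phantom
        other, _, _ = small_spleen(103)
        img = other.channel("green").astype(float)
        for sigma, threshold in zip(config.sigma_list_um, thresholds):
            resp = mexican_hat_filter(img, sigma, other.voxel_size_um)
            fraction = threshold_detect(resp, threshold).mean()
            assert fraction <= 1e-4

    def test_detection_count_non_increasing_in_threshold(self):
        # isolated cells give unimodal responses: raising T only shrinks each
        # component until it vanishes, so the count cannot grow
        rng = np.random.default_rng(4)
        img = np.zeros((12, 64, 64))
        lattice = [(y, x) for y in (10, 24, 38, 52) for x in (10, 24, 38, 52)]
        for y, x in lattice[:15]:
            img += gaussian_blob((12, 64, 64), (6, y, x), 1.5,
                                 peak=rng.uniform(60, 250))
        resp = mexican_hat_filter(img, 1.5, ISO)
        counts = []
        for t in (20.0, 60.0, 150.0, 400.0, 1200.0):
            _, n = connected_components_3d(threshold_detect(resp, t))
            counts.append(n)
        assert counts[0] > 0
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestConnectedComponents:
    def test_empty_mask(self):
        _, n = connected_components_3d(np.zeros((4, 4, 4), bool))
        assert n == 0

    def test_two_isolated_voxels(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1, 1, 1] = mask[5, 5, 5] = True
        _, n = connected_components_3d(mask, 26)
        assert n == 2

    def test_cell_plus_echo_single_component(self):
        # subsurface echo at (z+1, y, x) merges with its parent under any
        # supported connectivity, so the cell is counted once
        mask = np.zeros((8, 8, 8), bool)
        mask[3, 4, 4] = mask[4, 4, 4] = True
        for connectivity in (6, 18, 26):
            _, n = connected_components_3d(mask, connectivity)
            assert n == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_brute_force_flood_fill(self, connectivity):
        rng = np.random.default_rng(1)
        mask = rng.random((12, 12, 12)) < 0.2
        labels, n = connected_components_3d(mask, connectivity)
        ours = {
            frozenset(map(tuple, np.argwhere(labels == i))) for i in range(1, n + 1)
        }
        assert ours == brute_force_components(mask, connectivity)

    def test_invalid_connectivity(self):
        with pytest.raises(ConfigError):
            connected_components_3d(np.zeros((4, 4, 4), bool), 10)


# ---------------------------------------------------------------------------
# top-hat


class TestTopHat:
    def test_constant_volume_all_zero(self):
        out = white_tophat(np.full((8, 8, 8), 50.0), 2.5, ISO)
        assert np.max(np.abs(out)) < 1e-12

    def test_blob_on_constant_background_recovers_peak(self):
        img = np.full((9, 15, 15), 30.0)
        img[4, 7, 7] += 120.0
        out = white_tophat(img, 3.0, ISO)
        assert out[4, 7, 7] == pytest.approx(120.0, abs=1.0)

    def test_blob_on_zero_background(self):
        img = np.zeros((9, 15, 15))
        img[4, 7, 7] = 90.0
        out = white_tophat(img, 3.0, ISO)
        assert out[4, 7, 7] == pytest.approx(90.0, abs=1.0)

    def test_matches_brute_force_erosion_dilation(self):
        from cryoassay.detection import _tophat_footprint

        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(10, 14, 14)).astype(float)
        radius = 2.5
        fast = white_tophat(img, radius, ISO)
        slow = brute_force_tophat(img, _tophat_footprint(radius, ISO))
        assert np.max(np.abs(fast - slow)) == 0.0

    def test_intensity_assignment_uses_peak_voxel(self):
        img = np.full((9, 15, 15), 20.0)
        img[4, 7, 7] += 100.0
        det = CellDetection(
            centroid=(4.0, 7.0, 7.0),
            channel="green",
            scale_sigma_um=(1.0, 1.0, 1.0),
            component_voxels=1,
            peak_voxel=(4, 7, 7),
        )
        (out,) = tophat_intensity(img, [det], 3.0, ISO)
        assert out.intensity == pytest.approx(100.0, abs=1.0)


# ---------------------------------------------------------------------------
# full T-cell pipeline


@pytest.fixture(scope="module")
def calibrated_config():
    control, _, _ = small_spleen(101)
    config = DetectionConfig()
    return dataclasses.replace(
        config, t_isolated=calibrate_t_isolated(control, config)
    )


class TestDetectTcells:
    def test_empty_sigma_list_rejected(self):
        with pytest.raises(ConfigError):
            DetectionConfig(sigma_list_um=())

    def test_no_cells_no_noise_no_detections(self, calibrated_config):
        spec = PhantomSpec(
            grid_shape=(16, 48, 48),
            region_geometry=RegionGeometry((260.0, 220.0, 220.0)),
            noise_sd={"brightfield": 0.0, "green": 0.0, "red": 0.0},
        )
        volume, mask, _ = generate_phantom(spec, [])
        assert detect_tcells(volume, calibrated_config, mask=mask) == []

    def test_sparse_bright_cells_high_fidelity(self, calibrated_config):
        # 200 cells spread through the whole envelope: little merging
        volume, mask, truth = small_spleen(
            104, [tcell_pop(200, region_label="red_pulp", subsurface_fraction=0.0)]
        )
        detections = detect_tcells(volume, calibrated_config, mask=mask)
        precision, recall = greedy_match(detections, truth)
        assert precision >= 0.95
        assert recall >= 0.9  # small phantom: a few chance-adjacent pairs merge

    def test_echo_invariance_of_count(self, calibrated_config):
        kwargs = dict(region_label="red_pulp", subsurface_attenuation=0.5)
        v0, m0, _ = small_spleen(105, [tcell_pop(200, subsurface_fraction=0.0, **kwargs)])
        v1, m1, _ = small_spleen(105, [tcell_pop(200, subsurface_fraction=1.0, **kwargs)])
        n0 = len(detect_tcells(v0, calibrated_config, mask=m0))
        n1 = len(detect_tcells(v1, calibrated_config, mask=m1))
        assert abs(n1 - n0) <= max(0.02 * n0, 1)

    def test_scale_equivariance_in_plane_dilation(self):
        # dilating blobs and sigma by the same factor leaves the count fixed
        lattice = [(y, x) for y in (8, 20, 32, 44) for x in (8, 20, 32, 44)]
        centers = [(8, y, x) for y, x in lattice[:12]]
        sigma0, factor = 1.5, 2.0
        config = DetectionConfig(
            sigma_list_um=(sigma0,), t_isolated=20.0, min_component_voxels=1,
            max_component_voxels=10_000, tophat_radius_um=4.0,
        )
        img1 = sum(gaussian_blob((16, 48, 48), c, sigma0, 150.0) for c in centers)
        vol1 = np.clip(img1, 0, 255)[None].astype(np.uint8)
        from cryoassay.core import ImageVolume

        v1 = ImageVolume(vol1, ("green",), ISO)
        n1 = len(detect_tcells(v1, config))
        img2 = sum(
            gaussian_blob(
                (16, 96, 96), (c[0], c[1] * 2, c[2] * 2),
                (sigma0, sigma0 * factor, sigma0 * factor), 150.0,
            )
            for c in centers
        )
        v2 = ImageVolume(np.clip(img2, 0, 255)[None].astype(np.uint8), ("green",), ISO)
        config2 = dataclasses.replace(
            config, sigma_list_um=((sigma0, sigma0 * factor, sigma0 * factor),)
        )
        n2 = len(detect_tcells(v2, config2))
        assert n1 == n2 == len(centers)


class TestCountCellsByRegion:
    def test_counts_follow_centroid_labels(self, calibrated_config, seeded_small_spleen):
        volume, mask, truth = seeded_small_spleen
        detections = detect_tcells(volume, calibrated_config, mask=mask)
        counts = count_cells_by_region(detections, mask)
        assert counts["white_pulp"] + counts["marginal_zone"] >= 0.9 * len(detections)
        assert sum(counts.values()) == len(detections)

    def test_background_detection_counts_as_other(self, seeded_small_spleen):
        _, mask, _ = seeded_small_spleen
        det = CellDetection(
            centroid=(0.0, 0.0, 0.0), channel="green",
            scale_sigma_um=(1.0, 1.0, 1.0), component_voxels=1,
        )
        assert count_cells_by_region([det], mask)["other"] == 1


# ---------------------------------------------------------------------------
# MSC classifier


MSC_GEOMETRY = RegionGeometry(
    envelope_radii_um=(650.0, 700.0, 700.0),
    n_wp_nodules=2,
    wp_radius_um=190.0,
    mz_shell_voxels=3,
)


def msc_phantom(seed, populations):
    spec = PhantomSpec(
        grid_shape=(36, 140, 140), region_geometry=MSC_GEOMETRY, rng_seed=seed
    )
    return generate_phantom(spec, populations)


@pytest.fixture(scope="module")
def trained_msc_classifier():
    volume, _, truth = msc_phantom(41, [msc_pop(100), tcell_pop(150)])
    config = DetectionConfig()
    features, labels = make_msc_training_set(
        volume, truth, config, rng=np.random.default_rng(1)
    )
    return train_msc_classifier(features, labels, n_trees=50, rng_seed=7)


class TestMscClassifier:
    def test_feature_map_shape_and_constant_input(self):
        config = DetectionConfig(sigma_list_um=((2.0, 2.0, 2.0),), tophat_radius_um=3.0)
        flat = np.full((10, 12, 12), 40.0)
        features = extract_msc_features(flat, flat, config, ISO)
        assert features.shape == (10, 12, 12, 4)
        assert np.max(np.abs(features)) < 1e-6

    def test_separable_clouds_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, size=(300, 4))
        b = rng.normal(8.0, 1.0, size=(300, 4))
        features = np.vstack([a, b])
        labels = np.repeat([0, 1], 300)
        clf = train_msc_classifier(features, labels, n_trees=100, rng_seed=3)
        predictions = clf.predict_proba(features) > 0.5
        assert np.mean(predictions == labels) == 1.0
        # nearest-centroid oracle agrees: the clouds are trivially separable
        centroids = np.array([a.mean(axis=0), b.mean(axis=0)])
        oracle = np.argmin(
            ((features[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1
        )
        assert np.mean(oracle == labels) == 1.0

    def test_permutation_null_oob_near_half(self):
        rng = np.random.default_rng(6)
        features = np.vstack(
            [rng.normal(0, 1, size=(1000, 4)), rng.normal(8, 1, size=(1000, 4))]
        )
        labels = rng.permutation(np.repeat([0, 1], 1000))
        clf = train_msc_classifier(features, labels, n_trees=50, rng_seed=4)
        assert abs(clf.oob_accuracy - 0.5) <= 0.05

    def test_training_deterministic_for_seed(self):
        rng = np.random.default_rng(7)
        features = np.vstack(
            [rng.normal(0, 1, size=(200, 4)), rng.normal(4, 1, size=(200, 4))]
        )
        labels = np.repeat([0, 1], 200)
        grid = np.random.default_rng(8).normal(2, 2, size=(500, 4))
        a = train_msc_classifier(features, labels, 25, rng_seed=9)
        b = train_msc_classifier(features, labels, 25, rng_seed=9)
        assert np.array_equal(a.predict_proba(grid), b.predict_proba(grid))

    def test_duplicating_training_samples_preserves_predictions(self):
        rng = np.random.default_rng(10)
        features = np.vstack(
            [rng.normal(0, 1, size=(200, 4)), rng.normal(8, 1, size=(200, 4))]
        )
        labels = np.repeat([0, 1], 200)
        grid = np.vstack(
            [rng.normal(0, 1, size=(100, 4)), rng.normal(8, 1, size=(100, 4))]
        )
        a = train_msc_classifier(features, labels, 50, rng_seed=11)
        b = train_msc_classifier(
            np.vstack([features, features]), np.concatenate([labels, labels]),
            50, rng_seed=11,
        )
        assert np.array_equal(a.predict_proba(grid) > 0.5, b.predict_proba(grid) > 0.5)

    def test_single_class_training_rejected(self):
        with pytest.raises(DegenerateTrainingError):
            train_msc_classifier(np.zeros((10, 4)), np.zeros(10), 5)

    def test_untrained_classifier_rejected(self, seeded_small_spleen):
        volume, _, _ = seeded_small_spleen
        with pytest.raises(CryoAssayError):
            detect_mscs(volume, None, DetectionConfig())


class TestDetectMscs:
    def test_no_red_cells_no_detections(self, trained_msc_classifier):
        volume, mask, _ = msc_phantom(45, [])
        detections = detect_mscs(volume, trained_msc_classifier, DetectionConfig(), mask)
        assert len(detections) == 0

    def test_marginal_zone_mscs_high_fidelity(self, trained_msc_classifier):
        volume, mask, truth = msc_phantom(42, [msc_pop(100), tcell_pop(150)])
        detections = detect_mscs(volume, trained_msc_classifier, DetectionConfig(), mask)
        precision, recall = greedy_match(detections, truth, channel="red")
        assert precision >= 0.9
        assert recall >= 0.9

    def test_green_only_phantom_cross_channel_rejection(self, trained_msc_classifier):
        volume, mask, _ = msc_phantom(43, [tcell_pop(150)])
        detections = detect_mscs(volume, trained_msc_classifier, DetectionConfig(), mask)
        assert len(detections) <= 0.01 * 150
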