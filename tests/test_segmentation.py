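"""Vesselness, pulse gating, Otsu, branch labeling, section placement."""

import numpy as np
import pytest

import retiflow as rf
from retiflow.containers import ArterialMap, MomentVideo
from retiflow.errors import (DegenerateInputError, InvalidSpecError,
                             NoVesselFoundError)
from retiflow.segmentation import (SegmentationConfig, build_arterial_mask,
                                   frangi_vesselness, label_branches,
                                   otsu_threshold, place_sections,
                                   pulse_correlation_map, segment)


def gaussian_ridge(shape=(48, 48), row=24, sigma=2.5):
    rr = np.arange(shape[0])[:, None]
    return np.exp(-0.5 * ((rr - row) / sigma) ** 2) * np.ones((1, shape[1]))


class TestFrangi:
    def test_constant_image_has_zero_vesselness(self):
        assert np.all(frangi_vesselness(np.full((32, 32), 3.7)) == 0)

    def test_ridge_maximum_on_centerline(self):
        v = frangi_vesselness(gaussian_ridge())
        inner = v[:, 8:-8]  # away from border effects
        rows = np.argmax(inner, axis=0)
        assert np.all(np.abs(rows - 24) <= 1)

    def test_vessel_pixels_respond_stronger_than_background(self, phantom):
        _, video, truth = phantom
        m2_mean = video.m2.mean(axis=-1)
        img = np.sqrt(np.clip(m2_mean - np.median(m2_mean), 0, None))
        v = frangi_vesselness(img)
        on = v[truth.artery_mask].mean()
        off = v[~truth.artery_mask].mean()
        assert on > 5 * off

    def test_empty_scales_rejected(self):
        with pytest.raises(InvalidSpecError):
            frangi_vesselness(gaussian_ridge(), scales=())


class TestPulseCorrelation:
    def test_identical_series_correlate_to_one(self):
        ref = np.sin(np.linspace(0, 12 * np.pi, 256))
        series = np.tile(ref, (4, 4, 1))
        r = pulse_correlation_map(series, ref)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_negated_series_correlate_to_minus_one(self):
        ref = np.sin(np.linspace(0, 12 * np.pi, 256))
        r = pulse_correlation_map(-np.tile(ref, (4, 4, 1)), ref)
        np.testing.assert_allclose(r, -1.0, atol=1e-12)

    def test_independent_noise_has_small_correlation(self):
        rng = np.random.default_rng(0)
        ref = np.sin(np.linspace(0, 12 * np.pi, 512))
        series = rng.standard_normal((16, 16, 512))
        r = pulse_correlation_map(series, ref)
        # null |r| ~ 1/sqrt(n); 0.2 is ~4.5 sigma
        assert np.quantile(np.abs(r), 0.99) < 0.2

    def test_zero_variance_pixel_is_undefined(self):
        ref = np.sin(np.linspace(0, 12 * np.pi, 64))
        series = np.zeros((4, 4, 64))
        series[0, 0] = ref
        r = pulse_correlation_map(series, ref)
        assert np.isnan(r[1, 1]) and r[0, 0] == pytest.approx(1.0)


def brute_force_otsu(values, nbins=256):
    """Exhaustive between-class variance maximization on a 256-bin histogram."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = None, -1.0
    for cut in range(1, nbins):
        w0, w1 = hist[:cut].sum(), hist[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / w0
        mu1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[cut - 1:cut + 1].mean()
    return best_t


class TestOtsu:
    def test_bimodal_split(self):
        img = np.concatenate([np.zeros(50), np.ones(50)]).reshape(10, 10)
        mask, thr = otsu_threshold(img)
        assert 0 < thr < 1
        assert mask.sum() == 50 and np.all(img[mask] == 1)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            vals = np.concatenate([rng.normal(0.3, 0.1, 200),
                                   rng.normal(0.8, 0.05, 100)])
            _, thr = otsu_threshold(vals.reshape(20, -1))
            assert thr == pytest.approx(brute_force_otsu(vals),
                                        abs=np.ptp(vals) / 128)

    def test_gaussian_mixture_misclassification(self):
        rng = np.random.default_rng(2)
        n = 10_000
        lo = rng.normal(0.2, 0.05, n // 2)
        hi = rng.normal(0.8, 0.05, n // 2)
        img = np.concatenate([lo, hi]).reshape(100, 100)
        mask, _ = otsu_threshold(img)
        labels = np.concatenate([np.zeros(n // 2, bool),
                                 np.ones(n // 2, bool)]).reshape(100, 100)
        assert np.mean(mask != labels) < 0.01

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.ones((8, 8)))


class TestArterialMask:
    def test_phantom_mask_overlaps_truth(self, phantom):
        scene, video, truth = phantom
        amap = build_arterial_mask(video, disc_center=scene.disc_center,
                                   disc_diameter_px=scene.disc_diameter_px)
        inter = (amap.artery_mask & truth.artery_mask).sum()
        dice = 2 * inter / (amap.artery_mask.sum() + truth.artery_mask.sum())
        assert dice >= 0.9  # noise-free phantom, vessels >= 6 px wide

    def test_annulus_never_touches_vessels(self, phantom_map, phantom):
        _, _, truth = phantom
        assert not np.any(phantom_map.background_mask
                          & phantom_map.artery_mask)
        assert not np.any(phantom_map.background_mask & truth.artery_mask)

    def test_full_exclusion_raises_no_vessel(self, phantom):
        scene, video, _ = phantom
        with pytest.raises(NoVesselFoundError):
            build_arterial_mask(video,
                                exclusion_mask=np.ones(scene.shape, bool))

    def test_non_pulsatile_vessel_rejected(self):
        # one beating artery, one steady vessel: only the artery survives
        h, w, k = 48, 48, 200
        t = np.linspace(0, 4.0, k)
        pulse = 1.0 + 0.8 * np.sin(2 * np.pi * 1.25 * t)
        m2 = np.full((h, w, k), 5.0e7)
        m2[10:15, :, :] += 3e7 * pulse[None, None, :]  # pulsatile artery
        m2[30:35, :, :] += 3e7  # steady vessel (vein-like)
        video = MomentVideo(m0=np.ones((h, w, k)), m2=m2,
                            frame_rate_hz=67000.0, pixel_size_um=12.0,
                            window_times_s=t)
        amap = build_arterial_mask(video, reference_pulse=pulse - pulse.mean())
        rows = np.argwhere(amap.artery_mask)[:, 0]
        assert np.all((rows >= 9) & (rows <= 16))
        assert amap.vessel_mask[31:34].any()  # vein seen, but gated out

    def test_masks_deterministic(self, phantom):
        scene, video, _ = phantom
        a = build_arterial_mask(video)
        b = build_arterial_mask(video)
        assert np.array_equal(a.artery_mask, b.artery_mask)
        assert np.array_equal(a.background_mask, b.background_mask)


def straight_map(mask, disc_center=(24.0, 24.0), disc_px=8.0):
    return ArterialMap(artery_mask=mask,
                       background_mask=np.zeros_like(mask, dtype=bool),
                       branch_labels=np.zeros(mask.shape, dtype=int),
                       disc_center=disc_center, disc_diameter_px=disc_px)


class TestBranches:
    def test_two_disjoint_vessels_two_labels(self):
        mask = np.zeros((48, 48), bool)
        mask[10:14, 5:45] = True
        mask[30:34, 5:45] = True
        amap = label_branches(straight_map(mask))
        assert len(amap.branch_ids) == 2

    def test_blob_inside_disc_discarded(self):
        mask = np.zeros((48, 48), bool)
        mask[22:27, 22:27] = True  # entirely within the disc
        amap = label_branches(straight_map(mask, disc_px=16.0))
        assert len(amap.branch_ids) == 0

    def test_phantom_four_branches_with_accurate_endpoints(
            self, phantom, phantom_map):
        _, _, truth = phantom
        assert len(phantom_map.branch_ids) == 4
        for path in phantom_map.centerlines.values():
            d = min(np.linalg.norm(path[-1] - cl[-1])
                    for cl in truth.centerlines.values())
            assert d <= 2.0


class TestSections:
    def test_straight_branch_spacing_and_orthogonality(self):
        mask = np.zeros((64, 64), bool)
        mask[30:35, 7:57] = True  # 50 px long horizontal vessel
        amap = label_branches(straight_map(mask, disc_center=(32.0, 2.0),
                                           disc_px=4.0))
        cfg = SegmentationConfig(section_end_margin_px=0.0)
        amap = place_sections(amap, spacing=10, half_length=6, config=cfg)
        assert len(amap.sections) == 5
        for sec in amap.sections:
            # direction must be orthogonal to the (horizontal) centerline
            angle = np.degrees(np.arccos(abs(sec.direction[0])))
            assert angle <= 5.0

    def test_short_branch_gets_single_section(self):
        mask = np.zeros((48, 48), bool)
        mask[20:23, 10:14] = True  # 4 px long
        amap = label_branches(straight_map(mask, disc_center=(21.0, 2.0),
                                           disc_px=4.0))
        amap = place_sections(amap, spacing=10, half_length=4)
        assert len(amap.sections) == 1

    def test_section_touching_other_branch_dropped(self):
        mask = np.zeros((48, 48), bool)
        mask[20:24, 4:44] = True   # main vessel
        mask[26:29, 4:44] = True   # parallel vessel 3 px away
        amap = label_branches(straight_map(mask, disc_center=(22.0, 2.0),
                                           disc_px=2.0))
        amap = place_sections(amap, spacing=10, half_length=8)
        # every surviving section must sample only its own branch
        for sec in amap.sections:
            coords = np.round(sec.sample_coords()).astype(int)
            coords = coords[(coords[:, 0] >= 0) & (coords[:, 0] < 48)
                            & (coords[:, 1] >= 0) & (coords[:, 1] < 48)]
            touched = amap.branch_labels[coords[:, 0], coords[:, 1]]
            assert set(touched[touched > 0]) <= {sec.branch_id}

    def test_full_segment_pipeline_sections_on_all_branches(
            self, phantom_map):
        branch_with_sections = {s.branch_id for s in phantom_map.sections}
        assert branch_with_sections == set(phantom_map.branch_ids)
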