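"""LoG response properties, detection recovery, and punctum measurement."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from punctaquant import ImageStack, SceneParams, generate_cell_stack
from punctaquant.nuclei import LabelVolume, segment_nuclei
from punctaquant.puncta import detect_puncta, log_response, measure_puncta

from conftest import match_detections

ISO_VOX = (0.1, 0.1, 0.1)


def _gauss_blob(shape, center_vox, sigma_vox, amplitude):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return amplitude * np.exp(-d2 / (2 * sigma_vox ** 2))


class TestLogResponse:
    def test_uniform_image_zero_response(self):
        stack = ImageStack(np.full((1, 10, 20, 20), 55.0), ISO_VOX)
        resp = log_response(stack, scales_um=(0.2, 0.3))
        assert np.all(np.abs(resp) < 1e-6 * 55.0)

    def test_blob_peak_at_center(self):
        img = _gauss_blob((21, 21, 21), (10, 10, 10), 2.0, 100.0)
        stack = ImageStack(img[np.newaxis], ISO_VOX)
        resp = log_response(stack, scales_um=(0.2,))
        assert np.unravel_index(np.argmax(resp), resp.shape) == (10, 10, 10)

    def test_scale_selectivity(self):
        # blobs of sigma 0.2 and 0.4 μm each peak at their matching scale
        img = (_gauss_blob((31, 61, 61), (15, 30, 15), 2.0, 100.0)
               + _gauss_blob((31, 61, 61), (15, 30, 45), 4.0, 100.0))
        stack = ImageStack(img[np.newaxis], ISO_VOX)
        r_small = log_response(stack, scales_um=(0.2,))
        r_large = log_response(stack, scales_um=(0.4,))
        assert r_small[15, 30, 15] > r_large[15, 30, 15]
        assert r_large[15, 30, 45] > r_small[15, 30, 45]

    def test_subvoxel_scale_clamped_with_warning(self, caplog):
        stack = ImageStack(np.ones((1, 6, 10, 10)), (0.5, 0.2, 0.2))
        with caplog.at_level("WARNING"):
            log_response(stack, scales_um=(0.05,))
        assert any("clamp" in rec.message for rec in caplog.records)

    def test_empty_scale_list_rejected(self):
        stack = ImageStack(np.ones((1, 4, 8, 8)), ISO_VOX)
        with pytest.raises(ValueError):
            log_response(stack, scales_um=())


class TestDetection:
    def test_noiseless_recovery(self, clean_analysis, clean_scene):
        _, _, truth, _, puncta, _ = clean_analysis
        recall, precision, pairs = match_detections(puncta, truth)
        assert recall >= 0.95
        assert precision >= 0.95
        errors = [abs(rec.volume - truth.volumes_um3[i]) / truth.volumes_um3[i]
                  for rec, i in pairs]
        assert np.median(errors) <= 0.20

    def test_blank_protein_channel_zero_puncta(self):
        params = SceneParams(puncta_count=0, poisson_scale=0.0, gaussian_sd=0.0,
                             seed=3)
        stack, _ = generate_cell_stack(params)
        nuclei = segment_nuclei(stack)
        resp = log_response(stack)
        labels = detect_puncta(resp, stack, nuclei)
        assert labels.n_labels == 0
        assert measure_puncta(labels, stack, nuclei) == []

    @pytest.mark.parametrize("sep_factor,expected", [(1.5, 2), (0.5, 1)])
    def test_seed_separation_controls_splitting(self, sep_factor, expected):
        min_sep = 0.3
        gap_vox = int(round(sep_factor * min_sep / ISO_VOX[2]))
        c = (12, 20, 20)
        img = 10.0 + _gauss_blob((25, 41, 41), c, 1.5, 200.0) \
            + _gauss_blob((25, 41, 41), (c[0], c[1], c[2] + gap_vox), 1.5, 200.0)
        stack = ImageStack(img[np.newaxis], ISO_VOX, ("protein",))
        resp = log_response(stack, protein_channel=0, scales_um=(0.15,))
        labels = detect_puncta(resp, stack, None, protein_channel=0,
                               min_seed_separation_um=min_sep,
                               include_cytoplasm=True)
        assert labels.n_labels == expected

    def test_detection_invariant_to_positive_rescaling(self, clean_scene):
        params, stack, _ = clean_scene
        nuclei = segment_nuclei(stack)
        scaled = ImageStack(np.stack([stack.channel(0) * 13.0, stack.channel(1)]),
                            stack.voxel_size, stack.channel_names)
        l1 = detect_puncta(log_response(stack), stack, nuclei)
        l2 = detect_puncta(log_response(scaled), scaled, nuclei)
        assert np.array_equal(l1.labels, l2.labels)

    def test_stricter_threshold_never_increases_count(self, clean_scene):
        params, stack, _ = clean_scene
        nuclei = segment_nuclei(stack)
        resp = log_response(stack)
        counts = [detect_puncta(resp, stack, nuclei, threshold_policy="quantile",
                                threshold_value=q).n_labels
                  for q in (0.5, 0.8, 0.95, 0.999)]
        assert counts == sorted(counts, reverse=True)

    def test_count_error_at_snr_5(self):
        # SNR = (DP − LP)/noise sd = 5 with the default kp=10, lp=100
        noise_sd = (10 - 1) * 100 / 5
        errors = []
        for seed in (8, 21, 22):
            params = SceneParams(puncta_count=50, poisson_scale=0.0,
                                 gaussian_sd=noise_sd, seed=seed)
            stack, truth = generate_cell_stack(params)
            nuclei = segment_nuclei(stack)
            labels = detect_puncta(log_response(stack), stack, nuclei)
            n = len(measure_puncta(labels, stack, nuclei))
            errors.append(abs(n - truth.n_objects) / truth.n_objects)
        assert np.median(errors) <= 0.10


class TestMeasurement:
    def test_punctum_arithmetic(self):
        img = np.zeros((5, 10, 10))
        lab = np.zeros((5, 10, 10), np.int32)
        lab[2, 4:6, 3:8] = 1                      # 10 voxels
        img[lab == 1] = 50.0
        voxel = (0.2, 0.1, 0.1)                   # 0.002 μm³
        stack = ImageStack(img[np.newaxis], voxel, ("protein",))
        nuclei = LabelVolume(np.ones_like(lab), voxel, kind="nuclei")
        rec = measure_puncta(LabelVolume(lab, voxel, "puncta"), stack, nuclei,
                             protein_channel=0)[0]
        assert rec.volume == pytest.approx(0.02)
        assert rec.mean_intensity == pytest.approx(50.0)
        assert rec.integrated_intensity == pytest.approx(500.0)
        assert rec.integrated_intensity == pytest.approx(
            rec.mean_intensity * rec.voxel_count)

    def test_record_count_matches_labels(self, clean_analysis):
        _, stack, _, _, puncta, _ = clean_analysis
        assert len({p.punctum_id for p in puncta}) == len(puncta)

    def test_boundary_distance_matches_analytic_geometry(self):
        # punctum at the centre of a spherical nucleus: distance ≈ radius
        shape, voxel = (41, 41, 41), ISO_VOX
        grids = np.meshgrid(*[np.arange(s) - 20 for s in shape], indexing="ij")
        r_vox = np.sqrt(sum(g ** 2 for g in grids))
        nucleus = (r_vox <= 15).astype(np.int32)          # radius 1.5 μm
        lab = np.zeros(shape, np.int32)
        lab[19:22, 19:22, 19:22] = 1
        img = np.where(lab > 0, 500.0, 100.0) * nucleus
        stack = ImageStack(img[np.newaxis], voxel, ("protein",))
        rec = measure_puncta(LabelVolume(lab, voxel, "puncta"), stack,
                             LabelVolume(nucleus, voxel), protein_channel=0)[0]
        diag = np.linalg.norm(voxel)
        assert abs(rec.boundary_distance - 1.5) <= diag
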