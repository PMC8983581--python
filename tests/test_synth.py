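"""Generator tests: determinism, intensity conservation, model values."""

import numpy as np
import pytest

from punctaquant import SceneParams, generate_cell_stack, generate_dilution_series
from punctaquant.errors import ParameterError, PlacementError
from punctaquant.synth import (axial_span, frap_recovered_fraction,
                               generate_construct_sequence, generate_frap_trace,
                               plane_count)
from punctaquant.seqfeatures import count_fg, count_glfg


class TestCellStack:
    def test_empty_scene_is_uniform_nucleoplasm(self):
        p = SceneParams(puncta_count=0, poisson_scale=0.0, gaussian_sd=0.0,
                        psf_sigma=(0, 0, 0))
        stack, truth = generate_cell_stack(p)
        prot = stack.channel("protein")
        # deep interior voxels sit exactly at the light-phase level
        zc, yc, xc = (s // 2 for s in stack.shape)
        core = prot[zc - 2 : zc + 3, yc - 5 : yc + 6, xc - 5 : xc + 6]
        assert np.allclose(core, p.lp_intensity)
        assert truth.n_objects == 0

    def test_acquisition_geometry_axial_span(self):
        # 62 planes at 0.2 μm spacing cover 12.2 μm
        assert axial_span(62, 0.2) == pytest.approx(12.2)
        p = SceneParams(shape=(62, 40, 40), puncta_count=0)
        stack, _ = generate_cell_stack(p)
        assert stack.shape[0] == 62
        assert axial_span(stack.shape[0], stack.voxel_size[0]) == pytest.approx(12.2)

    def test_intensity_conservation_noise_off(self):
        p = SceneParams(puncta_count=50, punctum_radius_mean=0.3,
                        punctum_radius_sd=0.0, kp_true=10.0,
                        poisson_scale=0.0, gaussian_sd=0.0, seed=9)
        stack, truth = generate_cell_stack(p)
        vv = stack.voxel_volume
        total = stack.channel("protein").sum() * vv
        stack_volume = np.prod(stack.shape) * vv
        analytic = (
            p.cytoplasm_intensity * (stack_volume - truth.nucleus_volume_um3)
            + p.lp_intensity * truth.nucleus_volume_um3
            + (p.kp_true - 1) * p.lp_intensity * sum(truth.volumes_um3)
        )
        assert total == pytest.approx(analytic, rel=0.01)

    def test_punctum_core_intensity_and_kp_monotonicity(self):
        means = []
        for kp in (2.0, 5.0, 10.0):
            p = SceneParams(puncta_count=20, kp_true=kp, poisson_scale=0.0,
                            gaussian_sd=0.0, psf_sigma=(0, 0, 0), seed=4)
            stack, truth = generate_cell_stack(p)
            prot = stack.channel("protein")
            vs = np.asarray(p.voxel_size)
            cores = [prot[tuple(np.round(np.asarray(c) / vs).astype(int))]
                     for c in truth.centers_um]
            means.append(np.mean(cores))
            # unblurred core voxels are exactly kp × lp
            assert np.allclose(cores, kp * p.lp_intensity)
        assert means[0] < means[1] < means[2]

    def test_determinism_bit_identical(self):
        p = SceneParams(puncta_count=30, seed=12)
        s1, t1 = generate_cell_stack(p)
        s2, t2 = generate_cell_stack(p)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert t1.centers_um == t2.centers_um

    def test_ground_truth_volumes_are_analytic_spheres(self):
        p = SceneParams(puncta_count=10, poisson_scale=0.0, gaussian_sd=0.0, seed=2)
        _, truth = generate_cell_stack(p)
        assert truth.n_objects == 10
        expected = 4 / 3 * np.pi * np.asarray(truth.radii_um) ** 3
        assert np.allclose(truth.volumes_um3, expected)

    def test_overcrowded_scene_raises_placement_error(self):
        p = SceneParams(puncta_count=3000, punctum_radius_mean=0.4, seed=0)
        with pytest.raises(PlacementError):
            generate_cell_stack(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SceneParams(kp_true=0.5)
        with pytest.raises(ParameterError):
            SceneParams(dna_overlap=1.5)
        with pytest.raises(ParameterError):
            SceneParams(nucleus_semi_axes=(0, 1, 1))

    def test_cytoplasmic_puncta_lie_outside_nucleus(self):
        p = SceneParams(puncta_count=10, cytoplasm_puncta_count=5, seed=6,
                        poisson_scale=0.0, gaussian_sd=0.0)
        _, truth = generate_cell_stack(p)
        semi = np.asarray(p.nucleus_semi_axes)
        for c, inside in zip(truth.centers_um, truth.in_nucleus):
            norm = np.sqrt(np.sum(((np.asarray(c) - truth.nucleus_center_um) / semi) ** 2))
            assert (norm < 1.0) == inside


class TestFrapTraceGeneration:
    def test_full_recovery_limit(self):
        # m_f = 1: the noiseless recovered fraction tends to 1
        assert frap_recovered_fraction(1e6, t_half=10, m_f=1.0) == pytest.approx(1.0)

    def test_half_recovery_at_t_half(self):
        assert frap_recovered_fraction(10.0, t_half=10.0, m_f=0.8) == pytest.approx(0.4)

    def test_three_half_lives(self):
        # t_half=10 s, m_f=0.8 → value 0.8·(1−2⁻³) = 0.7 at t=30 s
        assert frap_recovered_fraction(30.0, 10.0, 0.8) == pytest.approx(0.7)

    def test_raw_trace_encodes_model(self):
        tr = generate_frap_trace(10.0, 0.8, noise_sd=0.0, n_points=61, seed=0,
                                 bleach_depth=0.5, t_max=30.0)
        norm = (tr.roi - tr.background) / (tr.reference - tr.background)
        # bleach floor at t=0, and 0.5 + 0.5·0.7 at three half-lives
        assert norm[0] == pytest.approx(0.5)
        assert norm[-1] == pytest.approx(0.5 + 0.5 * 0.7)

    def test_invalid_frap_params(self):
        with pytest.raises(ParameterError):
            generate_frap_trace(-1.0, 0.5)
        with pytest.raises(ParameterError):
            generate_frap_trace(10.0, 1.5)


class TestDilutionSeries:
    def test_below_csat_condensate_free(self):
        s = generate_dilution_series(50.0, [10, 20], seed=1)
        assert s.true_counts == [0, 0]

    def test_threshold_enumeration(self):
        # csat 200 against a 2× ladder: positives exactly at ≥ 200
        ladder = [10, 20, 40, 80, 160, 320, 640]
        s = generate_dilution_series(200.0, ladder, seed=1)
        assert [c >= 1 for c in s.true_counts] == [c >= 200 for c in ladder]

    def test_counts_grow_with_concentration(self):
        s = generate_dilution_series(50.0, [50, 100, 200, 400], seed=1)
        assert s.true_counts == sorted(s.true_counts)
        assert s.true_counts[0] >= 3

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ParameterError):
            generate_dilution_series(50.0, [20, 10], seed=0)
        with pytest.raises(ParameterError):
            generate_dilution_series(50.0, [], seed=0)


class TestConstructGeneration:
    def test_total_valence_38(self):
        # the wild-type two-region architecture: 17 + 21 FG motifs
        seq = generate_construct_sequence(17, 21, 3, 6, seed=0)
        assert count_fg(seq) == 38
        assert count_fg(seq, "nterm_fg") == 17
        assert count_fg(seq, "cterm_fg") == 21
        assert count_glfg(seq, "nterm_fg") == 3
        assert count_glfg(seq, "cterm_fg") == 6

    def test_zero_motifs(self):
        seq = generate_construct_sequence(0, 0, 0, 0, seed=1)
        assert count_fg(seq) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_regex_scan_matches(self, seed):
        import re
        seq = generate_construct_sequence(2, 3, 1, 1, seed=seed)
        assert len(re.findall("(?=FG)", seq.residues)) == 5
        assert len(re.findall("(?=GLFG)", seq.residues)) == 2

    def test_glfg_cannot_exceed_fg(self):
        with pytest.raises(ParameterError):
            generate_construct_sequence(2, 2, 3, 0)


def test_plane_count_matches_acquisition_scheme():
    # 6 μm span at 0.5 μm interval, endpoints included → 13 planes
    assert plane_count(6.0, 0.5) == 13
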