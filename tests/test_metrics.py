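"""Partition coefficient, transfer free energy, colocalization, periphery."""

import math

import numpy as np
import pytest

from punctaquant import ImageStack, SceneParams, generate_cell_stack
from punctaquant.errors import UndefinedMetricError
from punctaquant.metrics import (CalibrationModel, ThermoParams, cell_metrics,
                                 delta_g_transfer, partition_coefficient,
                                 pearson_colocalization, periphery_stats)
from punctaquant.nuclei import segment_nuclei
from punctaquant.pipeline import RunConfig, analyze_stack
from punctaquant.puncta import PunctumRecord


def _punctum(distance, volume=0.1):
    return PunctumRecord(punctum_id=1, nucleus_id=1, volume=volume,
                         mean_intensity=1.0, integrated_intensity=1.0,
                         centroid=(0, 0, 0), boundary_distance=distance)


class TestPartitionCoefficient:
    def test_equal_phases_give_unity(self):
        assert partition_coefficient(3.3, 3.3) == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert partition_coefficient(20.0, 2.0) == pytest.approx(10.0)

    def test_nonpositive_phase_undefined(self):
        with pytest.raises(UndefinedMetricError):
            partition_coefficient(5.0, 0.0)
        with pytest.raises(UndefinedMetricError):
            partition_coefficient(-1.0, 2.0)


class TestDeltaGTransfer:
    def test_zero_at_unity(self):
        assert delta_g_transfer(1.0) == 0.0

    def test_formula_at_body_temperature(self):
        thermo = ThermoParams()
        expected = -1.987e-3 * 310.15 * math.log(10.0)
        assert delta_g_transfer(10.0, thermo) == pytest.approx(expected)
        assert delta_g_transfer(10.0, thermo) < 0          # favorable

    def test_antisymmetry_under_phase_exchange(self):
        for k in (1.5, 2.0, 10.0, 42.0):
            assert delta_g_transfer(k) == pytest.approx(-delta_g_transfer(1 / k),
                                                        rel=1e-12)

    def test_strictly_decreasing_in_kp(self):
        ks = [1.0, 2.0, 5.0, 20.0, 50.0]
        gs = [delta_g_transfer(k) for k in ks]
        assert all(a > b for a, b in zip(gs, gs[1:]))


class TestKpRecovery:
    @pytest.mark.parametrize("kp_true", [2.0, 5.0, 10.0, 20.0])
    def test_pipeline_recovers_kp_within_10_percent(self, kp_true):
        errors = []
        for seed in (3, 7):
            params = SceneParams(puncta_count=50, kp_true=kp_true,
                                 poisson_scale=0.0, gaussian_sd=0.0, seed=seed)
            stack, _ = generate_cell_stack(params)
            _, _, cells = analyze_stack(stack,
                                        RunConfig(psf_sigma_um=params.psf_sigma))
            errors.append(abs(cells[0].k_p - kp_true) / kp_true)
        assert np.median(errors) <= 0.10

    def test_calibrated_concentrations(self):
        # slope 0.01 μmol/L per a.u. maps lp 100 → 1.0 and dp 500 → 5.0
        params = SceneParams(puncta_count=50, kp_true=5.0, poisson_scale=0.0,
                             gaussian_sd=0.0, seed=3)
        stack, _ = generate_cell_stack(params)
        _, _, cells = analyze_stack(stack, RunConfig(
            psf_sigma_um=params.psf_sigma, calibration_slope=0.01))
        cm = cells[0]
        assert cm.lp == pytest.approx(1.0, rel=0.10)
        assert cm.dp == pytest.approx(5.0, rel=0.10)

    def test_total_concentration_between_phases(self, clean_analysis):
        *_, cells = clean_analysis
        cm = cells[0]
        assert cm.lp <= cm.total_concentration <= cm.dp


class TestZeroPunctumConvention:
    def test_zero_puncta_metrics_undefined_not_zero(self):
        params = SceneParams(puncta_count=0, poisson_scale=0.0, gaussian_sd=0.0,
                             seed=3)
        stack, _ = generate_cell_stack(params)
        _, _, cells = analyze_stack(stack, RunConfig())
        cm = cells[0]
        assert cm.puncta_density == 0.0
        assert cm.total_concentration > 0
        assert cm.v_p is None and cm.dp is None
        assert cm.k_p is None and cm.delta_g_tr is None


class TestColocalization:
    def _mask_stack(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(10, 200, (6, 20, 20))
        return a

    def test_identical_channels_pcc_one(self):
        a = self._mask_stack()
        stack = ImageStack(np.stack([a, a]), (0.2, 0.1, 0.1))
        mask = np.ones(a.shape, bool)
        assert pearson_colocalization(stack, mask) == pytest.approx(1.0)

    def test_inverted_channel_pcc_minus_one(self):
        a = self._mask_stack()
        stack = ImageStack(np.stack([a, a.max() - a]), (0.2, 0.1, 0.1))
        mask = np.ones(a.shape, bool)
        assert pearson_colocalization(stack, mask) == pytest.approx(-1.0)

    def test_constant_channel_undefined(self):
        a = self._mask_stack()
        stack = ImageStack(np.stack([a, np.full_like(a, 7.0)]), (0.2, 0.1, 0.1))
        with pytest.raises(UndefinedMetricError):
            pearson_colocalization(stack, np.ones(a.shape, bool))

    def test_affine_rescaling_invariance(self):
        a = self._mask_stack()
        rng = np.random.default_rng(2)
        b = a + rng.normal(0, 20, a.shape)
        mask = np.ones(a.shape, bool)
        s1 = ImageStack(np.stack([a, b]), (0.2, 0.1, 0.1))
        s2 = ImageStack(np.stack([3.0 * a + 11.0, 0.5 * b + 2.0]), (0.2, 0.1, 0.1))
        assert pearson_colocalization(s1, mask) == pytest.approx(
            pearson_colocalization(s2, mask), rel=1e-9)

    def test_dna_overlap_raises_pcc(self):
        wins = 0
        for seed in range(10):
            scores = {}
            for overlap in (0.1, 0.9):
                params = SceneParams(puncta_count=60, dna_overlap=overlap,
                                     seed=200 + seed)
                stack, _ = generate_cell_stack(params)
                mask = segment_nuclei(stack).mask()
                scores[overlap] = pearson_colocalization(stack, mask)
            wins += scores[0.9] > scores[0.1]
        assert wins >= 9


class TestPeripheryStats:
    def test_zero_cutoff_zero_fraction(self):
        frac, interior = periphery_stats([_punctum(0.2), _punctum(1.0)], 0.0)
        assert frac == 0.0 and len(interior) == 2

    def test_shell_placement_all_peripheral(self):
        puncta = [_punctum(d) for d in (0.1, 0.2, 0.3)]
        frac, interior = periphery_stats(puncta, 0.5)
        assert frac == 1.0 and interior == []

    def test_default_cutoff_is_half_micron(self):
        import inspect
        sig = inspect.signature(periphery_stats)
        assert sig.parameters["cutoff_um"].default == 0.5

    def test_empty_list_undefined(self):
        frac, interior = periphery_stats([], 0.5)
        assert frac is None and interior == []


def test_calibration_model_validation():
    with pytest.raises(ValueError):
        CalibrationModel(slope=-1.0)
    model = CalibrationModel(slope=2.0, offset=1.0)
    assert model(10.0) == pytest.approx(21.0)
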