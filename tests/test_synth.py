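"""Simulator correctness: closed-form signal values, protocol defaults,
determinism, and truth-table conservation of the slide generator."""

import numpy as np
import pytest

from mpmr import synth
from mpmr.synth import ConfigurationError


class TestGroundTruth:
    def test_uniform_config_gives_constant_map(self):
        gt = synth.generate_ground_truth((32, 32), seed=1,
                                         heterogeneity_config={"D": (1.0, 1.0)})
        assert np.all(gt.D_map == 1.0)

    def test_full_f_range_stays_in_unit_interval(self):
        gt = synth.generate_ground_truth((32, 32), seed=2,
                                         heterogeneity_config={"f": (0.0, 1.0)})
        assert gt.f_map.min() >= 0.0 and gt.f_map.max() <= 1.0

    def test_seed_determinism_bit_identical(self):
        a = synth.generate_ground_truth((16, 16), seed=7)
        b = synth.generate_ground_truth((16, 16), seed=7)
        for name in ("D_map", "f_map", "Dstar_map", "T1_map", "T2star_map", "S0_map"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_out_of_range_config_rejected(self):
        with pytest.raises(ConfigurationError):
            synth.generate_ground_truth((16, 16), seed=0,
                                        heterogeneity_config={"D": (0.5, 9.0)})
        with pytest.raises(ConfigurationError):
            synth.generate_ground_truth((4, 4), seed=0)


class TestDwi:
    @pytest.mark.parametrize("f,Dstar,expected", [
        (0.0, 50.0, 1000 * np.exp(-0.8)),   # monoexponential limit, 449.33
        (0.1, 50.0, 404.396),               # biexponential closed form
    ])
    def test_signal_equation(self, f, Dstar, expected):
        s = synth.ivim_signal(800.0, 1000.0, 1.0, f, Dstar)
        assert s == pytest.approx(expected, rel=1e-4)

    def test_default_protocol_12_b_values(self, gt_small):
        series = synth.simulate_dwi(gt_small, snr=np.inf)
        assert len(series.acq_values) == 12
        assert series.acq_values[0] == 0 and series.acq_values[-1] == 800

    def test_negative_b_rejected(self, gt_small):
        with pytest.raises(ValueError):
            synth.simulate_dwi(gt_small, b_values=[-5, 0, 800])

    def test_noiseless_matches_model_and_noise_is_seeded(self, gt_small):
        clean = synth.simulate_dwi(gt_small, snr=np.inf)
        expected = synth.ivim_signal(
            clean.acq_values[:, None, None], gt_small.S0_map[None],
            gt_small.D_map[None], gt_small.f_map[None], gt_small.Dstar_map[None])
        assert np.allclose(clean.frames, expected)
        n1 = synth.simulate_dwi(gt_small, snr=50, seed=3)
        n2 = synth.simulate_dwi(gt_small, snr=50, seed=3)
        assert np.array_equal(n1.frames, n2.frames)
        assert not np.array_equal(n1.frames, clean.frames)


class TestRelaxometry:
    def test_t2star_closed_form(self):
        assert synth.t2star_signal(25.0, 0.0, 100.0, 25.0) == pytest.approx(
            100 * np.exp(-1), rel=1e-9)

    def test_t1_saturation_limit(self):
        s = synth.t1_signal(13000.0, 0.0, 100.0, 1500.0)
        assert abs(s - 100.0) / 100.0 < 2e-4

    def test_default_te_grid_10_echoes(self, gt_small):
        series = synth.simulate_relaxometry(gt_small, "T2star", snr=np.inf)
        assert len(series.acq_values) == 10
        assert series.acq_values[0] == 5 and series.acq_values[-1] == 50

    def test_default_tr_grid(self, gt_small):
        series = synth.simulate_relaxometry(gt_small, "T1", snr=np.inf)
        assert list(series.acq_values) == [13000, 9000, 4500, 2500, 1500, 750, 300]

    def test_nonpositive_acq_values_rejected(self, gt_small):
        with pytest.raises(ValueError):
            synth.simulate_relaxometry(gt_small, "T2star", acq_values=[0, 5, 10, 20])


class TestDce:
    def test_default_protocol(self, gt_small):
        series = synth.simulate_dce(gt_small, snr=np.inf)
        assert len(series.acq_values) == 100
        assert np.allclose(np.diff(series.acq_values), 4.2)
        assert series.injection_index == 6

    def test_zero_amplitude_flat_curve(self, gt_small):
        gt = synth.generate_ground_truth(
            (16, 16), seed=3, heterogeneity_config={"dce_amplitude": (0.0, 0.0)})
        series = synth.simulate_dce(gt, snr=np.inf)
        assert np.allclose(series.frames, series.frames[0], rtol=1e-12)

    def test_peak_value_analytic(self):
        # curve maximum is exactly baseline*(1+amplitude) at onset+rise
        t = np.linspace(0, 400, 4000)
        y = synth.dce_curve(t, 1000.0, 0.8, 10.0, 40.0, 2e-3, 21.0)
        assert y.max() == pytest.approx(1800.0, rel=1e-5)

    def test_short_series_warns(self, gt_small):
        with pytest.warns(UserWarning):
            synth.simulate_dce(gt_small, n_dynamics=8, injection_index=6, snr=np.inf)


class TestSlides:
    def test_truth_conservation_and_determinism(self, he_slide):
        a = he_slide
        b = synth.generate_slide("HE", (1000, 1000), 2.0, seed=5)
        assert np.array_equal(a.image, b.image)
        assert int(a.truth["value"].sum()) == len(a.cell_centroids)
        assert (a.truth["value"] >= 0).all()

    def test_mt_fraction_truth_bounded_and_realized(self):
        slide = synth.generate_slide(
            "MT", (500, 500), 2.0, seed=6,
            density_config={"fraction_range": (0.25, 0.25)})
        assert np.allclose(slide.truth["value"], 0.25, atol=0.01)

    def test_unresolvable_cell_radius_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_slide("HE", (500, 500), 4.0, seed=0,
                                 density_config={"radius_um": (3.0, 5.0)})

    def test_ink_marks_on_three_borders(self, he_slide):
        assert set(he_slide.ink_marks["label"]) == {"left", "right", "dorsal"}


class TestLandmarks:
    def test_identity_zero_jitter(self):
        tf = synth.similarity_matrix()
        src, dst = synth.make_landmark_pairs(tf, 4, 0.0, seed=1)
        assert np.allclose(src, dst)

    def test_too_few_points_rejected(self):
        tf = synth.similarity_matrix(10.0, 1.2)
        tf.family = "affine"
        with pytest.raises(ValueError):
            synth.make_landmark_pairs(tf, 2, 0.0, seed=1)

    def test_jitter_is_seeded(self):
        tf = synth.similarity_matrix(5.0)
        _, d1 = synth.make_landmark_pairs(tf, 5, 2.0, seed=9)
        _, d2 = synth.make_landmark_pairs(tf, 5, 2.0, seed=9)
        assert np.array_equal(d1, d2)
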