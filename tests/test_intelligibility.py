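"""Binaural intelligibility model: BMLD, band analysis, benefit maps."""

import numpy as np
import pytest

from headturn.intelligibility import (
    BenefitMap,
    ModelConstants,
    band_parameters,
    benefit_map,
    bmld,
    effective_tir,
    optimal_region,
    trajectory_benefit,
)
from headturn.room import HeadModel, ImpulseResponsePair, enumerate_images, render_brir
from headturn.trajectory import Trajectory, WordWindows
from conftest import make_scene


def _pair(left, right, fs=44100.0):
    return ImpulseResponsePair(np.asarray(left, float), np.asarray(right, float), fs)


class TestBmld:
    def test_homophasic_is_zero(self):
        assert bmld(0.7, 0.7, 1.0, 500.0) == 0.0

    def test_antiphasic_500hz_value(self):
        c = ModelConstants()
        k = (1 + c.sigma_eps**2) * np.exp((2 * np.pi * 500 * c.sigma_delta) ** 2)
        assert k == pytest.approx(1.1847, abs=1e-3)
        expected = 10 * np.log10((k + 1) / (k - 1))
        assert bmld(np.pi, 0.0, 1.0, 500.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(10.73, abs=0.05)

    def test_zero_coherence_equal_phase_clamped(self):
        assert bmld(0.4, 0.4, 0.0, 500.0) == 0.0

    def test_nonnegative_and_continuous(self, rng):
        c = ModelConstants()
        base = bmld(1.0, 0.2, 0.8, 700.0, c)
        for _ in range(200):
            pt, pi = rng.uniform(-np.pi, np.pi, 2)
            coh = rng.uniform(0, 1)
            fc = rng.uniform(100, 8000)
            assert bmld(pt, pi, coh, fc, c) >= 0.0
        eps = 1e-6
        for d_args in ((eps, 0, 0, 0), (0, eps, 0, 0), (0, 0, eps, 0), (0, 0, 0, eps)):
            v = bmld(1.0 + d_args[0], 0.2 + d_args[1], 0.8 + d_args[2], 700.0 + d_args[3], c)
            assert abs(v - base) < 1e-3

    def test_invalid_coherence_rejected(self):
        with pytest.raises(ValueError):
            bmld(0.0, 0.0, 1.5, 500.0)


class TestBandParameters:
    def test_diotic_input_full_coherence_zero_phase(self, rng):
        x = rng.standard_normal(4000)
        bd = band_parameters(_pair(x, x), _pair(x, x))
        assert np.all(bd.coherence_interferer[bd.valid] > 0.999)
        np.testing.assert_allclose(bd.phase_target[bd.valid], 0.0, atol=1e-6)
        np.testing.assert_allclose(
            bd.target_energy[0, bd.valid], bd.target_energy[1, bd.valid]
        )

    def test_uncorrelated_noise_low_coherence(self, rng):
        cohs = []
        for _ in range(50):
            l, r = rng.standard_normal((2, 20000))  # ~0.45 s of noise
            bd = band_parameters(_pair(l, l), _pair(l, r))
            cohs.append(bd.coherence_interferer[bd.valid].mean())
        assert np.mean(cohs) < 0.2

    def test_pure_delay_gives_expected_phase(self):
        fs = 40000.0
        c = ModelConstants(band_centers=np.array([500.0]), band_weights=np.array([1.0]))
        x = np.zeros(2000)
        y = np.zeros(2000)
        x[100] = 1.0
        y[100 + 20] = 1.0  # 500 us delay at 40 kHz
        bd = band_parameters(_pair(x, x, fs), _pair(x, y, fs), c)
        expected = 2 * np.pi * 500.0 * 500e-6  # pi/2
        assert abs(abs(bd.phase_interferer[0]) - expected) < 0.05


class TestEffectiveTir:
    def test_colocated_identity_zero(self, rng):
        x = rng.standard_normal(3000)
        y = 0.8 * x + 0.1 * rng.standard_normal(3000)
        bd = band_parameters(_pair(x, y), _pair(x, y))
        assert effective_tir(bd) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_target_pressure_adds_6db(self, rng):
        l, r = rng.standard_normal((2, 3000))
        il, ir = rng.standard_normal((2, 3000))
        t1 = effective_tir(band_parameters(_pair(l, r), _pair(il, ir)))
        t2 = effective_tir(band_parameters(_pair(2 * l, 2 * r), _pair(il, ir)))
        assert t2 - t1 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_joint_rescaling_invariance(self, rng):
        l, r = rng.standard_normal((2, 3000))
        il, ir = rng.standard_normal((2, 3000))
        t1 = effective_tir(band_parameters(_pair(l, r), _pair(il, ir)))
        t2 = effective_tir(band_parameters(_pair(3 * l, 3 * r), _pair(3 * il, 3 * ir)))
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_anechoic_lateral_vs_band_oracle(self, anechoic_scene):
        """Single-image BRIRs admit a closed-form band computation: energies
        are squared ear gains (gammatone filter energy cancels in the ratio),
        phases follow from Woodworth delay differences."""
        c = ModelConstants()
        head = HeadModel()
        imgs_t = enumerate_images(anechoic_scene, 1, 0.1)
        imgs_i = enumerate_images(anechoic_scene, 0, 0.1)
        bt = render_brir(imgs_t, head, anechoic_scene.listener_position)
        bi = render_brir(imgs_i, head, anechoic_scene.listener_position)
        model = effective_tir(band_parameters(bt, bi, c), c)

        lst = np.array(anechoic_scene.listener_position)
        expected = 0.0
        for fc, w in zip(c.band_centers, c.band_weights):
            gains = {}
            delays = {}
            for name, idx in (("t", 1), ("i", 0)):
                u = anechoic_scene.source_position(idx) - lst
                u = u / np.linalg.norm(u)
                ct = [u @ head.ear_vector(0.0, s) for s in ("left", "right")]
                g = [head.shadow_gain(np.array([x]), fc)[0] for x in ct]
                d = [head.ear_delay(np.array([x]))[0] for x in ct]
                gains[name] = g
                delays[name] = d
            be = max(
                20 * np.log10(gains["t"][0] / gains["i"][0]),
                20 * np.log10(gains["t"][1] / gains["i"][1]),
            )
            ph_t = 2 * np.pi * fc * (delays["t"][0] - delays["t"][1])
            ph_i = 2 * np.pi * fc * (delays["i"][0] - delays["i"][1])
            expected += w * (be + bmld(ph_t, ph_i, 1.0, fc, c))
        assert model == pytest.approx(expected, abs=0.5)


class TestBenefitMap:
    @pytest.fixture(scope="class")
    def lateral_map(self):
        scene = make_scene((11.0, 13.0, 3.0), (4.0, 7.0, 1.8),
                           [(0.0, 2.1, 70.0), (90.0, 2.1, 60.0)])
        return benefit_map(scene, 1, 0, grid_step_deg=5.0)

    def test_reference_yaw_exactly_zero(self, lateral_map):
        assert lateral_map.benefit_db[0] == 0.0

    def test_unmasking_minus_reference_is_benefit(self, lateral_map):
        np.testing.assert_allclose(
            lateral_map.benefit_db,
            lateral_map.unmasking_db - lateral_map.unmasking_db[0],
        )

    def test_anechoic_mirror_symmetry_exact(self):
        maps = {}
        for az in (90.0, -90.0):
            scene = make_scene((11.0, 13.0, 3.0), (4.0, 7.0, 1.8),
                               [(0.0, 2.1, 70.0), (az, 2.1, 60.0)])
            maps[az] = benefit_map(scene, 1, 0, grid_step_deg=15.0)
        m_pos = maps[90.0].benefit_db
        m_neg = maps[-90.0].benefit_db
        mirrored = np.concatenate([[m_neg[0]], m_neg[1:][::-1]])
        np.testing.assert_allclose(m_pos, mirrored, atol=1e-9)

    def test_colocated_anechoic_flat(self):
        scene = make_scene((11.0, 13.0, 3.0), (4.0, 7.0, 1.8),
                           [(0.0, 2.1, 70.0), (0.0, 2.1, 60.0)])
        with pytest.warns(UserWarning, match="co-located"):
            m = benefit_map(scene, 1, 0, grid_step_deg=30.0)
        assert np.max(np.abs(m.benefit_db)) < 0.1

    def test_reverberation_does_not_raise_peak(self):
        """More reverberant scenes show less head-orientation unmasking."""
        peaks = {}
        for alpha in (1.0, 0.3):
            scene = make_scene((11.0, 13.0, 3.0), (4.0, 7.0, 1.8),
                               [(0.0, 2.1, 70.0), (90.0, 2.1, 60.0)], alpha=alpha)
            m = benefit_map(scene, 1, 0, grid_step_deg=30.0, time_limit_s=0.15)
            peaks[alpha] = m.peak_unmasking_db
        assert peaks[0.3] <= peaks[1.0] + 0.2

    def test_same_source_index_rejected(self, anechoic_scene):
        with pytest.raises(ValueError):
            benefit_map(anechoic_scene, 0, 0)


class TestOptimalRegion:
    def test_constant_map_full_circle(self):
        m = BenefitMap(np.arange(0, 360, 72.0), np.zeros(5))
        assert optimal_region(m, 1.0).yaw_deg.size == 5

    def test_zero_margin_argmax_only(self):
        m = BenefitMap(np.arange(0, 360, 72.0), np.array([0.0, 1.0, 3.0, 2.0, 0.5]))
        r = optimal_region(m, 0.0)
        np.testing.assert_array_equal(r.yaw_deg, [144.0])

    def test_toy_map_one_db_margin(self):
        m = BenefitMap(np.arange(0, 360, 72.0), np.array([0.0, 2.0, 5.0, 4.2, 1.0]))
        r = optimal_region(m, 1.0)
        np.testing.assert_array_equal(r.yaw_deg, [144.0, 216.0])


class TestTrajectoryBenefit:
    @pytest.fixture
    def toy_map(self):
        yaws = np.arange(0.0, 360.0, 1.0)
        return BenefitMap(yaws, np.sin(np.deg2rad(yaws)) * 3.0)

    def _traj(self, yaw):
        t = np.arange(yaw.size) / 100.0
        return Trajectory(t, yaw)

    def _windows(self):
        return WordWindows(words=[(i * 0.4, (i + 1) * 0.4) for i in range(5)])

    def test_constant_trajectory(self, toy_map):
        traj = self._traj(np.full(220, 42.0))
        vals = trajectory_benefit(toy_map, traj, self._windows())
        np.testing.assert_allclose(vals, toy_map.benefit_at(42.0))

    def test_step_at_word_boundary(self, toy_map):
        yaw = np.where(np.arange(220) < 120, 10.0, 70.0)  # step at t=1.2 s
        vals = trajectory_benefit(toy_map, self._traj(yaw), self._windows())
        np.testing.assert_allclose(vals[:3], toy_map.benefit_at(10.0))
        np.testing.assert_allclose(vals[3:], toy_map.benefit_at(70.0))

    def test_ramp_monotone_words(self, toy_map):
        yaw = np.linspace(0.0, 80.0, 220)  # monotone region of the sine map
        vals = trajectory_benefit(toy_map, self._traj(yaw), self._windows())
        assert np.all(np.diff(vals) > 0)

    def test_empty_window_rejected(self, toy_map):
        traj = self._traj(np.full(50, 0.0))  # spans 0.5 s only
        with pytest.raises(ValueError):
            trajectory_benefit(toy_map, traj, self._windows())
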