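"""Image-source enumeration, binaural rendering, and reverberation estimation."""

import numpy as np
import pytest

from headturn.room import (
    DecayRangeError,
    HeadModel,
    RoomScene,
    SourcePlacement,
    enumerate_images,
    eyring_alpha,
    eyring_t30,
    render_brir,
    render_monaural,
    schroeder_t30,
)
from conftest import OCTAVES, make_scene


def brute_force_images(dims, source, max_order):
    """Independent oracle: breadth-first mirroring across the six wall planes.

    Returns {rounded position: reflection count} with the minimal count kept.
    """
    def mirrors(p):
        out = []
        for ax in range(3):
            for plane in (0.0, dims[ax]):
                q = list(p)
                q[ax] = 2 * plane - q[ax]
                out.append(tuple(q))
        return out

    found = {tuple(np.round(source, 9)): 0}
    frontier = [tuple(source)]
    for order in range(1, max_order + 1):
        nxt = []
        for p in frontier:
            for q in mirrors(p):
                key = tuple(np.round(q, 9))
                if key not in found:
                    found[key] = order
                    nxt.append(q)
        frontier = nxt
    return found


class TestEnumerateImages:
    def test_anechoic_returns_only_direct_path(self, anechoic_scene):
        imgs = enumerate_images(anechoic_scene, 0, 0.5)
        assert len(imgs) == 1
        np.testing.assert_allclose(imgs.positions[0], anechoic_scene.source_position(0))
        assert imgs.reflection_counts[0] == 0
        assert imgs.attenuation(1000.0)[0] == 1.0

    def test_first_order_seven_images(self):
        scene = make_scene((2.0, 2.0, 2.0), (1.0, 0.9, 1.0),
                           [(0.0, 0.1, 60.0)], alpha=0.5)
        src = scene.source_position(0)  # room center
        # first-order images lie within ~2.1 m of the listener; the nearest
        # second-order (face-diagonal) image is ~2.7 m away
        t_limit = 2.45 / 343.0
        imgs = enumerate_images(scene, 0, t_limit)
        oracle = brute_force_images(scene.dims, src, 1)
        oracle = {
            k: v
            for k, v in oracle.items()
            if np.linalg.norm(np.array(k) - scene.listener_position) <= 343.0 * t_limit
        }
        assert len(imgs) == len(oracle) == 7
        for pos, refl in zip(imgs.positions, imgs.reflection_counts):
            key = tuple(np.round(pos, 9))
            assert key in oracle
            assert oracle[key] == refl

    def test_matches_bruteforce_to_third_order(self):
        scene = make_scene((3.0, 4.0, 2.5), (1.2, 2.0, 1.1),
                           [(35.0, 0.8, 60.0)], alpha=0.3)
        src = scene.source_position(0)
        oracle = brute_force_images(scene.dims, src, 3)
        # keep oracle images whose distance is inside a radius below the
        # closest 4th-order image so enumeration and oracle cover the same set
        lst = np.array(scene.listener_position)
        all4 = brute_force_images(scene.dims, src, 4)
        d4 = min(np.linalg.norm(np.array(k) - lst)
                 for k, v in all4.items() if v == 4)
        radius = min(d4 * 0.999, 343.0)
        imgs = enumerate_images(scene, 0, radius / 343.0)
        oracle = {k: v for k, v in oracle.items()
                  if np.linalg.norm(np.array(k) - lst) <= radius}
        assert len(imgs) == len(oracle)
        for pos, refl in zip(imgs.positions, imgs.reflection_counts):
            key = tuple(np.round(pos, 9))
            assert key in oracle
            assert oracle[key] == refl
        r = np.sqrt(1.0 - 0.3)
        np.testing.assert_allclose(
            imgs.attenuation(1000.0), r ** imgs.reflection_counts.astype(float),
            rtol=1e-12)

    def test_volumetric_density(self):
        scene = make_scene((11.0, 13.0, 3.0), (4.0, 7.0, 1.8),
                           [(0.0, 2.1, 70.0)], alpha=0.2)
        imgs = enumerate_images(scene, 0, 1.4)
        ct = 343.0 * 1.4
        predicted = 4.0 / 3.0 * np.pi * ct**3 / scene.volume
        assert abs(len(imgs) - predicted) / predicted < 0.02

    def test_source_outside_room_rejected(self):
        with pytest.raises(ValueError):
            make_scene((2.0, 2.0, 2.0), (1.0, 1.0, 1.0), [(0.0, 5.0, 60.0)])


class TestRenderBrir:
    def test_midline_source_symmetric_ears(self, anechoic_scene):
        imgs = enumerate_images(anechoic_scene, 0, 0.1)  # interferer straight ahead
        brir = render_brir(imgs, HeadModel(), anechoic_scene.listener_position)
        np.testing.assert_allclose(brir.left, brir.right, atol=1e-12)

    def test_direct_path_delay_and_inverse_distance(self):
        head = HeadModel()
        peaks = {}
        for d in (1.0, 2.0, 4.0):
            scene = make_scene((11.0, 13.0, 3.0), (5.0, 6.0, 1.5), [(0.0, d, 60.0)])
            imgs = enumerate_images(scene, 0, 0.1)
            brir = render_brir(imgs, head, scene.listener_position)
            peaks[d] = np.max(np.abs(brir.left))
            if d == 2.0:
                i_peak = int(np.argmax(np.abs(brir.left)))
                delay = i_peak / brir.sample_rate
                assert abs(delay - d / 343.0) < 5e-4  # ear offset < 0.3 ms
        assert peaks[1.0] / peaks[2.0] == pytest.approx(2.0, rel=0.05)
        assert peaks[2.0] / peaks[4.0] == pytest.approx(2.0, rel=0.05)

    def test_ipsilateral_ear_louder(self, anechoic_scene):
        imgs = enumerate_images(anechoic_scene, 1, 0.1)  # target at +90 (right)
        brir = render_brir(imgs, HeadModel(), anechoic_scene.listener_position)
        assert np.sum(brir.right**2) > np.sum(brir.left**2)

    def test_mirror_scene_swaps_channels_exactly(self):
        head = HeadModel()
        for az in (40.0, 120.0):
            s1 = make_scene((10.0, 10.0, 3.0), (5.0, 5.0, 1.5), [(az, 2.0, 60.0)])
            s2 = make_scene((10.0, 10.0, 3.0), (5.0, 5.0, 1.5), [(-az, 2.0, 60.0)])
            b1 = render_brir(enumerate_images(s1, 0, 0.05), head, s1.listener_position)
            b2 = render_brir(enumerate_images(s2, 0, 0.05), head, s2.listener_position)
            np.testing.assert_array_equal(b1.left, b2.right)
            np.testing.assert_array_equal(b1.right, b2.left)

    def test_empty_image_set_rejected(self, anechoic_scene):
        imgs = enumerate_images(anechoic_scene, 0, 0.1)
        imgs.positions = imgs.positions[:0]
        imgs.reflection_counts = imgs.reflection_counts[:0]
        with pytest.raises(ValueError):
            render_brir(imgs, HeadModel(), anechoic_scene.listener_position)


class TestHeadModel:
    def test_shadow_limits(self):
        for shadow in ("sphere", "onepole"):
            head = HeadModel(shadow=shadow)
            ipsi = head.shadow_gain(np.array([1.0]), 8000.0)[0]
            assert 1.5 < ipsi < 2.1  # approaches +6 dB
            low = head.shadow_gain(np.array([-0.5, 0.2, 1.0]), 20.0)
            np.testing.assert_allclose(low, 1.0, atol=0.1)

    def test_woodworth_itd_magnitude(self):
        head = HeadModel()
        # source at 90 deg: ITD = a (theta + sin theta) / c with theta = 90 deg
        d_left = head.ear_delay(np.array([np.cos(np.deg2rad(170.0))]))[0]
        d_right = head.ear_delay(np.array([np.cos(np.deg2rad(10.0))]))[0]
        itd = d_left - d_right
        a = head.radius_m
        # both-ear Woodworth for ears at +/-100 deg and source at +90
        expected = (a / 343.0) * (np.deg2rad(170.0) - np.pi / 2) + (a / 343.0) * np.cos(
            np.deg2rad(10.0)
        )
        assert itd == pytest.approx(expected, rel=1e-9)
        assert 0.5e-3 < itd < 0.9e-3


class TestSchroederT30:
    def test_synthetic_exponential_decay(self, rng):
        fs = 44100.0
        tau = 0.2
        t = np.arange(int(fs * 1.6)) / fs
        ir = np.exp(-t / tau) * rng.standard_normal(t.size)
        # pressure envelope e^{-t/tau}: the 60 dB energy decay takes
        # 3 ln(10) tau = 6.9078 tau (= 1.38 s for tau = 0.2 s)
        assert schroeder_t30(ir, fs) == pytest.approx(6.907755 * tau, rel=0.03)

    def test_insufficient_decay_raises(self):
        fs = 16000.0
        ir = np.ones(1000)
        with pytest.raises(DecayRangeError):
            schroeder_t30(ir, fs)

    def test_time_reversal_preserves_total_energy(self, rng):
        fs = 16000.0
        ir = np.exp(-np.arange(8000) / 2000.0) * rng.standard_normal(8000)
        fwd = np.cumsum(ir[::-1] ** 2)[::-1]
        rev = np.cumsum(ir ** 2)[::-1]
        assert fwd[0] == pytest.approx(rev[0], rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.2, 0.4])
    def test_hybrid_render_matches_eyring(self, alpha):
        """With surface scattering the simulated band decay follows Eyring."""
        dims = (6.0, 5.0, 4.0)
        scene = RoomScene(dims, {1000.0: alpha}, (2.5, 2.0, 1.6),
                          [SourcePlacement(30.0, 1.2, 60.0)], scattering=0.15)
        t_eyr = eyring_t30(dims, alpha)
        imgs = enumerate_images(scene, 0, 1.5 * t_eyr)
        rir, fs = render_monaural(imgs, scene.listener_position, 16000.0)
        assert schroeder_t30(rir, fs, 1000.0) == pytest.approx(t_eyr, rel=0.10)


class TestEyring:
    def test_inverse_roundtrip(self):
        dims = (11.0, 13.0, 3.0)
        for t30 in (0.5, 1.15, 3.0):
            alpha = eyring_alpha(dims, t30)
            assert eyring_t30(dims, alpha) == pytest.approx(t30, rel=1e-12)

    def test_long_t30_limit_alpha_to_zero(self):
        assert eyring_alpha((11.0, 13.0, 3.0), 1e6) < 1e-5

    def test_rootfinding_oracle_paper_room(self):
        from scipy.optimize import brentq

        dims = (11.0, 13.0, 3.0)
        a_closed = eyring_alpha(dims, 1.15)
        a_root = brentq(lambda a: eyring_t30(dims, a) - 1.15, 1e-6, 0.999)
        assert a_closed == pytest.approx(a_root, rel=1e-9)

    def test_too_short_t30_rejected(self):
        with pytest.raises(ValueError):
            eyring_alpha((2.0, 2.0, 2.0), 1e-6)


class TestFileInterfaces:
    def test_brir_wav_roundtrip(self, anechoic_scene, tmp_path):
        from headturn.io import load_brir, save_brir

        imgs = enumerate_images(anechoic_scene, 0, 0.05)
        brir = render_brir(imgs, HeadModel(), anechoic_scene.listener_position)
        save_brir(tmp_path / "brir.wav", brir)
        back = load_brir(tmp_path / "brir.wav")
        assert back.sample_rate == brir.sample_rate
        np.testing.assert_allclose(back.left, brir.left, atol=1e-6)

    def test_scene_yaml_roundtrip(self, anechoic_scene, tmp_path):
        from headturn.io import load_scene, save_scene

        save_scene(tmp_path / "scene.yaml", anechoic_scene)
        back = load_scene(tmp_path / "scene.yaml")
        assert back.dims == anechoic_scene.dims
        assert back.band_absorption == anechoic_scene.band_absorption
        assert back.sources == anechoic_scene.sources
        assert back.scattering == anechoic_scene.scattering
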