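"""Scene simulator: ITD geometry, rendering, determinism, error handling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.io import wavfile
from scipy.signal import correlate, correlation_lags

from earshot import SceneRenderer, SceneSpec, SourceSpec, itd_for_source, render_frame
from earshot.scene import SceneError

FS = 48000.0


class TestItdForSource:
    @pytest.mark.parametrize(
        "azimuth,head,expected_s",
        [
            (0.0, 0.0, 0.0),                    # midline source
            (40.0, 40.0, 0.0),                  # head pointing at source
            (90.0, 0.0, 0.145 / 343.0),         # endfire: full d/c
            (-90.0, 0.0, -0.145 / 343.0),
            (30.0, 0.0, 0.145 / 343.0 * 0.5),   # sin 30 = 1/2
        ],
    )
    def test_known_delays(self, geometry, azimuth, head, expected_s):
        assert itd_for_source(geometry, azimuth, head) == pytest.approx(expected_s, abs=1e-12)

    def test_rear_source_carries_mirror_itd(self, geometry):
        """A source behind the interaural axis is indistinguishable from its
        front mirror image: itd(180 - a) == itd(a)."""
        for a in (10.0, 40.0, 75.0):
            assert itd_for_source(geometry, 180.0 - a, 0.0) == pytest.approx(
                itd_for_source(geometry, a, 0.0), abs=1e-15
            )

    @given(azimuth=st.floats(0, 360, allow_nan=False), head=st.floats(0, 360))
    def test_bounded_by_endfire_delay(self, azimuth, head):
        from earshot import ArrayGeometry

        geo = ArrayGeometry()
        assert abs(itd_for_source(geo, azimuth, head)) <= geo.max_itd_s + 1e-15


class TestRenderFrame:
    def test_midline_source_gives_identical_channels(self, geometry):
        scene = SceneSpec(sources=(SourceSpec.tone(500, azimuth_deg=0.0),),
                          duration_frames=1, seed=0)
        frame = render_frame(scene, geometry, 0.0, 0)
        np.testing.assert_allclose(frame.samples[0], frame.samples[1], atol=1e-12)

    def test_left_right_mirror_swaps_channels(self, geometry):
        left = SceneSpec(sources=(SourceSpec.tone(700, azimuth_deg=-90.0),),
                         duration_frames=1, seed=0)
        right = SceneSpec(sources=(SourceSpec.tone(700, azimuth_deg=90.0),),
                          duration_frames=1, seed=0)
        fl = render_frame(left, geometry, 0.0, 0)
        fr = render_frame(right, geometry, 0.0, 0)
        np.testing.assert_allclose(fl.samples[0], fr.samples[1], atol=1e-12)
        np.testing.assert_allclose(fl.samples[1], fr.samples[0], atol=1e-12)

    def test_cross_correlation_lag_matches_itd(self, geometry):
        """500 Hz tone at 30 deg: interaural lag of the rendered frame equals
        round(fs * (d/c) * sin 30) = 10 samples (brute-force oracle)."""
        scene = SceneSpec(sources=(SourceSpec.tone(500, azimuth_deg=30.0),),
                          duration_frames=1, seed=0)
        frame = render_frame(scene, geometry, 0.0, 0)
        left, right = frame.samples
        c = correlate(left, right, mode="full")
        lags = correlation_lags(left.size, right.size, mode="full")
        window = np.abs(lags) <= geometry.max_delay_samples  # one ITD period
        best = lags[window][np.argmax(c[window])]
        assert best == 10

    @pytest.mark.parametrize("ego_deg", [-60.0, -25.0, 0.0, 15.0, 45.0, 80.0])
    def test_lag_oracle_across_angles(self, geometry, ego_deg):
        scene = SceneSpec(sources=(SourceSpec.tone(400, azimuth_deg=ego_deg),),
                          duration_frames=1, seed=0)
        frame = render_frame(scene, geometry, 0.0, 0)
        left, right = frame.samples
        c = correlate(left, right, mode="full")
        lags = correlation_lags(left.size, right.size, mode="full")
        window = np.abs(lags) <= geometry.max_delay_samples
        best = lags[window][np.argmax(c[window])]
        expected = np.round(FS * itd_for_source(geometry, ego_deg, 0.0))
        assert abs(best - expected) <= 1

    def test_egocentric_equivalence(self, geometry):
        """Head at alpha with world sources == head at 0 with sources shifted
        by -alpha: the ears only ever see egocentric angles."""
        alpha = 25.0
        srcs = (SourceSpec.tone(500, azimuth_deg=40.0),
                SourceSpec.noise(azimuth_deg=300.0))
        rotated = tuple(
            SourceSpec(kind=s.kind, azimuth_deg=(s.azimuth_deg - alpha) % 360,
                       level=s.level, freq_hz=s.freq_hz) for s in srcs
        )
        a = SceneSpec(sources=srcs, background_noise_level=0.1, duration_frames=1, seed=7)
        b = SceneSpec(sources=rotated, background_noise_level=0.1, duration_frames=1, seed=7)
        fa = render_frame(a, geometry, alpha, 0)
        fb = render_frame(b, geometry, 0.0, 0)
        np.testing.assert_allclose(fa.samples, fb.samples, atol=1e-10)

    def test_frame_energy_invariant_to_orientation(self, geometry):
        """Delays do not change per-channel RMS beyond edge effects (<1%)."""
        scene = SceneSpec(
            sources=(SourceSpec.tone_complex((400, 1000, 2200), azimuth_deg=70.0),),
            duration_frames=1, seed=0,
        )
        renderer = SceneRenderer(scene, geometry)
        rms = [
            np.sqrt(np.mean(renderer.render_frame(h, 0).samples ** 2))
            for h in (0.0, 30.0, 90.0, 150.0)
        ]
        assert np.ptp(rms) / np.mean(rms) < 0.01

    def test_deterministic_given_seed(self, geometry):
        scene = SceneSpec(sources=(SourceSpec.noise(azimuth_deg=10.0),),
                          background_noise_level=0.05, duration_frames=2, seed=42)
        f1 = SceneRenderer(scene, geometry).render_frame(20.0, 1)
        f2 = SceneRenderer(scene, geometry).render_frame(20.0, 1)
        np.testing.assert_array_equal(f1.samples, f2.samples)

    def test_phase_continuity_across_frames(self, geometry):
        """Consecutive frames of a tone concatenate into one continuous sinusoid."""
        scene = SceneSpec(sources=(SourceSpec.tone(501.3, azimuth_deg=0.0),),
                          duration_frames=2, seed=0)
        r = SceneRenderer(scene, geometry)
        joined = np.concatenate(
            [r.render_frame(0.0, 0).samples[0], r.render_frame(0.0, 1).samples[0]]
        )
        t = np.arange(joined.size) / FS
        expected = np.sin(2 * np.pi * 501.3 * t)
        # compare shapes after unit-RMS normalization: any seam between the
        # frames would break pointwise phase agreement
        np.testing.assert_allclose(joined / np.sqrt(np.mean(joined**2)),
                                   expected / np.sqrt(np.mean(expected**2)),
                                   atol=1e-6)


class TestErrors:
    def test_tone_above_nyquist_rejected(self, geometry):
        scene = SceneSpec(sources=(SourceSpec.tone(30000, azimuth_deg=0.0),),
                          duration_frames=1)
        with pytest.raises(SceneError, match="outside"):
            SceneRenderer(scene, geometry)

    def test_missing_wav_reported_unreadable(self, geometry, tmp_path):
        scene = SceneSpec(
            sources=(SourceSpec.wav(str(tmp_path / "nope.wav"), azimuth_deg=0.0),),
            duration_frames=1,
        )
        with pytest.raises(SceneError, match="unreadable"):
            SceneRenderer(scene, geometry)

    def test_frame_index_out_of_range(self, geometry):
        scene = SceneSpec(sources=(SourceSpec.tone(500, azimuth_deg=0.0),),
                          duration_frames=1)
        with pytest.raises(SceneError, match="frame_index"):
            SceneRenderer(scene, geometry).render_frame(0.0, 5)

    def test_invalid_geometry_rejected(self):
        from earshot import ArrayGeometry

        with pytest.raises(SceneError):
            ArrayGeometry(mic_spacing_m=-1.0)
        with pytest.raises(SceneError):
            ArrayGeometry(mic_spacing_m=0.001)  # below one sample of delay


class TestWavInput:
    def test_wav_source_resampled_and_rendered(self, geometry, tmp_path):
        rng = np.random.default_rng(0)
        fs_in = 44100
        data = (rng.standard_normal(fs_in) * 8000).astype(np.int16)
        path = tmp_path / "talker.wav"
        wavfile.write(path, fs_in, data)
        scene = SceneSpec(sources=(SourceSpec.wav(str(path), azimuth_deg=20.0),),
                          duration_frames=1, seed=0)
        frame = SceneRenderer(scene, geometry).render_frame(0.0, 0)
        rms = np.sqrt(np.mean(frame.samples**2))
        assert np.isfinite(frame.samples).all()
        assert rms == pytest.approx(1.0, rel=0.15)  # unit-RMS level equalization
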