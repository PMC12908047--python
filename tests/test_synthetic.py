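"""Generator-level checks: waveforms, rendering forward model, conditions."""

import dataclasses

import numpy as np
import pytest

import flickermap as fm
from flickermap.synthetic import example_scene, sweep_segment_lengths


def small_scene(**kw):
    return example_scene(image_shape=(64, 64), n_hotspots=1, **kw)


class TestSimulateBundle:
    def test_entrained_pure_tone_is_exact_sine(self, quiet_camera, quiet_bundle):
        # 10 Hz drive at 60 nm for 5 s at 1000 fps, all noise off
        protocol = fm.StimulusProtocol(
            kind="pure_tone", amplitude=60.0, tone_frequency=10.0, duration=5.0
        )
        cam = dataclasses.replace(quiet_camera, frame_count=5000)
        trace = fm.simulate_bundle(quiet_bundle, protocol, cam, seed=0)
        t = np.arange(5000) / 1000.0
        assert trace.n == 5000
        np.testing.assert_allclose(
            trace.values, 60.0 * np.sin(2 * np.pi * 10.0 * t), atol=1e-9
        )

    def test_null_oscillator_is_all_zero(self, quiet_camera):
        model = fm.BundleModel(
            amplitude=0.0, dwell_noise_cv=0.0, position_noise_sd=0.0
        )
        trace = fm.simulate_bundle(
            model, fm.StimulusProtocol(kind="none", duration=1.0),
            dataclasses.replace(quiet_camera, frame_count=1000), seed=0,
        )
        assert np.all(trace.values == 0.0)

    @pytest.mark.parametrize("duty", [0.3, 0.5, 0.7])
    def test_relaxation_duty_cycle_matches_state_census(self, duty):
        # oracle: brute-force census of the raw two-state sequence
        from flickermap.synthetic import _relaxation_square, _rng

        model = fm.BundleModel(
            natural_frequency=20.0, amplitude=1.0, duty_cycle=duty, dwell_noise_cv=0.2
        )
        square = _relaxation_square(model, 200_000, 1000.0, _rng(7, 1))
        upper_fraction = np.count_nonzero(square > 0) / square.size
        assert upper_fraction == pytest.approx(duty, abs=0.03)

    def test_below_threshold_drive_leaves_spontaneous_statistics(self, quiet_camera):
        model = fm.BundleModel()
        cam = dataclasses.replace(quiet_camera, frame_count=2000)
        weak = fm.StimulusProtocol(kind="pure_tone", amplitude=10.0, duration=2.0)
        none = fm.StimulusProtocol(kind="none", duration=2.0)
        a = fm.simulate_bundle(model, weak, cam, seed=5)
        b = fm.simulate_bundle(model, none, cam, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_entrainment_raises_power_at_stimulus_frequency(self, quiet_camera):
        model = fm.BundleModel()
        cam = dataclasses.replace(quiet_camera, frame_count=3000)
        f_drive = 37.0
        strong = fm.StimulusProtocol(
            kind="pure_tone", amplitude=50.0, tone_frequency=f_drive, duration=3.0
        )
        none = fm.StimulusProtocol(kind="none", duration=3.0)
        driven = fm.simulate_bundle(model, strong, cam, seed=3)
        free = fm.simulate_bundle(model, none, cam, seed=3)
        band = (f_drive - 0.5, f_drive + 0.5)
        _, a_driven = fm.peak_metrics(fm.normalized_spectrum(driven), band=band)
        _, a_free = fm.peak_metrics(fm.normalized_spectrum(free), band=band)
        assert a_driven > a_free

    def test_rejects_non_positive_duration(self, quiet_camera, quiet_bundle):
        with pytest.raises(ValueError):
            fm.StimulusProtocol(kind="none", duration=0.0)


class TestRenderStack:
    def test_zero_amplitude_noiseless_render_is_static(self, quiet_camera):
        scene = small_scene()
        model = fm.BundleModel(amplitude=0.0, dwell_noise_cv=0.0, position_noise_sd=0.0)
        protocol = fm.StimulusProtocol(kind="none", duration=0.05)
        stacks, truth, _ = fm.make_dataset(
            scene, model, protocol, quiet_camera, seed=0, z_indices=[0]
        )
        frames = stacks[0].frames
        assert np.all(frames == frames[0])

    def test_hotspot_temporal_sd_matches_sine_closed_form(self, quiet_camera):
        # population SD of a sampled on-bin sinusoid is amplitude/sqrt(2)
        gain, amp_nm, z = 0.01, 50.0, 0
        scene = small_scene(gain=gain)
        model = fm.BundleModel(
            waveform="sinusoid", amplitude=amp_nm, natural_frequency=20.0,
            dwell_noise_cv=0.0, position_noise_sd=0.0,
        )
        protocol = fm.StimulusProtocol(kind="none", duration=1.0)
        stacks, truth, _ = fm.make_dataset(
            scene, model, protocol, quiet_camera, seed=0, z_indices=[z]
        )
        amap = fm.temporal_stats(stacks[z], normalize=False)
        r, c = scene.hotspots[0].center
        measured = amap.sigma[int(round(r)), int(round(c))]
        expected = gain * amp_nm * scene.background_level * scene.z_attenuation[z] / np.sqrt(2)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_suppression_scales_modulation_by_render_difference(self, quiet_camera):
        # oracle: subtract noiseless static render from noiseless dynamic render
        def modulation_rms(suppression):
            scene = small_scene(gain=0.01, suppression=suppression)
            model = fm.BundleModel(
                waveform="sinusoid", amplitude=50.0, natural_frequency=20.0,
                dwell_noise_cv=0.0, position_noise_sd=0.0,
            )
            protocol = fm.StimulusProtocol(kind="none", duration=0.5)
            stacks, _, _ = fm.make_dataset(
                scene, model, protocol, quiet_camera, seed=4, z_indices=[0]
            )
            frames = stacks[0].frames.astype(float)
            r, c = scene.hotspots[0].center
            pixel = frames[:, int(round(r)), int(round(c))]
            return (pixel - pixel.mean()).std()

        ratio = modulation_rms(0.35) / modulation_rms(1.0)
        assert ratio == pytest.approx(0.35, abs=0.01)

    def test_out_of_bounds_hotspot_blob_rejected(self, quiet_camera):
        scene = small_scene()
        bad = dataclasses.replace(scene.hotspots[0], center=(2.0, 2.0))
        scene = dataclasses.replace(scene, hotspots=[bad])
        model = fm.BundleModel(amplitude=0.0, dwell_noise_cv=0.0, position_noise_sd=0.0)
        with pytest.raises(ValueError, match="beyond"):
            fm.make_dataset(
                scene, model, fm.StimulusProtocol(kind="none", duration=0.05),
                quiet_camera, seed=0, z_indices=[0],
            )


class TestMakeDataset:
    def test_salicylate_is_dynamically_identical_to_control(self):
        scene = small_scene()
        camera = fm.CameraModel(frame_count=200)
        protocol = fm.StimulusProtocol(kind="none", duration=0.2)
        out_c = fm.make_dataset(scene, fm.BundleModel(), protocol, camera,
                                condition="control", seed=9, z_indices=[0])
        out_s = fm.make_dataset(scene, fm.BundleModel(), protocol, camera,
                                condition="salicylate", seed=9, z_indices=[0])
        for a, b in zip(out_c[1].hotspot_modulations, out_s[1].hotspot_modulations):
            np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(out_c[0][0].frames, out_s[0][0].frames)

    def test_bapta_zeroes_hotspot_modulation(self):
        scene = small_scene(intrinsic_noise_sd=0.002)
        camera = fm.CameraModel(frame_count=600)
        protocol = fm.StimulusProtocol(
            kind="sweep", amplitude=50.0, sweep_start=20.0, sweep_end=60.0,
            n_steps=3, cycles_per_step=10,
        )
        _, truth, _ = fm.make_dataset(scene, fm.BundleModel(), protocol, camera,
                                      condition="bapta", seed=2, z_indices=[0])
        for mod in truth.hotspot_modulations:
            assert np.all(mod.values == 0.0)

    def test_fixed_seed_is_bit_reproducible(self):
        scene = small_scene()
        camera = fm.CameraModel(frame_count=120)
        protocol = fm.StimulusProtocol(kind="none", duration=0.12)
        runs = [
            fm.make_dataset(scene, fm.BundleModel(), protocol, camera, seed=11,
                            z_indices=[0])
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0][0][0].frames, runs[1][0][0].frames)
        np.testing.assert_array_equal(
            runs[0][1].bundle_trace.values, runs[1][1].bundle_trace.values
        )

    def test_no_saturation_under_defaults(self):
        scene = small_scene()
        camera = fm.CameraModel(frame_count=300)
        protocol = fm.StimulusProtocol(kind="none", duration=0.3)
        stacks, _, _ = fm.make_dataset(scene, fm.BundleModel(), protocol, camera,
                                       seed=0, z_indices=[0])
        frames = stacks[0].frames
        saturated = np.count_nonzero(frames >= camera.max_count) / frames.size
        assert saturated < 0.001

    def test_sweep_sample_count_matches_summation_oracle(self):
        protocol = fm.StimulusProtocol(kind="sweep", amplitude=50.0)
        fs = 1000.0
        # independent summation over the frequency ladder
        freqs = np.geomspace(1.0, 100.0, 30)
        expected = sum(int(round(10 * fs / f)) for f in freqs)
        assert sweep_segment_lengths(protocol, fs).sum() == expected

    def test_manifest_records_condition_and_seed(self):
        scene = small_scene()
        camera = fm.CameraModel(frame_count=100)
        protocol = fm.StimulusProtocol(kind="none", duration=0.1)
        _, _, manifest = fm.make_dataset(scene, fm.BundleModel(), protocol, camera,
                                         condition="salicylate", seed=31, z_indices=[0])
        assert manifest["condition"] == "salicylate"
        assert manifest["seed"] == 31
        assert manifest["protocol"]["kind"] == "none"
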