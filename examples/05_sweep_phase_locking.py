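"""Frequency-sweep phase-locking curves at strong and weak drive.

Applies a stepped sweep (10 cycles per step) to the bundle at 50 nm
(above the entrainment threshold) and at 10 nm (below it), and computes
the hotspot's phase-locked response — the amplitude of its ΔI/I component
at each step's stimulus frequency.  A shortened 12-step, 3-40 Hz sweep
keeps this example quick; the analysis is identical for the full
30-step, 1-100 Hz protocol.
"""

import numpy as np

import flickermap as fm
from flickermap.entrainment import segment_sweep
from flickermap.synthetic import background_roi, example_scene


def curve(amplitude, seed=5):
    scene = example_scene(image_shape=(64, 64), n_hotspots=1)
    protocol = fm.StimulusProtocol(
        kind="sweep", amplitude=amplitude, sweep_start=3.0, sweep_end=40.0,
        n_steps=12, cycles_per_step=10,
    )
    stacks, _, _ = fm.make_dataset(
        scene, fm.BundleModel(), protocol, fm.CameraModel(), seed=seed,
        z_indices=[0],
    )
    roi = fm.Roi(center=scene.hotspots[0].center, radius=5.0)
    trace = fm.extract_trace(stacks[0], roi, background_roi(scene))
    seg = segment_sweep(protocol, 1000.0)
    return fm.phase_locked_response(trace, seg, amplitude_label=amplitude)


strong = curve(50.0)
weak = curve(10.0)
table, median_ratio = fm.compare_curves(weak, strong)

print(f"{'f (Hz)':>8} {'50 nm resp':>11} {'10 nm resp':>11} {'ratio':>8}")
for _, row in table.iterrows():
    print(f"{row['frequency_hz']:8.2f} {row['response_b']:11.5f} "
          f"{row['response_a']:11.5f} {row['response_b'] / row['response_a']:8.1f}")
print(f"median 50nm/10nm response ratio: {median_ratio:.0f}x")
print("the strong drive entrains the bundle, so the hotspot phase-locks at "
      "every step; the weak drive leaves only the spontaneous 15 Hz activity, "
      "visible as a locally raised 10 nm response near that frequency")
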