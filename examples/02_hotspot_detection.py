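"""Detect activity hotspots and extract their ΔI/I traces.

Thresholds the sigma map at mean + 3 SD, groups supra-threshold pixels by
8-connectivity, and extracts the background-normalized intensity trace of
each detected hotspot.  The trace's spectral peak should sit at the
bundle's oscillation frequency (15 Hz here).
"""

import flickermap as fm
from flickermap.synthetic import background_roi, example_scene, soma_analysis_mask

scene = example_scene(n_hotspots=2)
camera = fm.CameraModel(frame_count=3000)
stacks, _, _ = fm.make_dataset(
    scene, fm.BundleModel(), fm.StimulusProtocol(kind="none", duration=3.0),
    camera, seed=42, z_indices=[0],
)
stack = stacks[0]
bg = background_roi(scene)

amap = fm.temporal_stats(stack, background=bg, mask=soma_analysis_mask(scene))
hotspots = fm.detect_hotspots(amap, k_sigma=3.0, min_area=4, roi_radius=5.0)

print(f"{len(hotspots)} hotspots detected (injected: "
      f"{[tuple(round(v, 1) for v in h.center) for h in scene.hotspots]})")
for i, hs in enumerate(hotspots):
    trace = fm.extract_trace(stack, hs.roi, bg)
    spec = fm.normalized_spectrum(trace)
    f_peak, amp = fm.peak_metrics(spec, band=(2.0, 100.0))
    print(f"  hotspot {i}: centroid ({hs.centroid[0]:.1f}, {hs.centroid[1]:.1f}), "
          f"area {hs.area_px} px, ΔI/I peak {amp:.4f} at {f_peak:.2f} Hz")
# each centroid lands within a fraction of a pixel of an injected center,
# and the ΔI/I spectra peak at the bundle's 15 Hz oscillation
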