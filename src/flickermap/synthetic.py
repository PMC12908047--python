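"""Synthetic hair-cell recording generator with ground-truth annotation.

The forward model emulates a wide-field, high-speed bright-field recording
of a single hair cell: a static soma scene imaged at 108.3 nm/px and
1000 frames/s, a hair bundle rendered as an intensity ridge that
translates with the bundle's (spontaneous or driven) displacement, and
somatic "hotspots" — diffuse Gaussian blobs whose brightness is modulated
coherently with the bundle motion, with configurable optical gain, time
lag, per-depth attenuation across six axial sections, and a suppression
factor standing in for tip-link severing.  Camera shot noise (Poisson,
with a Gaussian approximation at high counts), Gaussian read noise, and
16-bit quantization complete the model.

The spontaneous bundle waveform is a two-state relaxation oscillation
with gamma-jittered dwell times smoothed by a 2 ms low-pass — the
square-wave-like limit-cycle characteristic of bullfrog saccular bundles —
with a pure-sinusoid mode for analytic tests.  Entrainment is a binary
threshold on the stimulus amplitude: above it the bundle follows the
stimulus waveform (plus position noise), below it the bundle keeps
oscillating spontaneously.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
import yaml
from numpy.random import default_rng
from scipy.ndimage import gaussian_filter1d
from skimage.draw import polygon as draw_polygon

from .activity import Roi
from .io import ImageStack, Trace, write_stack, write_trace

__all__ = [
    "CameraModel",
    "BundleModel",
    "HotspotSpec",
    "StimulusProtocol",
    "SceneSpec",
    "GroundTruth",
    "sweep_frequencies",
    "sweep_segment_lengths",
    "protocol_sample_count",
    "stimulus_trace",
    "simulate_bundle",
    "render_stack",
    "make_dataset",
    "example_scene",
    "background_roi",
    "control_roi",
    "load_config",
    "save_dataset",
]

# Fixed per-component RNG stream tags so conditions sharing a master seed
# are paired (control vs treated reuse the same bundle and camera noise).
_STREAM_BUNDLE = 1
_STREAM_HOTSPOT = 2
_STREAM_CAMERA = 3
_MAX_SEED = 2**31
_RENDER_CHUNK = 1024
_SMOOTH_TAU_S = 0.002  # low-pass applied to the relaxation square wave
_POISSON_GAUSS_MIN = 50.0  # counts above which shot noise is Gaussian


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return default_rng([int(seed) % _MAX_SEED, *stream])


@dataclasses.dataclass
class CameraModel:
    """Acquisition parameters of the (simulated) high-speed camera.

    ``gain`` is in electrons per count (sCMOS-style); ``read_noise_sd`` in
    counts.  ``shot_noise`` switches photon noise off entirely for
    analytic tests.
    """

    frame_rate: float = 1000.0
    pixel_pitch: float = 108.3
    bit_depth: int = 16
    gain: float = 0.46
    read_noise_sd: float = 1.6
    frame_count: int = 3000
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclasses.dataclass
class BundleModel:
    """Parameters of the spontaneous hair-bundle oscillator.

    ``amplitude`` is the half peak-to-peak excursion in nm.  The
    relaxation waveform dwells near ±amplitude with gamma-distributed
    dwell times (coefficient of variation ``dwell_noise_cv``,
    up-state fraction ``duty_cycle``).  ``entrainment_threshold`` is the
    stimulus amplitude (nm) above which an applied drive captures the
    bundle.
    """

    natural_frequency: float = 15.0
    amplitude: float = 10.0
    waveform: str = "relaxation"  # {"relaxation", "sinusoid"}
    duty_cycle: float = 0.5
    dwell_noise_cv: float = 0.1
    position_noise_sd: float = 3.0
    entrainment_threshold: float = 25.0

    def __post_init__(self) -> None:
        if not self.natural_frequency > 0:
            raise ValueError("natural_frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.waveform not in ("relaxation", "sinusoid"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.dwell_noise_cv < 0:
            raise ValueError("dwell_noise_cv must be >= 0")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")


@dataclasses.dataclass
class HotspotSpec:
    """A simulated somatic activity hotspot.

    ``gain`` converts bundle displacement (nm) into fractional intensity
    modulation ΔI/I; ``lag`` delays the modulation relative to the bundle;
    ``suppression_factor`` scales the whole modulation (1 = healthy,
    0 = fully suppressed, emulating severed tip links).
    """

    center: tuple[float, float]
    radius_px: float = 4.0
    z_index: int = 0
    gain: float = 0.004
    lag: float = 0.0
    intrinsic_noise_sd: float = 0.0
    suppression_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius_px >= 1:
            raise ValueError("radius_px must be >= 1")
        if not 0 <= self.suppression_factor <= 1:
            raise ValueError("suppression_factor must be in [0, 1]")
        if not 0 <= self.z_index <= 5:
            raise ValueError("z_index must be in 0..5")
        if self.intrinsic_noise_sd < 0:
            raise ValueError("intrinsic_noise_sd must be >= 0")


@dataclasses.dataclass
class StimulusProtocol:
    """Mechanical stimulus applied to the bundle via the glass probe.

    ``amplitude`` is the probe-tip displacement in nm.  A sweep steps
    through ``n_steps`` discrete frequencies from ``sweep_start`` to
    ``sweep_end`` (linear or logarithmic spacing), holding each for
    exactly ``cycles_per_step`` cycles.
    """

    kind: str = "none"  # {"none", "pure_tone", "sweep"}
    amplitude: float = 0.0
    tone_frequency: float = 10.0
    sweep_start: float = 1.0
    sweep_end: float = 100.0
    cycles_per_step: int = 10
    step_spacing: str = "log"  # {"linear", "log"}
    n_steps: int = 30
    duration: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "pure_tone", "sweep"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind == "sweep":
            if not self.sweep_start < self.sweep_end:
                raise ValueError("sweep requires sweep_start < sweep_end")
            if self.cycles_per_step < 1:
                raise ValueError("cycles_per_step must be >= 1")
            if self.n_steps < 1:
                raise ValueError("n_steps must be >= 1")
            if self.step_spacing not in ("linear", "log"):
                raise ValueError(f"unknown step_spacing {self.step_spacing!r}")
        if self.kind in ("none", "pure_tone") and not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.kind == "pure_tone" and not self.tone_frequency > 0:
            raise ValueError("tone_frequency must be positive")


@dataclasses.dataclass
class SceneSpec:
    """Static geometry of the simulated field of view.

    The soma is a filled polygon slightly brighter than the background;
    the bundle is a Gaussian intensity ridge inside ``bundle_roi`` that
    translates along ``bundle_axis``.  ``z_attenuation`` multiplies
    hotspot modulation per axial section (index 0 = bundle plane).
    """

    image_shape: tuple[int, int] = (128, 128)
    soma_outline: Optional[np.ndarray] = None  # (k, 2) array of (row, col)
    bundle_roi: Optional[tuple[int, int, int, int]] = None  # r0, c0, r1, c1
    bundle_axis: tuple[float, float] = (0.0, 1.0)
    background_level: float = 1000.0
    hotspots: Sequence[HotspotSpec] = ()
    z_attenuation: Sequence[float] = (1.0, 0.85, 0.70, 0.55, 0.45, 0.35)
    seed: int = 0
    ridge_amplitude: float = 800.0
    ridge_sigma_px: float = 2.0
    soma_contrast: float = 1.15

    def __post_init__(self) -> None:
        h, w = self.image_shape
        ax = np.asarray(self.bundle_axis, dtype=float)
        norm = np.hypot(ax[0], ax[1])
        if norm == 0:
            raise ValueError("bundle_axis must be a nonzero vector")
        self.bundle_axis = (float(ax[0] / norm), float(ax[1] / norm))
        if self.soma_outline is not None:
            self.soma_outline = np.asarray(self.soma_outline, dtype=float)
        att = np.asarray(self.z_attenuation, dtype=float)
        if np.any(att <= 0) or np.any(att > 1):
            raise ValueError("z_attenuation entries must be in (0, 1]")
        self.z_attenuation = tuple(att)
        if not self.background_level > 0:
            raise ValueError("background_level must be positive")
        for hs in self.hotspots:
            r, c = hs.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"hotspot center {hs.center} outside image {self.image_shape}")

    @property
    def n_z(self) -> int:
        return len(self.z_attenuation)


@dataclasses.dataclass
class GroundTruth:
    """Generator-side truth for one dataset: what the pipeline should recover."""

    bundle_trace: Trace
    hotspot_modulations: list[Trace]
    stimulus_trace: Trace
    step_boundaries: list[int]

    def __post_init__(self) -> None:
        n = self.bundle_trace.n
        for tr in [*self.hotspot_modulations, self.stimulus_trace]:
            if tr.n != n:
                raise ValueError("all ground-truth traces must share one sample count")


# --------------------------------------------------------------------------
# stimulus protocols


def sweep_frequencies(protocol: StimulusProtocol) -> np.ndarray:
    """The discrete frequency ladder of a stepped sweep."""
    if protocol.kind != "sweep":
        raise ValueError("sweep_frequencies requires a sweep protocol")
    if protocol.step_spacing == "log":
        return np.geomspace(protocol.sweep_start, protocol.sweep_end, protocol.n_steps)
    return np.linspace(protocol.sweep_start, protocol.sweep_end, protocol.n_steps)


def sweep_segment_lengths(protocol: StimulusProtocol, sample_rate: float) -> np.ndarray:
    """Samples per sweep step: round(cycles_per_step * fs / f_i)."""
    freqs = sweep_frequencies(protocol)
    return np.rint(protocol.cycles_per_step * sample_rate / freqs).astype(int)


def protocol_sample_count(protocol: StimulusProtocol, sample_rate: float) -> int:
    """Number of camera frames a protocol occupies at a given rate."""
    if protocol.kind == "sweep":
        return int(sweep_segment_lengths(protocol, sample_rate).sum())
    n = int(round(protocol.duration * sample_rate))
    if n < 2:
        raise ValueError("protocol duration too short at this sample rate")
    return n


def _stimulus_values(protocol: StimulusProtocol, sample_rate: float, n: int) -> np.ndarray:
    if protocol.kind == "none" or protocol.amplitude == 0:
        return np.zeros(n)
    if protocol.kind == "pure_tone":
        t = np.arange(n) / sample_rate
        return protocol.amplitude * np.sin(2 * np.pi * protocol.tone_frequency * t)
    # sweep: each step starts at phase zero; steps hold an integer number of
    # cycles, so the waveform is continuous across boundaries up to rounding.
    freqs = sweep_frequencies(protocol)
    lengths = sweep_segment_lengths(protocol, sample_rate)
    parts = []
    for f, m in zip(freqs, lengths):
        t = np.arange(m) / sample_rate
        parts.append(protocol.amplitude * np.sin(2 * np.pi * f * t))
    out = np.concatenate(parts)
    if out.size != n:
        raise ValueError("stimulus length does not match requested sample count")
    return out


def stimulus_trace(protocol: StimulusProtocol, sample_rate: float, n: Optional[int] = None) -> Trace:
    """The probe-tip command waveform as a Trace (nm)."""
    if n is None:
        n = protocol_sample_count(protocol, sample_rate)
    return Trace(_stimulus_values(protocol, sample_rate, n), sample_rate, kind="stimulus_nm")


# --------------------------------------------------------------------------
# bundle motion


def _relaxation_square(model: BundleModel, n: int, sample_rate: float, rng) -> np.ndarray:
    """Raw two-state (±amplitude) dwell sequence before smoothing."""
    period = 1.0 / model.natural_frequency
    mean_dwell = {1: model.duty_cycle * period, -1: (1 - model.duty_cycle) * period}
    cv = model.dwell_noise_cv
    state = 1
    counts: list[tuple[int, int]] = []
    total = 0
    while total < n:
        mean = mean_dwell[state]
        if cv == 0:
            dwell = mean
        else:
            shape = 1.0 / cv**2
            dwell = rng.gamma(shape, mean / shape)
        m = max(1, int(round(dwell * sample_rate)))
        counts.append((state, m))
        total += m
        state = -state
    states = np.repeat([s for s, _ in counts], [m for _, m in counts])[:n]
    return model.amplitude * states.astype(float)


def simulate_bundle(
    model: BundleModel,
    protocol: StimulusProtocol,
    camera: CameraModel,
    seed: int = 0,
    entrain: bool = True,
) -> Trace:
    """Bundle displacement (nm) over ``camera.frame_count`` frames.

    With no stimulus (or a drive below ``entrainment_threshold``) the
    bundle oscillates spontaneously near its natural frequency; at or
    above the threshold it follows the stimulus waveform.  ``entrain``
    can be forced off to emulate a bundle whose transduction machinery is
    disabled.  Deterministic for a fixed seed.
    """
    fs = camera.frame_rate
    n = camera.frame_count
    if protocol.kind in ("none", "pure_tone") and not protocol.duration > 0:
        raise ValueError("protocol duration must be positive")
    rng = _rng(seed, _STREAM_BUNDLE)
    driven = (
        entrain
        and protocol.kind != "none"
        and protocol.amplitude >= model.entrainment_threshold
    )
    if driven:
        x = _stimulus_values(protocol, fs, n)
    elif model.waveform == "sinusoid":
        t = np.arange(n) / fs
        x = model.amplitude * np.sin(2 * np.pi * model.natural_frequency * t)
    else:
        square = _relaxation_square(model, n, fs, rng)
        x = gaussian_filter1d(square, sigma=_SMOOTH_TAU_S * fs, mode="nearest")
    if model.position_noise_sd > 0:
        x = x + rng.normal(0.0, model.position_noise_sd, n)
    return Trace(x, fs, kind="displacement_nm")


def _delayed(values: np.ndarray, shift: int) -> np.ndarray:
    """Shift a trace by `shift` samples (positive = delayed), edge-padded."""
    if shift == 0:
        return values.copy()
    out = np.empty_like(values)
    if shift > 0:
        out[:shift] = values[0]
        out[shift:] = values[:-shift]
    else:
        out[shift:] = values[-1]
        out[:shift] = values[-shift:]
    return out


def _hotspot_modulation(
    bundle_values: np.ndarray,
    spec: HotspotSpec,
    z_attenuation: Sequence[float],
    sample_rate: float,
    rng,
) -> np.ndarray:
    """ΔI/I modulation of one hotspot at its own axial section."""
    shift = int(round(spec.lag * sample_rate))
    mod = spec.gain * _delayed(bundle_values, shift)
    if spec.intrinsic_noise_sd > 0:
        mod = mod + rng.normal(0.0, spec.intrinsic_noise_sd, bundle_values.size)
    return z_attenuation[spec.z_index] * spec.suppression_factor * mod


# --------------------------------------------------------------------------
# rendering


def _static_scene(scene: SceneSpec) -> np.ndarray:
    img = np.full(scene.image_shape, scene.background_level, dtype=np.float64)
    if scene.soma_outline is not None:
        rr, cc = draw_polygon(
            scene.soma_outline[:, 0], scene.soma_outline[:, 1], shape=scene.image_shape
        )
        img[rr, cc] = scene.background_level * scene.soma_contrast
    return img


def _gaussian_blob(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def render_stack(
    scene: SceneSpec,
    truth: GroundTruth,
    camera: CameraModel,
    z_index: int = 0,
) -> ImageStack:
    """Render one axial section of the recording as a quantized image stack.

    Each frame is the static scene plus, for every hotspot assigned to
    this section, a Gaussian blob (SD = radius/2) whose amplitude is
    ``background_level × modulation[k]`` — the modulation trace already
    carries gain, lag, depth attenuation and suppression.  At section 0
    the bundle ridge translates along the bundle axis following the
    bundle trace at the camera's pixel pitch.  Shot noise, read noise and
    saturating quantization are applied last.  Deterministic for a fixed
    ``scene.seed``.
    """
    n = camera.frame_count
    if truth.bundle_trace.n != n:
        raise ValueError("ground-truth traces do not match camera.frame_count")
    if not 0 <= z_index < scene.n_z:
        raise ValueError(f"z_index {z_index} outside 0..{scene.n_z - 1}")
    h, w = scene.image_shape

    blobs: list[tuple[slice, slice, np.ndarray]] = []
    mods: list[np.ndarray] = []
    for spec, mod in zip(scene.hotspots, truth.hotspot_modulations, strict=True):
        if spec.z_index != z_index:
            continue
        margin = 2.0 * spec.radius_px  # 4 blob SDs
        r, c = spec.center
        if r - margin < 0 or c - margin < 0 or r + margin > h - 1 or c + margin > w - 1:
            raise ValueError(
                f"hotspot blob at {spec.center} (radius {spec.radius_px}) extends "
                f"beyond the {scene.image_shape} image"
            )
        # blob support restricted to its 4-SD bounding box
        rs = slice(int(np.floor(r - margin)), int(np.ceil(r + margin)) + 1)
        cs = slice(int(np.floor(c - margin)), int(np.ceil(c + margin)) + 1)
        rr, cc = np.mgrid[rs, cs]
        blob = np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * (spec.radius_px / 2.0) ** 2)
        )
        blobs.append((rs, cs, blob))
        mods.append(mod.values)

    static = _static_scene(scene)
    render_ridge = z_index == 0 and scene.bundle_roi is not None
    if render_ridge:
        r0, c0, r1, c1 = scene.bundle_roi
        rr, cc = np.mgrid[r0:r1, c0:c1]
        ar, ac = scene.bundle_axis
        center_u = ((r0 + r1 - 1) / 2.0) * ar + ((c0 + c1 - 1) / 2.0) * ac
        u = rr * ar + cc * ac - center_u  # axis coordinate relative to roi center
        bundle_px = truth.bundle_trace.values / camera.pixel_pitch

    rng = _rng(scene.seed, _STREAM_CAMERA, z_index)
    out = np.empty((n, h, w), dtype=camera.dtype)
    read_var = camera.read_noise_sd**2
    for i0 in range(0, n, _RENDER_CHUNK):
        i1 = min(i0 + _RENDER_CHUNK, n)
        f = np.empty((i1 - i0, h, w), dtype=np.float32)
        f[:] = static
        for (rs, cs, blob), mod in zip(blobs, mods):
            f[:, rs, cs] += (
                scene.background_level * mod[i0:i1, None, None] * blob[None]
            ).astype(np.float32)
        if render_ridge:
            shift = u[None, :, :] - bundle_px[i0:i1, None, None]
            f[:, r0:r1, c0:c1] += (
                scene.ridge_amplitude
                * np.exp(-(shift**2) / (2.0 * scene.ridge_sigma_px**2))
            ).astype(np.float32)
        # shot noise (Gaussian above _POISSON_GAUSS_MIN counts, exact Poisson
        # below) and read noise share one Gaussian draw where both apply
        if camera.shot_noise:
            lam = np.clip(f, 0.0, None)
            var = lam / camera.gain + read_var
            noisy = f + rng.standard_normal(f.shape, dtype=np.float32) * np.sqrt(var)
            small = lam <= _POISSON_GAUSS_MIN
            if small.any():
                poisson = rng.poisson(lam[small].astype(np.float64) * camera.gain)
                noisy[small] = poisson / camera.gain
                if camera.read_noise_sd > 0:
                    noisy[small] += rng.normal(
                        0.0, camera.read_noise_sd, int(small.sum())
                    )
            f = noisy
        elif camera.read_noise_sd > 0:
            f = f + rng.standard_normal(f.shape, dtype=np.float32) * camera.read_noise_sd
        np.clip(np.rint(f), 0, camera.max_count, out=f)
        out[i0:i1] = f.astype(camera.dtype)
    return ImageStack(
        frames=out,
        frame_rate=camera.frame_rate,
        pixel_pitch=camera.pixel_pitch,
        z_index=z_index,
        source=f"synthetic:z{z_index}",
    )


# --------------------------------------------------------------------------
# datasets

CONDITIONS = ("control", "bapta", "salicylate")


def make_dataset(
    scene: SceneSpec,
    bundle_model: BundleModel,
    protocol: StimulusProtocol,
    camera: CameraModel,
    condition: str = "control",
    seed: int = 0,
    z_indices: Optional[Sequence[int]] = None,
):
    """Generate a full annotated dataset for one pharmacological condition.

    ``control`` and ``salicylate`` are dynamically identical (salicylate
    blocks prestin, which plays no role in these fluctuations); ``bapta``
    severs the tip links, zeroing all hotspot modulation and disabling
    entrainment of the bundle by any stimulus.  Conditions sharing a
    master seed are paired: they reuse the same bundle, hotspot and camera
    noise streams.  Returns ``(stacks, truth, manifest)`` where ``stacks``
    maps z-index to :class:`ImageStack`.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    fs = camera.frame_rate
    n = protocol_sample_count(protocol, fs)
    cam = dataclasses.replace(camera, frame_count=n)

    hotspots = list(scene.hotspots)
    if condition == "bapta":
        hotspots = [dataclasses.replace(hs, suppression_factor=0.0) for hs in hotspots]
    scene_c = dataclasses.replace(scene, hotspots=hotspots, seed=seed)

    bundle = simulate_bundle(
        bundle_model, protocol, cam, seed=seed, entrain=condition != "bapta"
    )
    stim = stimulus_trace(protocol, fs, n)
    mods = [
        Trace(
            _hotspot_modulation(
                bundle.values, hs, scene_c.z_attenuation, fs, _rng(seed, _STREAM_HOTSPOT, i)
            ),
            fs,
            kind="delta_i_over_i",
        )
        for i, hs in enumerate(hotspots)
    ]
    if protocol.kind == "sweep":
        boundaries = [0, *np.cumsum(sweep_segment_lengths(protocol, fs)).tolist()]
    else:
        boundaries = []
    truth = GroundTruth(
        bundle_trace=bundle,
        hotspot_modulations=mods,
        stimulus_trace=stim,
        step_boundaries=boundaries,
    )
    if z_indices is None:
        z_indices = range(scene_c.n_z)
    stacks = {int(z): render_stack(scene_c, truth, cam, z_index=int(z)) for z in z_indices}
    manifest = {
        "condition": condition,
        "seed": int(seed),
        "camera": dataclasses.asdict(cam),
        "bundle_model": dataclasses.asdict(bundle_model),
        "protocol": dataclasses.asdict(protocol),
        "scene": {
            **{
                k: v
                for k, v in dataclasses.asdict(scene_c).items()
                if k not in ("soma_outline", "hotspots")
            },
            "soma_outline": None
            if scene_c.soma_outline is None
            else scene_c.soma_outline.tolist(),
            "hotspots": [dataclasses.asdict(hs) for hs in hotspots],
        },
        "z_indices": [int(z) for z in z_indices],
    }
    return stacks, truth, manifest


def save_dataset(stacks, truth: GroundTruth, manifest: dict, out_dir) -> None:
    """Write a dataset to disk: one TIFF per z, truth CSVs, JSON manifest."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for z, stack in stacks.items():
        write_stack(stack, out / f"stack_z{z}.tif")
    write_trace(truth.bundle_trace, out / "bundle_truth.csv")
    write_trace(truth.stimulus_trace, out / "stimulus.csv")
    for i, mod in enumerate(truth.hotspot_modulations):
        write_trace(mod, out / f"hotspot_{i}_modulation.csv")
    manifest = dict(manifest, step_boundaries=truth.step_boundaries)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# --------------------------------------------------------------------------
# canonical scene and configuration loading


def example_scene(
    image_shape: tuple[int, int] = (128, 128),
    n_hotspots: int = 2,
    hotspot_z: int = 0,
    hotspot_lag: float = 0.0,
    gain: float = 0.004,
    suppression: float = 1.0,
    radius_px: float = 4.0,
    intrinsic_noise_sd: float = 0.0,
    seed: int = 0,
) -> SceneSpec:
    """A canonical single-cell scene: soma, bundle ridge, peripheral hotspots.

    Geometry scales with ``image_shape``: the soma is a circle in the
    lower two-thirds of the frame, the bundle ridge sits above it, and
    hotspots lie near the soma periphery toward the basal pole — the
    arrangement the activity maps of real recordings show.
    """
    h, w = image_shape
    theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    soma_center = (0.61 * h, 0.50 * w)
    soma_radius = 0.30 * min(h, w)
    outline = np.column_stack(
        [
            soma_center[0] + soma_radius * np.sin(theta),
            soma_center[1] + soma_radius * np.cos(theta),
        ]
    )
    positions = [(0.78 * h, 0.31 * w), (0.75 * h, 0.69 * w), (0.68 * h, 0.50 * w)]
    if n_hotspots > len(positions):
        raise ValueError(f"example scene supports at most {len(positions)} hotspots")
    hotspots = [
        HotspotSpec(
            center=positions[i],
            radius_px=radius_px,
            z_index=hotspot_z,
            gain=gain,
            lag=hotspot_lag,
            intrinsic_noise_sd=intrinsic_noise_sd,
            suppression_factor=suppression,
        )
        for i in range(n_hotspots)
    ]
    return SceneSpec(
        image_shape=image_shape,
        soma_outline=outline,
        bundle_roi=(int(0.06 * h), int(0.34 * w), int(0.22 * h), int(0.66 * w)),
        bundle_axis=(0.0, 1.0),
        hotspots=hotspots,
        seed=seed,
    )


def background_roi(scene: SceneSpec, radius: float = 5.0) -> Roi:
    """A background disk outside both the soma and the bundle region."""
    h, w = scene.image_shape
    return Roi(center=(0.16 * h, 0.09 * w), radius=radius, label="background")


def control_roi(scene: SceneSpec, radius: float = 5.0) -> Roi:
    """A control disk outside the cell (should show no activity)."""
    h, w = scene.image_shape
    return Roi(center=(0.31 * h, 0.86 * w), radius=radius, label="control")


def soma_analysis_mask(scene: SceneSpec) -> np.ndarray:
    """Analysis mask for hotspot detection: everything but the bundle region.

    The moving bundle ridge produces the strongest σ signal by far; like
    the hand-drawn cell outlines of a real analysis, the hotspot search
    excludes it (with a 2 px guard band) and keeps the rest of the frame.
    """
    mask = np.ones(scene.image_shape, dtype=bool)
    if scene.bundle_roi is not None:
        r0, c0, r1, c1 = scene.bundle_roi
        g = 2
        mask[max(0, r0 - g) : r1 + g, max(0, c0 - g) : c1 + g] = False
    return mask


def bundle_tracker_roi(scene: SceneSpec) -> Roi:
    """A tracking disk hugging the bundle ridge inside the bundle region."""
    if scene.bundle_roi is None:
        raise ValueError("scene has no bundle region")
    r0, c0, r1, c1 = scene.bundle_roi
    center = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)
    radius = (r1 - r0) / 2.0 + 2.0
    return Roi(center=center, radius=radius, label="bundle")


def _build(cls, data: dict):
    if data is None:
        return cls()
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> tuple[SceneSpec, BundleModel, StimulusProtocol, CameraModel]:
    """Load a YAML simulation config into the four model objects.

    Top-level keys: ``scene``, ``bundle``, ``protocol``, ``camera`` — each
    a mapping of the corresponding dataclass fields.  ``scene.hotspots``
    is a list of hotspot mappings.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    scene_cfg = dict(cfg.get("scene") or {})
    if "hotspots" in scene_cfg:
        scene_cfg["hotspots"] = [
            _build(HotspotSpec, {**hs, "center": tuple(hs["center"])})
            for hs in scene_cfg["hotspots"]
        ]
    for key in ("image_shape", "bundle_roi", "bundle_axis", "center"):
        if key in scene_cfg and scene_cfg[key] is not None:
            scene_cfg[key] = tuple(scene_cfg[key])
    scene = _build(SceneSpec, scene_cfg)
    bundle = _build(BundleModel, cfg.get("bundle"))
    protocol = _build(StimulusProtocol, cfg.get("protocol"))
    camera = _build(CameraModel, cfg.get("camera"))
    return scene, bundle, protocol, camera
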