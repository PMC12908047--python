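"""Image-stack and trace containers with TIFF/CSV readers and writers.

High-speed recordings are multi-page grayscale TIFF stacks (one file per
axial section).  Acquisition metadata (frame rate in Hz, pixel pitch in
nm/px, z index) is stored as a JSON dictionary in the ImageDescription tag
of the first page; ImageJ-style ``finterval`` metadata is also understood
on read.  Traces are plain CSV with a single comment header line carrying
the sampling metadata.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "Trace",
    "TRACE_KINDS",
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
]

TRACE_KINDS = ("displacement_nm", "delta_i_over_i", "stimulus_nm")

_DESCRIPTION_KEY = "flickermap"


@dataclasses.dataclass
class ImageStack:
    """Time-ordered sequence of 2-D intensity frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)`` holding raw camera counts.
        Frame index 0 is the first acquired frame.
    frame_rate
        Acquisition rate in frames per second.
    pixel_pitch
        Physical size of one pixel in nm.
    z_index
        Index of the axial section this stack was recorded at, if any.
    source
        Free-form provenance string (file path or simulator tag).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    z_index: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (frame, row, col); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if np.issubdtype(self.frames.dtype, np.integer) and self.frames.min() < 0:
            raise ValueError("intensity counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclasses.dataclass
class Trace:
    """Uniformly sampled 1-D time series.

    ``kind`` declares the physical quantity: bundle displacement in nm,
    normalized intensity fluctuation ΔI/I (dimensionless), or the stimulus
    command in nm.
    """

    values: np.ndarray
    sample_rate: float
    kind: str = "displacement_nm"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}; expected one of {TRACE_KINDS}")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate


def _metadata_from_tiff(tf: tifffile.TiffFile) -> dict:
    meta: dict = {}
    desc = tf.pages[0].description or ""
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict) and parsed.get("format") == _DESCRIPTION_KEY:
                meta.update(parsed)
        except (json.JSONDecodeError, UnicodeDecodeError):
            pass
    ij = tf.imagej_metadata
    if ij and "finterval" in ij and ij["finterval"]:
        meta.setdefault("frame_rate", 1.0 / float(ij["finterval"]))
    return meta


def read_stack(
    path: os.PathLike | str,
    frame_rate: Optional[float] = None,
    pixel_pitch: Optional[float] = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Metadata found in the file takes precedence over the ``frame_rate`` /
    ``pixel_pitch`` arguments, which serve as fallbacks for files written
    by other software.  Raises ``ValueError`` for color files, pages of
    mixed shapes, or when no frame rate is available from either source.
    """
    with tifffile.TiffFile(path) as tf:
        page0 = tf.pages[0]
        photometric = page0.photometric
        if photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK,
            tifffile.PHOTOMETRIC.MINISWHITE,
        ):
            raise ValueError(
                f"expected a grayscale stack; page photometric interpretation is "
                f"{photometric.name}"
            )
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"pages have mixed shapes: {sorted(shapes)}")
        frames = tf.asarray()
        meta = _metadata_from_tiff(tf)

    if frames.ndim == 2:
        raise ValueError("file holds a single frame; an image stack needs at least 2")
    if frames.ndim != 3:
        raise ValueError(f"expected a (frame, row, col) stack; got shape {frames.shape}")

    rate = meta.get("frame_rate", frame_rate)
    if rate is None:
        raise ValueError(
            "frame_rate is neither stored in the file nor supplied as an argument"
        )
    pitch = meta.get("pixel_pitch_nm", pixel_pitch)
    if pitch is None:
        raise ValueError(
            "pixel_pitch is neither stored in the file nor supplied as an argument"
        )
    z_index = meta.get("z_index")
    return ImageStack(
        frames=frames,
        frame_rate=float(rate),
        pixel_pitch=float(pitch),
        z_index=None if z_index is None else int(z_index),
        source=str(path),
    )


def write_stack(stack: ImageStack, path: os.PathLike | str) -> str:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF.

    Counts are stored losslessly as unsigned integers; acquisition metadata
    goes into the ImageDescription tag so a later :func:`read_stack`
    round-trips bit-identically.
    """
    frames = stack.frames
    if frames.dtype not in (np.uint8, np.uint16):
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValueError("only integer count stacks can be written losslessly")
        if frames.min() < 0 or frames.max() > np.iinfo(np.uint16).max:
            raise ValueError("counts out of range for 16-bit output")
        frames = frames.astype(np.uint16)
    meta = {
        "format": _DESCRIPTION_KEY,
        "frame_rate": stack.frame_rate,
        "pixel_pitch_nm": stack.pixel_pitch,
        "z_index": stack.z_index,
    }
    tifffile.imwrite(
        path,
        frames,
        photometric="minisblack",
        description=json.dumps(meta),
        metadata=None,
    )
    return str(path)


def write_trace(trace: Trace, path: os.PathLike | str) -> str:
    """Write a trace as CSV: one comment header line plus (time_s, value) rows.

    Values are written with 12 significant digits.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# flickermap-trace kind={trace.kind} "
            f"sample_rate={trace.sample_rate:.12g} t0={trace.t0:.12g}\n"
        )
        fh.write("time_s,value\n")
        for t, v in zip(trace.times(), trace.values):
            fh.write(f"{t:.12g},{v:.12g}\n")
    return str(path)


def read_trace(path: os.PathLike | str) -> Trace:
    """Read a trace CSV written by :func:`write_trace`.

    The time column must be uniform to within 1e-6 of the sample interval.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# flickermap-trace"):
            raise ValueError(f"{path}: not a flickermap trace CSV (bad header line)")
        fields = dict(
            item.split("=", 1) for item in header.split()[2:] if "=" in item
        )
        try:
            kind = fields["kind"]
            sample_rate = float(fields["sample_rate"])
            t0 = float(fields.get("t0", "0"))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed trace header: {header!r}") from exc
        column_line = fh.readline().strip()
        if column_line.replace(" ", "") != "time_s,value":
            raise ValueError(f"{path}: expected 'time_s,value' column header")
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed CSV body") from exc
    if data.size == 0:
        raise ValueError(f"{path}: empty trace")
    times, values = data[:, 0], data[:, 1]
    dt = 1.0 / sample_rate
    if times.size > 1:
        if np.max(np.abs(np.diff(times) - dt)) > 1e-6 * dt:
            raise ValueError(f"{path}: time column is not uniform at 1/sample_rate")
    return Trace(values=values, sample_rate=sample_rate, kind=kind, t0=t0)
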