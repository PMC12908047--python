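"""Phase-locked response quantification for swept and pure-tone stimuli.

A stepped frequency sweep holds each frequency f_i for an integer number
of cycles.  The phase-locked response at step i is the amplitude of the
trace's frequency component at exactly f_i, computed per segment by a
single-frequency discrete Fourier projection of the mean-subtracted
segment:

    response_i = 2 |Σ_t x_t exp(−i 2π f_i t / fs)| / M_i

which coincides with the FFT-bin amplitude when the segment holds an
integer number of cycles, and degrades gracefully when rounding makes the
cycle count slightly non-integer.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Trace
from .synthetic import StimulusProtocol, sweep_frequencies, sweep_segment_lengths

__all__ = [
    "SweepSegmentation",
    "PhaseLockCurve",
    "segment_sweep",
    "phase_locked_response",
    "compare_curves",
    "aggregate_curves",
]

_MIN_SEGMENT = 16


@dataclasses.dataclass
class SweepSegmentation:
    """Partition of a sweep recording into per-frequency segments.

    ``boundaries`` has ``n_steps + 1`` entries, starting at 0; segment i
    spans samples ``[boundaries[i], boundaries[i+1])`` (closed-open, so
    the first sample of each step belongs to that step).
    """

    boundaries: np.ndarray
    frequencies: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.boundaries.size != self.frequencies.size + 1:
            raise ValueError("need one more boundary than frequencies")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return int(self.frequencies.size)

    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)


@dataclasses.dataclass
class PhaseLockCurve:
    """Per-frequency phase-locked response amplitudes of one sweep."""

    frequencies: np.ndarray
    response: np.ndarray
    amplitude_label: Optional[float] = None  # stimulus amplitude in nm
    dispersion: Optional[tuple[np.ndarray, np.ndarray]] = None  # (lo, hi)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.frequencies.shape != self.response.shape:
            raise ValueError("frequencies and response must align")
        if np.any(self.response < 0):
            raise ValueError("response amplitudes must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"frequency_hz": self.frequencies, "response": self.response}
        )
        df["amplitude_nm_label"] = self.amplitude_label
        return df


def segment_sweep(protocol: StimulusProtocol, sample_rate: float) -> SweepSegmentation:
    """Segment boundaries of a stepped sweep at a given sample rate.

    Segment i holds ``round(cycles_per_step × fs / f_i)`` samples; any
    segment shorter than 16 samples is rejected as too short for a
    meaningful projection.
    """
    if protocol.kind != "sweep":
        raise ValueError("segment_sweep requires a sweep protocol")
    freqs = sweep_frequencies(protocol)
    lengths = sweep_segment_lengths(protocol, sample_rate)
    if np.any(lengths < _MIN_SEGMENT):
        bad = freqs[lengths < _MIN_SEGMENT]
        raise ValueError(
            f"segments shorter than {_MIN_SEGMENT} samples at frequencies {bad}"
        )
    boundaries = np.concatenate(([0], np.cumsum(lengths)))
    return SweepSegmentation(
        boundaries=boundaries, frequencies=freqs, sample_rate=sample_rate
    )


def single_frequency_amplitude(values: np.ndarray, freq: float, sample_rate: float) -> float:
    """Amplitude of one frequency component of a mean-subtracted segment."""
    x = values - values.mean()
    m = x.size
    t = np.arange(m)
    phasor = np.exp(-2j * np.pi * freq * t / sample_rate)
    return float(2.0 * np.abs(np.dot(x, phasor)) / m)


def phase_locked_response(
    trace: Trace,
    seg: SweepSegmentation,
    amplitude_label: Optional[float] = None,
) -> PhaseLockCurve:
    """Phase-locked response of a trace over a segmented sweep.

    Each segment is mean-subtracted and projected onto its own stimulus
    frequency.  The trace must cover every segment and share the
    segmentation's sample rate.
    """
    if trace.sample_rate != seg.sample_rate:
        raise ValueError("trace and segmentation sample rates differ")
    if trace.n < seg.boundaries[-1]:
        raise ValueError(
            f"trace has {trace.n} samples but the sweep needs {seg.boundaries[-1]}"
        )
    response = np.array(
        [
            single_frequency_amplitude(
                trace.values[b0:b1], f, seg.sample_rate
            )
            for b0, b1, f in zip(seg.boundaries[:-1], seg.boundaries[1:], seg.frequencies)
        ]
    )
    return PhaseLockCurve(
        frequencies=seg.frequencies.copy(),
        response=response,
        amplitude_label=amplitude_label,
    )


def compare_curves(
    curve_a: PhaseLockCurve, curve_b: PhaseLockCurve
) -> tuple[pd.DataFrame, float]:
    """Per-frequency response ratios b/a and their median.

    Frequencies where ``a`` is zero get a NaN ratio (flagged in the
    ``undefined`` column) and are excluded from the median.  The two
    curves must share one frequency grid.
    """
    if curve_a.frequencies.shape != curve_b.frequencies.shape or not np.allclose(
        curve_a.frequencies, curve_b.frequencies
    ):
        raise ValueError("curves are on different frequency grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            curve_a.response == 0, np.nan, curve_b.response / curve_a.response
        )
    table = pd.DataFrame(
        {
            "frequency_hz": curve_a.frequencies,
            "response_a": curve_a.response,
            "response_b": curve_b.response,
            "ratio": ratio,
            "undefined": curve_a.response == 0,
        }
    )
    finite = ratio[np.isfinite(ratio)]
    summary = float(np.median(finite)) if finite.size else float("nan")
    return table, summary


def aggregate_curves(curves: Sequence[PhaseLockCurve]) -> PhaseLockCurve:
    """Mean curve across repeat sweeps with a min–max dispersion envelope."""
    if not curves:
        raise ValueError("need at least one curve")
    freqs = curves[0].frequencies
    for c in curves[1:]:
        if c.frequencies.shape != freqs.shape or not np.allclose(c.frequencies, freqs):
            raise ValueError("curves are on different frequency grids")
    stackd = np.vstack([c.response for c in curves])
    dispersion = None
    if len(curves) > 1:
        dispersion = (stackd.min(axis=0), stackd.max(axis=0))
    return PhaseLockCurve(
        frequencies=freqs.copy(),
        response=stackd.mean(axis=0),
        amplitude_label=curves[0].amplitude_label,
        dispersion=dispersion,
    )
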