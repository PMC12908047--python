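"""Amplitude spectra, peak statistics, and maximum lagged Pearson correlation.

The spectral convention used throughout: after mean removal, the one-sided
amplitude spectrum is scaled so a pure sinusoid of amplitude A landing
exactly on a frequency bin reports amplitude A at that bin.  Pairwise
similarity between a bundle trace and a hotspot trace is scored by the
maximal Pearson coefficient over all integer time shifts within a lag
window, each overlap re-centered and re-scaled; a conservative threshold
of 0.2 (about 4 SDs above a noise-pair null) classifies a pair as
correlated.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io import Trace

__all__ = [
    "Spectrum",
    "CorrelationResult",
    "normalized_spectrum",
    "peak_metrics",
    "peak_amplitude_change",
    "max_shift_correlation",
    "classify_correlated",
    "CORRELATION_THRESHOLD",
]

#: Conservative correlated/uncorrelated boundary (inclusive), ≈4 null SDs.
CORRELATION_THRESHOLD = 0.2


@dataclasses.dataclass
class Spectrum:
    """One-sided amplitude spectrum from 0 to the Nyquist frequency."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    normalization: str = "none"  # {"none", "max"}

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.amplitudes.shape:
            raise ValueError("frequencies and amplitudes must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclasses.dataclass
class CorrelationResult:
    """Outcome of a maximum-shift correlation scan."""

    max_corr: float
    lag: int
    threshold: float = CORRELATION_THRESHOLD
    correlated: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.max_corr <= 1.0 + 1e-12:
            raise ValueError("Pearson coefficient out of [-1, 1]")


def normalized_spectrum(
    trace: Trace, window: str = "none", normalization: str = "none"
) -> Spectrum:
    """Amplitude spectrum of a mean-subtracted trace.

    Parameters
    ----------
    window
        ``"none"`` or ``"hann"``.  Windowed spectra are rescaled by the
        window's coherent gain so on-bin sinusoid amplitudes stay correct.
    normalization
        ``"none"`` keeps input units; ``"max"`` divides by the spectral
        peak (the convention used for comparing bundle and hotspot
        spectra), so the peak is exactly 1.
    """
    x = trace.values
    m = x.size
    if m < 16:
        raise ValueError("trace too short for a spectrum (need >= 16 samples)")
    x = x - x.mean()
    if window == "hann":
        w = np.hanning(m)
    elif window == "none":
        w = np.ones(m)
    else:
        raise ValueError(f"unknown window {window!r}")
    spectrum = np.fft.rfft(x * w)
    amplitudes = 2.0 * np.abs(spectrum) / w.sum()
    amplitudes[0] /= 2.0
    if m % 2 == 0:
        amplitudes[-1] /= 2.0
    frequencies = np.fft.rfftfreq(m, d=1.0 / trace.sample_rate)
    if normalization == "max":
        peak = amplitudes.max()
        if peak == 0:
            raise ValueError("cannot max-normalize an all-zero spectrum")
        amplitudes = amplitudes / peak
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return Spectrum(frequencies=frequencies, amplitudes=amplitudes, normalization=normalization)


def peak_metrics(
    spec: Spectrum, band: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    """Frequency and amplitude of the spectral maximum within a band.

    Ties are broken toward the lower frequency.  ``band`` bounds are
    inclusive; omitting it scans the full spectrum.
    """
    if band is None:
        sel = np.ones(spec.frequencies.size, dtype=bool)
    else:
        f_lo, f_hi = band
        sel = (spec.frequencies >= f_lo) & (spec.frequencies <= f_hi)
    if not sel.any():
        raise ValueError("band contains no spectral bins")
    freqs = spec.frequencies[sel]
    amps = spec.amplitudes[sel]
    idx = int(np.argmax(amps))  # argmax returns the first (lowest-f) maximum
    return float(freqs[idx]), float(amps[idx])


def peak_amplitude_change(control_amp: float, treated_amp: float) -> float:
    """Percent change of a spectral peak amplitude from control to treated.

    Returns ``100 × (treated − control) / control``; e.g. a drop to 35% of
    the control amplitude reports −65.0.
    """
    if not control_amp > 0:
        raise ValueError("control amplitude must be positive")
    return 100.0 * (treated_amp - control_amp) / control_amp


def _pearson_by_lag(
    a: np.ndarray, b: np.ndarray, lags: np.ndarray, min_overlap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson coefficient of a[t] vs b[t + lag] for each lag, via prefix sums.

    Returns (r, valid); invalid lags (short overlap or zero variance) get
    r = nan.  The raw lagged inner products come from a full
    cross-correlation; means and variances of each overlap come from
    cumulative sums, so the whole scan is O(n log n).
    """
    n_a, n_b = a.size, b.size
    # cross[l] = sum_t a[t] * b[t + l]
    cc = sps.correlate(b, a, mode="full", method="auto")
    # cc index: cc[k] = sum_m b[m] a[m - (k - (n_b - 1))] ... use explicit offset:
    # scipy.signal.correlate(b, a)[k] = sum_m b[m + k - (n_a - 1)] a[m]; so
    # cross[l] = cc[l + n_a - 1].
    ca = np.concatenate(([0.0], np.cumsum(a)))
    ca2 = np.concatenate(([0.0], np.cumsum(a * a)))
    cb = np.concatenate(([0.0], np.cumsum(b)))
    cb2 = np.concatenate(([0.0], np.cumsum(b * b)))

    i0 = np.maximum(0, -lags)
    i1 = np.minimum(n_a, n_b - lags)
    m = np.maximum(0, i1 - i0)
    valid = m >= max(min_overlap, 2)

    r = np.full(lags.size, np.nan)
    if not valid.any():
        return r, valid
    vl = np.nonzero(valid)[0]
    lo_a, hi_a = i0[vl], i1[vl]
    lo_b, hi_b = lo_a + lags[vl], hi_a + lags[vl]
    mm = m[vl].astype(float)
    sa = ca[hi_a] - ca[lo_a]
    sa2 = ca2[hi_a] - ca2[lo_a]
    sb = cb[hi_b] - cb[lo_b]
    sb2 = cb2[hi_b] - cb2[lo_b]
    cross = cc[lags[vl] + n_a - 1]
    num = cross - sa * sb / mm
    var_a = sa2 - sa * sa / mm
    var_b = sb2 - sb * sb / mm
    denom2 = np.clip(var_a, 0.0, None) * np.clip(var_b, 0.0, None)
    scale_a = np.max(np.abs(a)) if n_a else 0.0
    scale_b = np.max(np.abs(b)) if n_b else 0.0
    tiny = max((1e-12 * scale_a * scale_b) ** 2, np.finfo(float).tiny)
    ok = denom2 > tiny * mm * mm
    rr = np.full(vl.size, np.nan)
    rr[ok] = np.clip(num[ok] / np.sqrt(denom2[ok]), -1.0, 1.0)
    r[vl] = rr
    valid = valid & np.isfinite(r)
    return r, valid


def max_shift_correlation(
    a: Trace,
    b: Trace,
    max_lag: Optional[int] = None,
    min_overlap_frac: float = 0.5,
    threshold: float = CORRELATION_THRESHOLD,
    absolute: bool = False,
) -> CorrelationResult:
    """Maximal Pearson correlation of two traces over integer time shifts.

    For each lag ℓ in ``[-max_lag, +max_lag]``, ``a[t]`` is compared with
    ``b[t + ℓ]`` over their overlap, each segment re-centered and
    re-scaled.  A positive lag therefore means ``b`` trails ``a`` by ℓ
    samples.  The default lag window is ``min(n // 2, 500)`` samples; lags
    whose overlap is shorter than ``min_overlap_frac`` of the shorter
    trace, or has zero variance, are skipped.  Ties are broken by the
    smallest ``|lag|``, then by the negative lag.  With ``absolute`` the
    scan maximizes ``|r|`` while still reporting the signed coefficient.
    """
    if a.sample_rate != b.sample_rate:
        raise ValueError("traces must share one sample rate")
    n_a, n_b = a.n, b.n
    n_min = min(n_a, n_b)
    if n_min < 32:
        raise ValueError("traces too short for a correlation scan (need >= 32)")
    if max_lag is None:
        max_lag = min(n_min // 2, 500)
    if max_lag < 0:
        raise ValueError("max_lag must be non-negative")
    lags = np.arange(-max_lag, max_lag + 1)
    min_overlap = int(np.ceil(min_overlap_frac * n_min))
    r, valid = _pearson_by_lag(a.values, b.values, lags, min_overlap)
    if not valid.any():
        raise ValueError("no lag yields a long enough overlap with nonzero variance")
    score = np.abs(r) if absolute else r
    best = np.nanmax(np.where(valid, score, -np.inf))
    candidates = np.nonzero(valid & (score == best))[0]
    pick = min(candidates, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    max_corr = float(r[pick])
    return CorrelationResult(
        max_corr=max_corr,
        lag=int(lags[pick]),
        threshold=threshold,
        correlated=bool(max_corr >= threshold),
    )


def classify_correlated(
    result: CorrelationResult, threshold: float = CORRELATION_THRESHOLD
) -> bool:
    """True iff the maximal correlation reaches the threshold (inclusive)."""
    return bool(result.max_corr >= threshold)
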