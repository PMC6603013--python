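"""One-dimensional assignment toolkit: second-derivative spectra, difference
spectra, peak detection and band-intensity extraction.

Second-derivative spectroscopy sharpens overlapped NIR bands: an absorption
maximum of :math:`A(\\lambda)` appears as a sharp local minimum of
:math:`d^2A/d\\lambda^2`, so bands whose raw sum shows a single maximum can
still be counted and located.  Difference spectra (pointwise subtraction of a
reference compound) isolate substituent-induced bands directly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Literal, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectra import GridMismatchError, Spectrum

__all__ = [
    "Peak",
    "second_derivative",
    "difference_spectrum",
    "detect_peaks",
    "band_intensity",
    "normalize_by_concentration",
    "write_peaks_csv",
]

PeakMode = Literal["raw_maxima", "second_derivative_minima"]


@dataclass(frozen=True)
class Peak:
    """A located absorption band.

    ``position_nm`` is parabolic-refined (sub-grid); ``intensity`` is the raw
    absorbance at that position (signed trace value for diagonal autopeaks);
    ``prominence`` is measured on the trace that was searched.
    """

    position_nm: float
    intensity: float
    prominence: float
    source: str = "raw_maximum"

    def __post_init__(self) -> None:
        if self.prominence < 0:
            raise ValueError("prominence must be >= 0")


def _require_uniform(spectrum: Spectrum) -> float:
    if not spectrum.is_uniform():
        raise ValueError("spectrum grid is not uniform; resample() it first")
    return float(spectrum.wavelengths_nm[1] - spectrum.wavelengths_nm[0])


def second_derivative(spectrum: Spectrum, window_points: int = 21,
                      polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavelength.

    Exact on polynomials up to ``polyorder``; the output shares the input
    grid.  The half-window at each end is edge-fitted by the filter and is
    excluded from peak reporting by :func:`detect_peaks`.
    """
    step = _require_uniform(spectrum)
    if window_points % 2 == 0 or window_points <= polyorder or polyorder < 2:
        raise ValueError("window_points must be odd and > polyorder >= 2")
    if window_points > len(spectrum):
        raise ValueError("window larger than spectrum")
    d2 = savgol_filter(spectrum.absorbance, window_points, polyorder,
                       deriv=2, delta=step, mode="interp")
    return spectrum.with_absorbance(d2)


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise ``a - b`` on identical grids.

    Positive lobes mark bands the first compound has and the reference lacks
    (e.g. the 2330 nm methyl combination band of a methylbenzene against
    benzene); negative lobes mark weakened reference bands.
    """
    if not np.array_equal(a.wavelengths_nm, b.wavelengths_nm):
        raise GridMismatchError("difference_spectrum requires identical grids")
    return Spectrum(a.wavelengths_nm, a.absorbance - b.absorbance,
                    compound_id=f"{a.compound_id} - {b.compound_id}")


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (x[i-1..i+1], y[i-1..i+1])."""
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = x[i + 1] - x[i]
    return float(x[i] + np.clip(shift, -1.0, 1.0) * step)


def _mad_threshold(trace: np.ndarray) -> float:
    """Default prominence: 3x the median absolute deviation plus a small
    fraction of the trace range, so noise-free traces do not report the
    numerical ripple between bands."""
    med = np.median(trace)
    mad = float(np.median(np.abs(trace - med)))
    return 3.0 * mad + 1e-4 * float(np.ptp(trace))


def detect_peaks(spectrum: Spectrum,
                 mode: PeakMode = "raw_maxima",
                 min_prominence: float | None = None,
                 window_points: int = 21,
                 polyorder: int = 3) -> list[Peak]:
    """Locate absorption bands as raw maxima or second-derivative minima.

    In ``second_derivative_minima`` mode the search runs on the negated
    second derivative (so absorption bands are maxima of the searched trace),
    the half-window edge regions are excluded, and the reported intensity is
    the raw absorbance interpolated at the refined position.  The default
    prominence threshold is 3x the median absolute deviation of the searched
    trace; pass 0 for noise-free data.  Peaks are returned sorted by
    position; plateau ties resolve to the lower wavelength.
    """
    if min_prominence is not None and min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    wl = spectrum.wavelengths_nm
    if mode == "raw_maxima":
        trace = spectrum.absorbance
        lo, hi = 0, len(trace)
        source = "raw_maximum"
    elif mode == "second_derivative_minima":
        d2 = second_derivative(spectrum, window_points, polyorder)
        trace = -d2.absorbance
        half = window_points // 2
        lo, hi = half, len(trace) - half
        source = "second_derivative_minimum"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    thr = _mad_threshold(trace) if min_prominence is None else float(min_prominence)
    # in derivative mode require genuinely negative curvature at the peak:
    # flat stretches between band sidelobes are prominent but have ~zero height
    height = thr if (source == "second_derivative_minimum" and thr > 0) else None
    idx, props = find_peaks(trace, prominence=thr, height=height,
                            plateau_size=(1, None))
    # plateau ties: report the lower-wavelength edge
    idx = np.where(props.get("left_edges", idx) < idx,
                   props.get("left_edges", idx), idx)
    keep = (idx >= lo) & (idx < hi)
    idx = idx[keep]
    proms = props["prominences"][keep] if "prominences" in props else np.zeros(idx.size)
    peaks = []
    for i, p in zip(idx, proms):
        pos = _parabolic_refine(wl, trace, int(i))
        intensity = float(np.interp(pos, wl, spectrum.absorbance))
        peaks.append(Peak(pos, intensity, float(p), source))
    peaks.sort(key=lambda pk: pk.position_nm)
    return peaks


def band_intensity(spectrum: Spectrum, center_nm: float) -> float:
    """Absorbance at a band centre (linear interpolation between neighbours)."""
    return spectrum.value_at(center_nm)


def normalize_by_concentration(spectrum: Spectrum) -> Spectrum:
    """Scale absorbance to unit concentration (per-mole comparison)."""
    c = spectrum.concentration
    if c is None or c == 0:
        raise ValueError("concentration metadata missing or zero")
    return Spectrum(spectrum.wavelengths_nm, spectrum.absorbance / c,
                    compound_id=spectrum.compound_id,
                    concentration=1.0,
                    concentration_unit=f"per {spectrum.concentration_unit}")


def write_peaks_csv(peaks: Sequence[Peak], sink: str | Path | IO[str]) -> None:
    """Export peaks as CSV (position_nm, intensity, prominence, source)."""
    close = False
    if isinstance(sink, (str, Path)):
        sink = open(sink, "w", encoding="utf-8", newline="")
        close = True
    try:
        writer = csv.writer(sink)
        writer.writerow(["position_nm", "intensity", "prominence", "source"])
        for p in peaks:
            writer.writerow([repr(p.position_nm), repr(p.intensity),
                             repr(p.prominence), p.source])
    finally:
        if close:
            sink.close()
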