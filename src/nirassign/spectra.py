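"""Containers and I/O for near-infrared absorbance spectra.

A :class:`Spectrum` holds one compound's absorbance trace :math:`A(\\lambda)`
on a strictly increasing wavelength grid in nanometres; a
:class:`SpectrumSet` stacks several spectra sharing one grid, ordered by a
perturbation variable (here: concentration), which is the input to 2D
correlation spectroscopy.  All public APIs work in nm; conversion to vacuum
wavenumber uses :math:`\\tilde\\nu\\,[\\mathrm{cm}^{-1}] = 10^7/\\lambda\\,[\\mathrm{nm}]`.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "IntensityTable",
    "GridMismatchError",
    "SpectrumParseError",
    "default_grid",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_series_dir",
    "resample",
    "average_replicates",
    "load_intensity_table",
    "TABLE1_WAVELENGTHS",
]

#: Wavelength columns of the packaged methylbenzene intensity table (nm).
TABLE1_WAVELENGTHS = (1670, 2130, 2330, 2460)

CSV_HEADER = "wavelength_nm,absorbance"


class GridMismatchError(ValueError):
    """Raised when an operation requires identical wavelength grids."""


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


def nm_to_wavenumber(nm):
    """Vacuum wavelength (nm) to wavenumber (cm^-1)."""
    return 1e7 / np.asarray(nm, dtype=float)


def wavenumber_to_nm(wavenumber_cm):
    """Wavenumber (cm^-1) to vacuum wavelength (nm)."""
    return 1e7 / np.asarray(wavenumber_cm, dtype=float)


def default_grid(start_nm: float = 400.0, stop_nm: float = 2500.0,
                 step_nm: float = 0.5) -> np.ndarray:
    """Instrument acquisition grid: 400-2500 nm at 0.5 nm (4201 points)."""
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths, nm.
    absorbance
        Absorbance values (dimensionless AU), same length.
    compound_id
        Free-text compound label.
    concentration
        Optional concentration metadata, >= 0; unit in ``concentration_unit``
        (``mol/L`` or ``volume_fraction``).
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    compound_id: str = ""
    concentration: float | None = None
    concentration_unit: str = "mol/L"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ValueError("wavelengths and absorbance must be 1-D of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.isfinite(wl).all() and np.isfinite(ab).all()):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            bad = wl[1:][np.diff(wl) <= 0][0]
            raise ValueError(f"wavelengths must be strictly increasing (offending value {bad} nm)")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def grid_step_nm(self) -> float:
        return float(np.mean(np.diff(self.wavelengths_nm)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.wavelengths_nm)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))

    def value_at(self, wavelength_nm: float) -> float:
        """Absorbance at a wavelength, linearly interpolated; no extrapolation."""
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"{wavelength_nm} nm outside spectrum range [{wl[0]}, {wl[-1]}] nm")
        return float(np.interp(wavelength_nm, wl, self.absorbance))

    def with_absorbance(self, absorbance: np.ndarray, **meta) -> "Spectrum":
        kwargs = dict(compound_id=self.compound_id,
                      concentration=self.concentration,
                      concentration_unit=self.concentration_unit)
        kwargs.update(meta)
        return Spectrum(self.wavelengths_nm, absorbance, **kwargs)


@dataclass(frozen=True)
class SpectrumSet:
    """m spectra on a shared grid, ordered by a perturbation variable.

    ``traces`` has shape (m, n); ``perturbation`` holds the m concentration
    values in row order.  Correlation analysis requires m >= 2.
    """

    grid_nm: np.ndarray
    traces: np.ndarray
    perturbation: np.ndarray
    compound_id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_nm, dtype=float)
        traces = np.asarray(self.traces, dtype=float)
        pert = np.asarray(self.perturbation, dtype=float)
        object.__setattr__(self, "grid_nm", grid)
        object.__setattr__(self, "traces", traces)
        object.__setattr__(self, "perturbation", pert)
        if traces.ndim != 2 or traces.shape[1] != grid.size:
            raise ValueError("traces must be (m, n) with n matching the grid")
        if pert.shape != (traces.shape[0],):
            raise ValueError("one perturbation value per trace required")
        if not np.isfinite(pert).all():
            raise ValueError("perturbation values must be finite")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def m(self) -> int:
        return int(self.traces.shape[0])

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum],
                     compound_id: str = "") -> "SpectrumSet":
        """Stack spectra (identical grids) ordered as given; perturbation is
        each spectrum's concentration metadata."""
        if not spectra:
            raise ValueError("need at least one spectrum")
        grid = spectra[0].wavelengths_nm
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths_nm, grid):
                raise GridMismatchError(
                    f"spectrum '{s.compound_id}' is not on the shared grid")
        conc = []
        for s in spectra:
            if s.concentration is None:
                raise ValueError(
                    f"spectrum '{s.compound_id}' lacks concentration metadata")
            conc.append(s.concentration)
        traces = np.vstack([s.absorbance for s in spectra])
        cid = compound_id or spectra[0].compound_id
        return cls(grid, traces, np.asarray(conc, dtype=float), cid)

    def spectra(self) -> list[Spectrum]:
        return [Spectrum(self.grid_nm, row, compound_id=self.compound_id,
                         concentration=float(c))
                for row, c in zip(self.traces, self.perturbation)]


# ---------------------------------------------------------------------------
# Spectrum file I/O (2-column CSV: wavelength_nm, absorbance)

def _as_text_stream(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_spectrum_csv(source: str | Path | IO[str],
                      compound_id: str = "",
                      concentration: float | None = None,
                      concentration_unit: str = "mol/L") -> Spectrum:
    """Read a two-column CSV (wavelength_nm, absorbance).

    A single non-numeric header line is tolerated.  Rows are sorted by
    wavelength if needed (with a warning); duplicate wavelengths are an
    error naming the offending value.
    """
    stream, opened = _as_text_stream(source)
    try:
        rows = list(csv.reader(stream))
    finally:
        if opened:
            stream.close()
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise SpectrumParseError("empty spectrum file")

    def _parse(row, lineno):
        if len(row) < 2:
            raise SpectrumParseError(f"line {lineno}: expected 2 columns, got {len(row)}")
        try:
            return float(row[0]), float(row[1])
        except ValueError as exc:
            raise SpectrumParseError(f"line {lineno}: non-numeric cell in {row!r}") from exc

    start = 0
    try:
        float(rows[0][0])
    except (ValueError, IndexError):
        start = 1  # header line
    data = [_parse(r, i + 1) for i, r in enumerate(rows[start:], start=start)]
    wl = np.array([d[0] for d in data])
    ab = np.array([d[1] for d in data])
    if np.any(np.diff(wl) < 0):
        warnings.warn("wavelengths were not sorted; sorting", stacklevel=2)
        order = np.argsort(wl, kind="stable")
        wl, ab = wl[order], ab[order]
    dup = np.flatnonzero(np.diff(wl) == 0)
    if dup.size:
        raise SpectrumParseError(f"duplicate wavelength {wl[dup[0]]} nm")
    return Spectrum(wl, ab, compound_id=compound_id,
                    concentration=concentration,
                    concentration_unit=concentration_unit)


def write_spectrum_csv(spectrum: Spectrum, sink: str | Path | IO[str]) -> None:
    """Write a spectrum at full (round-trip) precision."""
    stream, opened = _as_text_stream(sink, "w")
    try:
        stream.write(CSV_HEADER + "\n")
        for wl, ab in zip(spectrum.wavelengths_nm, spectrum.absorbance):
            stream.write(f"{float(wl)!r},{float(ab)!r}\n")
    finally:
        if opened:
            stream.close()


def read_series_dir(directory: str | Path, compound_id: str = "") -> SpectrumSet:
    """Read a concentration series from a directory of ``<concentration>.csv``
    files (the layout written by the ``simulate`` CLI)."""
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"), key=lambda p: float(p.stem))
    if not files:
        raise FileNotFoundError(f"no spectrum CSVs in {directory}")
    spectra = [read_spectrum_csv(p, compound_id=compound_id or directory.name,
                                 concentration=float(p.stem)) for p in files]
    return SpectrumSet.from_spectra(spectra, compound_id=compound_id or directory.name)


# ---------------------------------------------------------------------------
# Resampling and replicate averaging

def resample(spectrum: Spectrum, grid_nm: Sequence[float]) -> Spectrum:
    """Linear interpolation of a spectrum onto a new strictly increasing grid.

    The target grid must lie within the source range; extrapolation is
    refused.  Exact at shared abscissae and on affine absorbance functions.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("target grid must be 1-D and strictly increasing")
    lo, hi = spectrum.wavelengths_nm[0], spectrum.wavelengths_nm[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"target grid [{grid[0]}, {grid[-1]}] nm extends outside the "
            f"source range [{lo}, {hi}] nm; extrapolation is not performed")
    ab = np.interp(grid, spectrum.wavelengths_nm, spectrum.absorbance)
    return Spectrum(grid, ab, compound_id=spectrum.compound_id,
                    concentration=spectrum.concentration,
                    concentration_unit=spectrum.concentration_unit)


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate scans on identical grids.

    Mirrors the acquisition convention of averaging parallel scans; metadata
    of the first replicate is retained.
    """
    if not spectra:
        raise ValueError("need at least one replicate")
    grid = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths_nm, grid):
            raise GridMismatchError("replicates are not on identical grids")
    mean = np.mean(np.vstack([s.absorbance for s in spectra]), axis=0)
    return spectra[0].with_absorbance(mean)


# ---------------------------------------------------------------------------
# Packaged methylbenzene intensity table

@dataclass(frozen=True)
class IntensityTable:
    """Peak absorbances of benzene and its methyl substitutes at the four
    diagnostic wavelengths (1670, 2130, 2330, 2460 nm).

    Missing cells (benzene has no 2330 nm methyl band) are NaN, never 0.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if tuple(self.df.columns) != TABLE1_WAVELENGTHS:
            raise ValueError(f"columns must be {TABLE1_WAVELENGTHS}")
        vals = self.df.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("all present absorbances must be > 0")

    @property
    def compounds(self) -> list[str]:
        return list(self.df.index)

    def value(self, compound: str, wavelength_nm: int) -> float:
        """Absorbance for a compound at a column wavelength; NaN if missing."""
        key = _match_compound(self.df.index, compound)
        return float(self.df.at[key, int(wavelength_nm)])

    def max_absorbance(self) -> float:
        return float(np.nanmax(self.df.to_numpy(dtype=float)))


def _match_compound(index: Iterable[str], name: str) -> str:
    wanted = name.strip().lower().replace("_", "-")
    for key in index:
        if key.strip().lower().replace("_", "-") == wanted:
            return key
    raise KeyError(f"unknown compound {name!r}; have {list(index)}")


def load_intensity_table(fixture: str | Path | IO[str] | None = None) -> IntensityTable:
    """Load the packaged (or a user-supplied) methylbenzene intensity table.

    The fixture CSV has columns ``compound,a1670,a2130,a2330,a2460``; an empty
    cell marks a genuinely absent band.
    """
    if fixture is None:
        text = resources.files("nirassign.data").joinpath(
            "table1_intensities.csv").read_text(encoding="utf-8")
        fixture = io.StringIO(text)
    stream, opened = _as_text_stream(fixture)
    try:
        df = pd.read_csv(stream)
    finally:
        if opened:
            stream.close()
    expected = ["compound"] + [f"a{w}" for w in TABLE1_WAVELENGTHS]
    if list(df.columns) != expected:
        raise ValueError(f"intensity table must have columns {expected}, "
                         f"got {list(df.columns)}")
    df = df.set_index("compound")
    df.columns = list(TABLE1_WAVELENGTHS)
    return IntensityTable(df)
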