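"""Spectra-structure attribution and substituent-effect statistics.

Detected peaks are matched against a library of characteristic NIR band
intervals (ring/methyl/methylene C-H, O-H and natural-product compound
classes), and the substituent regularities of the methylbenzene series are
quantified: the linearity of the 2330 nm methyl combination band with the
methyl C-H count, the displacement ordering of the ring skeleton bands, and
the steric-hindrance width ordering.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .preprocess import Peak
from .spectra import IntensityTable, Spectrum, _match_compound

__all__ = [
    "BandLibraryEntry",
    "AssignmentRecord",
    "LinearityReport",
    "ShiftReport",
    "WidthReport",
    "load_band_library",
    "assign_peak",
    "intensity_ratio",
    "ch_linearity",
    "shift_report",
    "width_ordering",
    "DEFAULT_ASSIGN_TOLERANCE_NM",
]

BAND_CLASSES = ("fundamental", "first_overtone", "second_overtone",
                "third_overtone", "combination")
SOURCES = ("Table 2", "Table 3", "Table 4", "Table 5", "Table 6",
           "Results text")

#: Default matching tolerance: the largest quoted second-overtone shift.
DEFAULT_ASSIGN_TOLERANCE_NM = 10.0


@dataclass(frozen=True)
class BandLibraryEntry:
    """One characteristic band interval with its group attribution."""

    group: str
    low_nm: float
    high_nm: float
    band_class: str
    source: str
    compound_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.low_nm < self.high_nm):
            raise ValueError(
                f"malformed interval [{self.low_nm}, {self.high_nm}] nm "
                f"for group {self.group!r}")
        if self.band_class not in BAND_CLASSES:
            raise ValueError(f"unknown band class {self.band_class!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def contains(self, position_nm: float, tolerance_nm: float = 0.0) -> bool:
        return self.low_nm - tolerance_nm <= position_nm <= self.high_nm + tolerance_nm

    @property
    def midpoint_nm(self) -> float:
        return 0.5 * (self.low_nm + self.high_nm)

    @property
    def halfwidth_nm(self) -> float:
        return 0.5 * (self.high_nm - self.low_nm)


@dataclass(frozen=True)
class AssignmentRecord:
    """A peak with its library matches, best first."""

    peak: Peak
    matches: tuple[tuple[BandLibraryEntry, float], ...]
    status: str  # assigned | ambiguous | unassigned

    def to_dict(self) -> dict:
        return {
            "position_nm": self.peak.position_nm,
            "intensity": self.peak.intensity,
            "status": self.status,
            "matches": [{"group": e.group, "band_nm": [e.low_nm, e.high_nm],
                         "band_class": e.band_class, "source": e.source,
                         "compound_class": e.compound_class,
                         "score": round(s, 6)}
                        for e, s in self.matches],
        }


def load_band_library(config: str | Path | IO[str] | None = None
                      ) -> list[BandLibraryEntry]:
    """Load the packaged (or a user-supplied) YAML band library.

    Each entry carries a group attribution, a closed interval ``band_nm:
    [low, high]``, a band class, the table it was transcribed from, and
    optionally a natural-product compound class.  Exact duplicates
    (identical group and interval) raise a warning; a malformed interval is
    an error.
    """
    if config is None:
        text = resources.files("nirassign.data").joinpath(
            "band_library.yaml").read_text(encoding="utf-8")
    elif isinstance(config, (str, Path)):
        text = Path(config).read_text(encoding="utf-8")
    else:
        text = config.read()
    raw = yaml.safe_load(text)
    entries: list[BandLibraryEntry] = []
    seen = set()
    for item in raw["entries"]:
        low, high = (float(v) for v in item["band_nm"])
        entry = BandLibraryEntry(group=str(item["group"]), low_nm=low,
                                 high_nm=high,
                                 band_class=str(item["band_class"]),
                                 source=str(item["source"]),
                                 compound_class=item.get("compound_class"))
        key = (entry.group, entry.compound_class, entry.low_nm, entry.high_nm)
        if key in seen:
            warnings.warn(f"duplicate band-library entry {key}", stacklevel=2)
        seen.add(key)
        entries.append(entry)
    return entries


def assign_peak(peak: Peak | float, library: Sequence[BandLibraryEntry],
                tolerance_nm: float = DEFAULT_ASSIGN_TOLERANCE_NM
                ) -> AssignmentRecord:
    """Attribute one peak to the library intervals containing it.

    A library interval, widened by ``tolerance_nm``, matches if it contains
    the peak position; the match score 1 - d/(halfwidth + tolerance) (d the
    distance from the interval midpoint, clamped to [0, 1]) grades how
    central the hit is.  Status is ``unassigned`` with no match,
    ``ambiguous`` when two different groups tie within 0.1 of the top score,
    else ``assigned``.
    """
    if tolerance_nm < 0:
        raise ValueError("tolerance_nm must be >= 0")
    if not isinstance(peak, Peak):
        peak = Peak(float(peak), math.nan, 0.0, source="external")
    pos = peak.position_nm
    matches = []
    for entry in library:
        if entry.contains(pos, tolerance_nm):
            d = abs(pos - entry.midpoint_nm)
            score = 1.0 - d / (entry.halfwidth_nm + tolerance_nm)
            matches.append((entry, float(np.clip(score, 0.0, 1.0))))
    matches.sort(key=lambda t: (-t[1], t[0].group, t[0].low_nm))
    if not matches:
        status = "unassigned"
    elif (len(matches) > 1 and matches[0][1] - matches[1][1] < 0.1
          and matches[0][0].group != matches[1][0].group):
        status = "ambiguous"
    else:
        status = "assigned"
    return AssignmentRecord(peak=peak, matches=tuple(matches), status=status)


# ---------------------------------------------------------------------------
# Substituent-effect statistics

@dataclass(frozen=True)
class LinearityReport:
    """OLS fit of band intensity against methyl C-H count."""

    points: tuple[tuple[int, float], ...]
    slope: float
    intercept: float
    r_squared: float
    ratios_to_reference: tuple[float, ...]


def ch_linearity(points: Sequence[tuple[int, float]]) -> LinearityReport:
    """Ordinary least squares of intensity on methyl C-H count.

    ``ratios_to_reference`` divides each intensity by the mean intensity of
    the smallest C-H count present (the reference compound).  Requires at
    least two distinct counts; a constant-intensity input yields slope 0 and
    r-squared 0.
    """
    pts = [(int(c), float(i)) for c, i in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    counts = np.array([p[0] for p in pts], dtype=float)
    intens = np.array([p[1] for p in pts], dtype=float)
    if np.any(counts < 0) or np.any(intens < 0):
        raise ValueError("counts and intensities must be >= 0")
    if np.unique(counts).size < 2:
        raise ValueError("all ch_count values equal: degenerate design")
    if np.ptp(intens) == 0.0:
        slope, intercept, r2 = 0.0, float(intens[0]), 0.0
    else:
        fit = stats.linregress(counts, intens)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)
    ref = float(np.mean(intens[counts == counts.min()]))
    ratios = tuple(float(i / ref) for i in intens)
    return LinearityReport(points=tuple(pts), slope=slope, intercept=intercept,
                           r_squared=r2, ratios_to_reference=ratios)


def intensity_ratio(table: IntensityTable, wavelength_nm: int,
                    reference_compound: str,
                    round_to: float | None = None) -> dict[str, float]:
    """Per-compound intensity ratios to a reference compound at one column.

    Missing cells propagate as NaN; a missing reference value is an error
    (benzene has no 2330 nm methyl band).  ``round_to`` rounds each ratio to
    the nearest multiple (e.g. 0.5 reproduces 'about 1:2:3.5' granularity).
    """
    ref = table.value(reference_compound, wavelength_nm)
    if math.isnan(ref):
        raise ValueError(
            f"reference {reference_compound!r} has no value at {wavelength_nm} nm")
    out = {}
    for compound in table.compounds:
        v = table.value(compound, wavelength_nm)
        r = v / ref
        if round_to is not None and not math.isnan(r):
            r = round(r / round_to) * round_to
        out[compound] = r
    return out


@dataclass(frozen=True)
class ShiftReport:
    """Band displacements of compounds against a reference compound.

    ``pairs`` holds (compound_id, reference_position_nm, compound_position_nm,
    displacement_nm); displacement > 0 is a shift to longer wavelength.
    ``ordering`` sorts the compounds by displacement at the named band.
    """

    pairs: tuple[tuple[str, float, float, float], ...]
    ordering: tuple[str, ...]
    ordered_band_nm: float
    unpaired: tuple[str, ...] = ()


def shift_report(reference_peaks: Sequence[Peak],
                 compound_peaks: Mapping[str, Sequence[Peak]],
                 pairing_tolerance_nm: float = 35.0,
                 order_at_nm: float | None = None) -> ShiftReport:
    """Pair each reference band with each compound's nearest band and report
    displacements.

    ``order_at_nm`` names the reference band used for the compound ordering
    (default: the most intense reference peak).  A compound with no peak
    within tolerance of a reference band is flagged unpaired for that band.
    """
    if not reference_peaks:
        raise ValueError("no reference peaks")
    if order_at_nm is None:
        order_ref = max(reference_peaks,
                        key=lambda p: (p.intensity if math.isfinite(p.intensity)
                                       else -math.inf))
    else:
        order_ref = min(reference_peaks,
                        key=lambda p: abs(p.position_nm - order_at_nm))
    pairs = []
    unpaired = []
    order_disp: dict[str, float] = {}
    for compound, peaks in compound_peaks.items():
        for ref in reference_peaks:
            if not peaks:
                candidates = []
            else:
                candidates = sorted(peaks, key=lambda p: abs(p.position_nm - ref.position_nm))
            if candidates and abs(candidates[0].position_nm - ref.position_nm) <= pairing_tolerance_nm:
                comp_pos = candidates[0].position_nm
                disp = comp_pos - ref.position_nm
                pairs.append((compound, ref.position_nm, comp_pos, disp))
                if ref is order_ref:
                    order_disp[compound] = disp
            else:
                unpaired.append(compound)
                if ref is order_ref:
                    order_disp.pop(compound, None)
    ordering = tuple(sorted(order_disp, key=lambda c: order_disp[c]))
    return ShiftReport(pairs=tuple(pairs), ordering=ordering,
                       ordered_band_nm=order_ref.position_nm,
                       unpaired=tuple(dict.fromkeys(unpaired)))


@dataclass(frozen=True)
class WidthReport:
    """FWHM of one band across compounds, widest first."""

    widths_nm: tuple[tuple[str, float], ...]  # descending FWHM
    ties: tuple[tuple[str, ...], ...]
    flagged: tuple[str, ...]

    @property
    def ordering(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.widths_nm)


def width_ordering(spectra: Mapping[str, Spectrum], band_center_nm: float,
                   search_halfwidth_nm: float = 50.0,
                   tie_tolerance_nm: float = 1e-6) -> WidthReport:
    """Order compounds by the FWHM of the band nearest ``band_center_nm``.

    Within a local window the band is measured after removing a linear
    baseline through the window edges; FWHM is the distance between the
    half-maximum crossings (linear interpolation).  A band whose
    half-maximum crossings are clipped by the window edge, or with no local
    maximum, is flagged rather than silently measured.
    """
    widths: dict[str, float] = {}
    flagged = []
    for name, spec in spectra.items():
        wl, ab = spec.wavelengths_nm, spec.absorbance
        lo, hi = band_center_nm - search_halfwidth_nm, band_center_nm + search_halfwidth_nm
        mask = (wl >= lo) & (wl <= hi)
        if mask.sum() < 5:
            flagged.append(name)
            continue
        x, y = wl[mask], ab[mask]
        baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        ys = y - baseline
        i = int(np.argmax(ys))
        if i in (0, len(ys) - 1) or ys[i] <= 0:
            flagged.append(name)
            continue
        half = ys[i] / 2.0
        left = right = None
        for k in range(i, 0, -1):
            if ys[k - 1] <= half <= ys[k]:
                frac = (half - ys[k - 1]) / (ys[k] - ys[k - 1])
                left = x[k - 1] + frac * (x[k] - x[k - 1])
                break
        for k in range(i, len(ys) - 1):
            if ys[k + 1] <= half <= ys[k]:
                frac = (ys[k] - half) / (ys[k] - ys[k + 1])
                right = x[k] + frac * (x[k + 1] - x[k])
                break
        if left is None or right is None:
            flagged.append(name)  # clipped at the window edge
            continue
        widths[name] = float(right - left)
    ordered = sorted(widths.items(), key=lambda kv: (-kv[1], kv[0]))
    ties = []
    used = set()
    names = [n for n, _ in ordered]
    for a in names:
        if a in used:
            continue
        grp = [b for b in names if abs(widths[b] - widths[a]) <= tie_tolerance_nm]
        if len(grp) > 1:
            ties.append(tuple(grp))
            used.update(grp)
    return WidthReport(widths_nm=tuple((n, w) for n, w in ordered),
                       ties=tuple(ties), flagged=tuple(flagged))


def write_assignments(records: Sequence[AssignmentRecord],
                      path_json: str | Path) -> None:
    """Serialize assignment records to JSON."""
    payload = [r.to_dict() for r in records]
    Path(path_json).write_text(json.dumps(payload, indent=2, sort_keys=True),
                               encoding="utf-8")
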