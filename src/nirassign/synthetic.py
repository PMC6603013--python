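"""Synthetic NIR spectra with the statistical structure the assignment
pipeline assumes.

The generator emulates: an anharmonic overtone ladder
:math:`\\Delta G(0 \\to n) = n\\,\\omega_e - n(n+1)\\,\\omega_e\\chi_e`
(wavenumbers; NIR overtones are the n >= 2 rungs), Beer-Lambert response
(absorbance = pathlength x concentration x molar absorptivity profile),
substituent-controlled band amplitude/shift/width, and additive Gaussian
instrument noise.  A methylbenzene family constructor encodes the
substituent regularities the pipeline must recover (methyl-band intensity
proportional to methyl C-H count; skeleton band shifted to longer
wavelength and broadened in a fixed order), and a 12-band analog of a
natural-product spectrum feeds the 2D-COS autopeak analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spectra import Spectrum, SpectrumSet, wavenumber_to_nm

__all__ = [
    "VibrationalMode",
    "BandModel",
    "CompoundModel",
    "overtone_positions",
    "band_profile",
    "simulate_spectrum",
    "simulate_concentration_series",
    "make_methylbenzene_family",
    "make_magnolol_analog",
    "default_synthetic_grid",
    "FAMILY_COMPOUNDS",
    "DEFAULT_SHIFTS_NM",
    "DEFAULT_SKELETON_FWHM_NM",
    "METHYL_H_COUNTS",
    "EPSILON_PER_METHYL_H",
]

#: Family keys in canonical order.
FAMILY_COMPOUNDS = ("benzene", "toluene", "ortho-xylene", "meta-xylene",
                    "para-xylene", "mesitylene")

#: Skeleton first-overtone displacement to longer wavelength, nm.  Encodes
#: the observed ordering toluene < ortho < meta < para < mesitylene with the
#: largest shift 30 nm.
DEFAULT_SHIFTS_NM = {"benzene": 0.0, "toluene": 5.0, "ortho-xylene": 10.0,
                     "meta-xylene": 15.0, "para-xylene": 20.0,
                     "mesitylene": 30.0}

#: Skeleton band FWHM, nm.  Encodes the steric-hindrance width ordering
#: ortho > meta > para > benzene.
DEFAULT_SKELETON_FWHM_NM = {"benzene": 20.0, "toluene": 24.0,
                            "ortho-xylene": 40.0, "meta-xylene": 32.0,
                            "para-xylene": 26.0, "mesitylene": 28.0}

#: Number of methyl C-H per compound (toluene 3, each xylene 6, mesitylene 9).
METHYL_H_COUNTS = {"benzene": 0, "toluene": 3, "ortho-xylene": 6,
                   "meta-xylene": 6, "para-xylene": 6, "mesitylene": 9}

#: Peak molar absorptivity of the 2330 nm methyl combination band per methyl
#: C-H (AU per mol/L per cm); free magnitude chosen so a 1 mol/L xylene sits
#: near its measured peak absorbance.
EPSILON_PER_METHYL_H = 0.16

# Skeleton-band peak absorptivities at 1 mol/L.  The 1670 nm values encode
# the symmetry rule (higher symmetry => lower skeleton intensity:
# ortho > meta > para); the 2130/2460 nm values follow the measured peak
# absorbances of the real compounds.
_SKELETON_EPS_1670 = {"benzene": 0.44, "toluene": 0.31, "ortho-xylene": 0.34,
                      "meta-xylene": 0.31, "para-xylene": 0.28,
                      "mesitylene": 0.40}
_EPS_2130 = {"benzene": 0.3746, "toluene": 0.4169, "ortho-xylene": 0.3598,
             "meta-xylene": 0.3456, "para-xylene": 0.4980,
             "mesitylene": 0.3846}
_EPS_2460 = {"benzene": 2.0124, "toluene": 1.1594, "ortho-xylene": 0.6920,
             "meta-xylene": 1.0973, "para-xylene": 1.1597,
             "mesitylene": 1.0621}


def default_synthetic_grid(start_nm: float = 780.0, stop_nm: float = 2500.0,
                           step_nm: float = 0.5) -> np.ndarray:
    """Default synthetic instrument window: 780-2500 nm at 0.5 nm."""
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass(frozen=True)
class VibrationalMode:
    """Anharmonic oscillator: harmonic frequency and anharmonicity, cm^-1."""

    omega_e: float
    omega_e_chi_e: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.omega_e <= 0 or self.omega_e_chi_e < 0:
            raise ValueError("omega_e must be > 0 and omega_e_chi_e >= 0")


@dataclass(frozen=True)
class BandModel:
    """One absorption band: centre, FWHM, peak molar absorptivity, shape."""

    center_nm: float
    fwhm_nm: float
    epsilon: float
    shape: str = "gaussian"  # gaussian | lorentzian | pseudo_voigt
    eta: float = 0.5         # Lorentzian fraction for pseudo_voigt
    group: str = ""

    def __post_init__(self) -> None:
        if self.center_nm <= 0 or self.fwhm_nm <= 0 or self.epsilon < 0:
            raise ValueError("centre and FWHM must be > 0, epsilon >= 0")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")


@dataclass(frozen=True)
class CompoundModel:
    """Generative description of a compound's NIR bands."""

    name: str
    bands: tuple[BandModel, ...]
    methyl_h_count: int = 0
    skeleton_shift_nm: float = 0.0
    skeleton_fwhm_nm: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.methyl_h_count < 0:
            raise ValueError("methyl_h_count must be >= 0")
        if self.skeleton_fwhm_nm <= 0:
            raise ValueError("skeleton_fwhm_nm must be > 0")


def overtone_positions(mode: VibrationalMode,
                       n_max: int = 3) -> list[tuple[int, float, float]]:
    """Transition energies of the 0 -> n ladder and their NIR wavelengths.

    Returns (n, wavenumber_cm, wavelength_nm) for n = 1..n_max with
    Delta G(0->n) = n*omega_e - n(n+1)*omega_e_chi_e.  Anharmonicity makes
    successive overtones fall below the harmonic multiples (red shift in
    wavenumber); if it is so large that the ladder stops increasing within
    n_max, the mode is rejected.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    out = []
    prev = 0.0
    for n in range(1, n_max + 1):
        dg = n * mode.omega_e - n * (n + 1) * mode.omega_e_chi_e
        if dg <= prev:
            raise ValueError(
                f"anharmonicity too large: Delta G(0->{n}) = {dg} cm^-1 does "
                f"not exceed Delta G(0->{n - 1}) = {prev} cm^-1")
        out.append((n, dg, float(wavenumber_to_nm(dg))))
        prev = dg
    return out


def band_profile(band: BandModel, grid_nm: Sequence[float]) -> np.ndarray:
    """Absorbance contribution per unit concentration and pathlength."""
    x = np.asarray(grid_nm, dtype=float) - band.center_nm
    w = band.fwhm_nm
    gauss = np.exp(-4.0 * np.log(2.0) * x ** 2 / w ** 2)
    if band.shape == "gaussian":
        prof = gauss
    else:
        lor = (w / 2.0) ** 2 / (x ** 2 + (w / 2.0) ** 2)
        if band.shape == "lorentzian":
            prof = lor
        else:
            prof = band.eta * lor + (1.0 - band.eta) * gauss
    return band.epsilon * prof


def simulate_spectrum(compound: CompoundModel, concentration: float,
                      grid_nm: Sequence[float] | None = None,
                      noise_sd: float = 0.0, seed: int = 0,
                      pathlength_cm: float = 1.0) -> Spectrum:
    """Beer-Lambert spectrum of a compound at one concentration.

    A(lambda) = pathlength * concentration * sum of band profiles, plus
    additive homoscedastic Gaussian noise from a generator seeded with
    ``seed`` (identical seeds give bit-identical spectra).
    """
    if concentration < 0 or noise_sd < 0 or pathlength_cm <= 0:
        raise ValueError("concentration/noise must be >= 0, pathlength > 0")
    grid = default_synthetic_grid() if grid_nm is None else np.asarray(grid_nm, float)
    a = np.zeros_like(grid)
    for band in compound.bands:
        a += band_profile(band, grid)
    a *= pathlength_cm * concentration
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, a, compound_id=compound.name,
                    concentration=float(concentration))


def simulate_concentration_series(compound: CompoundModel,
                                  concentrations: Sequence[float],
                                  grid_nm: Sequence[float] | None = None,
                                  noise_sd: float = 0.0,
                                  seed: int = 0,
                                  pathlength_cm: float = 1.0) -> SpectrumSet:
    """One spectrum per concentration with independent seeded noise."""
    if len(concentrations) < 2:
        raise ValueError("a concentration series needs >= 2 levels")
    grid = default_synthetic_grid() if grid_nm is None else np.asarray(grid_nm, float)
    spectra = [simulate_spectrum(compound, c, grid, noise_sd,
                                 seed=(seed * 100003 + i) % (2 ** 31 - 1),
                                 pathlength_cm=pathlength_cm)
               for i, c in enumerate(concentrations)]
    return SpectrumSet.from_spectra(spectra, compound_id=compound.name)


def make_methylbenzene_family(
        skeleton_center_nm: float = 1670.0,
        methyl_center_nm: float = 2330.0,
        shifts_nm: Mapping[str, float] | None = None,
        widths_nm: Mapping[str, float] | None = None,
        epsilon_per_h: float = EPSILON_PER_METHYL_H) -> list[CompoundModel]:
    """Benzene and its methyl substitutes as synthetic compound models.

    Each compound carries a skeleton (ring C-H) first overtone near
    ``skeleton_center_nm`` displaced to longer wavelength per ``shifts_nm``
    and broadened per ``widths_nm``, a second-overtone echo near 1140 nm
    (one third of the displacement, as seen experimentally), ring
    combination bands at 2130 and 2460 nm, and — for the substituted
    compounds — a methyl C-H combination band at ``methyl_center_nm`` whose
    peak absorptivity is exactly proportional to the methyl C-H count
    (3 / 6 / 9).  The benzene analog has no methyl band at all.
    """
    shifts = dict(DEFAULT_SHIFTS_NM if shifts_nm is None else shifts_nm)
    widths = dict(DEFAULT_SKELETON_FWHM_NM if widths_nm is None else widths_nm)
    for name in FAMILY_COMPOUNDS:
        if name not in shifts or name not in widths:
            raise KeyError(f"missing shift/width for family compound {name!r}")
    family = []
    for name in FAMILY_COMPOUNDS:
        shift = float(shifts[name])
        fwhm = float(widths[name])
        h = METHYL_H_COUNTS[name]
        bands = [
            BandModel(1140.0 + shift / 3.0, 16.0, 0.12,
                      group="C-H of benzene ring (second overtone)"),
            BandModel(skeleton_center_nm + shift, fwhm,
                      _SKELETON_EPS_1670[name],
                      group="C-H of benzene ring (first overtone)"),
            BandModel(2130.0, 24.0, _EPS_2130[name],
                      group="C-H of benzene ring (combination)"),
            BandModel(2460.0, 20.0, _EPS_2460[name],
                      group="C-H of benzene ring (combination)"),
        ]
        if h > 0:
            bands.append(BandModel(methyl_center_nm, 20.0, epsilon_per_h * h,
                                   group="C-H of methyl (combination)"))
        family.append(CompoundModel(name=name, bands=tuple(bands),
                                    methyl_h_count=h,
                                    skeleton_shift_nm=shift,
                                    skeleton_fwhm_nm=fwhm))
    return family


def make_magnolol_analog(n_bands: int = 12, window_nm=(1100.0, 2500.0),
                         fwhm_nm: float = 20.0) -> CompoundModel:
    """A multi-band natural-product analog for autopeak counting.

    ``n_bands`` well-separated Gaussian bands (spacing >= 4x FWHM) evenly
    placed inside ``window_nm`` with distinct absorptivities, so a noiseless
    concentration series produces exactly ``n_bands`` synchronous autopeaks.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    lo, hi = window_nm
    margin = 2.0 * fwhm_nm
    centers = np.linspace(lo + margin, hi - margin, n_bands)
    if n_bands > 1:
        spacing = centers[1] - centers[0]
        if spacing < 4.0 * fwhm_nm:
            raise ValueError(
                f"{n_bands} bands of FWHM {fwhm_nm} nm cannot keep spacing "
                f">= {4.0 * fwhm_nm} nm inside {window_nm} (got {spacing:.1f} nm)")
    eps = np.linspace(0.4, 1.5, n_bands) if n_bands > 1 else np.array([1.0])
    bands = tuple(BandModel(float(c), fwhm_nm, float(e), group=f"band {i + 1}")
                  for i, (c, e) in enumerate(zip(centers, eps)))
    return CompoundModel(name="magnolol-analog", bands=bands)
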