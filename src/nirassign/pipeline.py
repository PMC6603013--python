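"""End-to-end orchestration of the assignment workflow.

A :class:`RunConfig` (every field defaulted; the fully-defaulted config runs
the packaged synthetic demo) drives five stages: second-derivative spectra,
difference spectra against a reference compound, 2D correlation maps with
autopeak lists, band-library assignment of detected peaks, and the
substituent reports (methyl C-H linearity, skeleton shift ordering, width
ordering, intensity-ratio table).  A JSON manifest records the package
version, seed, parameters and a SHA-256 digest of every artifact; two runs
with identical config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assignment import (assign_peak, ch_linearity, intensity_ratio,
                         load_band_library, shift_report, width_ordering,
                         write_assignments)
from .preprocess import (band_intensity, detect_peaks, difference_spectrum,
                         second_derivative, write_peaks_csv)
from .spectra import (Spectrum, load_intensity_table, read_spectrum_csv,
                      write_spectrum_csv)
from .synthetic import (make_magnolol_analog, make_methylbenzene_family,
                        simulate_concentration_series, simulate_spectrum)
from .twodcos import autopeaks, correlate, write_correlation_csv

__all__ = ["RunConfig", "PipelineError", "run_assignment_pipeline"]

log = logging.getLogger("nirassign.pipeline")

STAGES = ("derivative", "difference", "cos2d", "assignment", "reports")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs of the run have been removed."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration; defaults run the synthetic demo."""

    input_dir: str | None = None
    outdir: str = "nirassign_output"
    seed: int = 0
    grid_start_nm: float = 780.0
    grid_stop_nm: float = 2500.0
    grid_step_nm: float = 0.5
    sg_window_points: int = 21
    sg_polyorder: int = 3
    cos_window: tuple[float, float] = (1100.0, 2500.0)
    cos_stride: int = 4
    cos_reference: str = "mean"
    band_library_path: str | None = None
    assign_tolerance_nm: float = 10.0
    concentrations: tuple[float, ...] = (0.2, 0.4, 0.6, 9.6, 9.8, 10.0)
    noise_sd: float = 0.0
    reference_compound: str = "benzene"
    stages: tuple[str, ...] = STAGES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cos_window"] = list(self.cos_window)
        d["concentrations"] = list(self.concentrations)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "cos_window" in kwargs:
            kwargs["cos_window"] = tuple(kwargs["cos_window"])
        if "concentrations" in kwargs:
            kwargs["concentrations"] = tuple(kwargs["concentrations"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _grid(config: RunConfig) -> np.ndarray:
    n = int(round((config.grid_stop_nm - config.grid_start_nm)
                  / config.grid_step_nm)) + 1
    return config.grid_start_nm + config.grid_step_nm * np.arange(n)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _demo_inputs(config: RunConfig):
    """Synthetic demo: methylbenzene family at 1 mol/L + a 12-band series."""
    grid = _grid(config)
    family = make_methylbenzene_family()
    spectra = {c.name: simulate_spectrum(c, 1.0, grid, config.noise_sd,
                                         seed=config.seed)
               for c in family}
    magnolol = make_magnolol_analog()
    series = {magnolol.name: simulate_concentration_series(
        magnolol, config.concentrations, grid, config.noise_sd,
        seed=config.seed)}
    return family, spectra, series


def _load_inputs(config: RunConfig):
    """Measured-data mode: flat CSVs are compound spectra; subdirectories of
    ``<concentration>.csv`` files are concentration series."""
    from .spectra import read_series_dir
    root = Path(config.input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} does not exist")
    spectra = {}
    for p in sorted(root.glob("*.csv")):
        spectra[p.stem] = read_spectrum_csv(p, compound_id=p.stem)
    series = {}
    for d in sorted(x for x in root.iterdir() if x.is_dir()):
        series[d.name] = read_series_dir(d)
    if not spectra and not series:
        raise FileNotFoundError(f"no spectrum CSVs under {root}")
    return None, spectra, series


def run_assignment_pipeline(config: RunConfig | None = None) -> dict:
    """Run the configured stages and return the manifest (also written to
    ``<outdir>/manifest.json``).

    On any stage failure the files created by this run are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    config = config or RunConfig()
    if config.band_library_path is not None and \
            not Path(config.band_library_path).is_file():
        raise FileNotFoundError(
            f"band library not found: {config.band_library_path}")
    library = load_band_library(config.band_library_path)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    artifacts: dict[str, list[str]] = {}

    def _register(stage: str, path: Path) -> None:
        created.append(path)
        artifacts.setdefault(stage, []).append(
            path.relative_to(outdir).as_posix())

    family, spectra, series = (_demo_inputs(config) if config.input_dir is None
                               else _load_inputs(config))
    ref_name = config.reference_compound
    current = "setup"
    try:
        if "derivative" in config.stages:
            current = "derivative"
            d = outdir / "derivatives"
            d.mkdir(exist_ok=True)
            for name, spec in spectra.items():
                d2 = second_derivative(spec, config.sg_window_points,
                                       config.sg_polyorder)
                path = d / f"{name}_d2.csv"
                write_spectrum_csv(d2, path)
                _register("derivative", path)
            log.info("derivative: %d spectra, window=%d polyorder=%d",
                     len(spectra), config.sg_window_points, config.sg_polyorder)

        if "difference" in config.stages and ref_name in spectra:
            current = "difference"
            d = outdir / "differences"
            d.mkdir(exist_ok=True)
            ref = spectra[ref_name]
            for name, spec in spectra.items():
                if name == ref_name:
                    continue
                path = d / f"{name}_minus_{ref_name}.csv"
                write_spectrum_csv(difference_spectrum(spec, ref), path)
                _register("difference", path)

        if "cos2d" in config.stages:
            current = "cos2d"
            d = outdir / "cos2d"
            d.mkdir(exist_ok=True)
            for name, sset in series.items():
                result = correlate(sset, reference=config.cos_reference,
                                   window=config.cos_window,
                                   stride=config.cos_stride)
                write_correlation_csv(result, d / name)
                peaks = autopeaks(result)
                ppath = d / f"{name}_autopeaks.csv"
                write_peaks_csv(peaks, ppath)
                for suffix in ("sync", "async"):
                    _register("cos2d", d / f"{name}_{suffix}.csv")
                _register("cos2d", ppath)
                log.info("cos2d: %s m=%d window=%s stride=%d autopeaks=%d",
                         name, sset.m, config.cos_window, config.cos_stride,
                         len(peaks))

        if "assignment" in config.stages:
            current = "assignment"
            d = outdir / "assignments"
            d.mkdir(exist_ok=True)
            for name, spec in spectra.items():
                peaks = detect_peaks(spec, mode="second_derivative_minima",
                                     window_points=config.sg_window_points,
                                     polyorder=config.sg_polyorder)
                records = [assign_peak(p, library, config.assign_tolerance_nm)
                           for p in peaks]
                path = d / f"{name}_assignments.json"
                write_assignments(records, path)
                _register("assignment", path)

        if "reports" in config.stages:
            current = "reports"
            d = outdir / "reports"
            d.mkdir(exist_ok=True)
            reports: dict[str, dict] = {}
            if family is not None:
                points = [(c.methyl_h_count,
                           band_intensity(spectra[c.name], 2330.0))
                          for c in family if c.methyl_h_count > 0]
                lin = ch_linearity(points)
                reports["linearity"] = {
                    "points": [list(p) for p in lin.points],
                    "slope": lin.slope, "intercept": lin.intercept,
                    "r_squared": lin.r_squared,
                    "ratios_to_reference": list(lin.ratios_to_reference)}
                ref_peaks = detect_peaks(
                    spectra[ref_name], mode="second_derivative_minima",
                    window_points=config.sg_window_points,
                    polyorder=config.sg_polyorder)
                comp_peaks = {c.name: detect_peaks(
                    spectra[c.name], mode="second_derivative_minima",
                    window_points=config.sg_window_points,
                    polyorder=config.sg_polyorder)
                    for c in family if c.name != ref_name}
                shifts = shift_report(ref_peaks, comp_peaks,
                                      order_at_nm=1670.0)
                reports["shift"] = {
                    "ordered_band_nm": shifts.ordered_band_nm,
                    "ordering": list(shifts.ordering),
                    "pairs": [list(p) for p in shifts.pairs]}
                widths = width_ordering(spectra, 1670.0, search_halfwidth_nm=80.0)
                reports["width"] = {
                    "widths_nm": [list(w) for w in widths.widths_nm],
                    "ordering": list(widths.ordering),
                    "flagged": list(widths.flagged)}
            table = load_intensity_table()
            reports["intensity_ratio_2330"] = {
                k: (None if np.isnan(v) else v)
                for k, v in intensity_ratio(table, 2330, "toluene",
                                            round_to=0.5).items()}
            path = d / "reports.json"
            path.write_text(json.dumps(reports, indent=2, sort_keys=True),
                            encoding="utf-8")
            _register("reports", path)
    except Exception as exc:  # noqa: BLE001 - abort semantics
        for p in created:
            p.unlink(missing_ok=True)
        raise PipelineError(current, exc) from exc

    manifest = {
        "package": "nirassign",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {stage: [{"path": rel,
                               "sha256": _sha256(outdir / rel)}
                              for rel in sorted(paths)]
                      for stage, paths in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest
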