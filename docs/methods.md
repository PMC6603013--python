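# Methods

## Scope and model

`nirassign` treats an NIR spectrum as a sampled absorbance trace A(λ) on a
strictly increasing wavelength grid in nm (vacuum wavenumber via
ν̃ = 10⁷/λ).  The default acquisition grid is 400–2500 nm at 0.5 nm
(4201 points), matching common grating instruments; synthetic spectra use
780–2500 nm by default because all analysis bands lie there and the smaller
arrays keep tests fast.  Replicate scans are combined by pointwise
arithmetic mean.  Resampling is linear interpolation with extrapolation
refused: nothing outside the measured range is ever invented.

The scientific model underlying every stage is Beer–Lambert additivity:
A(λ) = ℓ·c·Σ_bands ε_b·p_b(λ), with ℓ the path length (cm), c the
concentration, ε_b a peak molar absorptivity and p_b a unit-height band
profile.  Band positions follow the anharmonic-oscillator ladder
ΔG(0→n) = n·ωₑ − n(n+1)·ωₑχₑ (cm⁻¹); the generator rejects parameter
combinations whose ladder stops increasing within the requested overtone
order.  Combination bands are modelled as free-standing bands (e.g. the
methyl C–H combination near 2330 nm) rather than computed from mode sums,
because computing combination-level positions would require anharmonic
cross terms that are not available; their positions are taken from the band
library instead.

## Second derivative and peak detection

The second derivative is a Savitzky–Golay filter (scipy) with respect to
wavelength; it is exact on polynomials up to the fit order, and turns each
absorption maximum into a sharp local minimum whose negative side lobes are
what give the method its resolving power.  Defaults: window 21 points
(10.5 nm on the 0.5 nm grid), polynomial order 3.  These are package
choices — derivative parameters are rarely reported with published spectra
— and the half-window at each spectrum end is excluded from peak reporting
rather than padded, so no fabricated edge structure can enter an
assignment.

Peak detection runs `scipy.signal.find_peaks` on either the raw trace or
the negated second derivative.  Sub-grid positions come from parabolic
interpolation through the extremal sample and its two neighbours; plateau
ties resolve to the lower wavelength for determinism.  The default
prominence threshold is 3× the median absolute deviation of the searched
trace plus 10⁻⁴ of its range; noise-free tests pass 0.  In derivative mode
a peak must additionally have height above the threshold (genuinely
concave-down absorbance): the flat stretches between two bands' negative
side lobes are formally prominent local maxima of −d²A/dλ² but carry no
absorbance, and the height criterion removes them.  Reported intensity in
derivative mode is the raw absorbance interpolated at the refined position.

## 2D correlation spectroscopy

Synchronous and asynchronous maps use Noda's generalized formulation with
the discrete Hilbert transform implemented by the Hilbert–Noda matrix
N_jk = 0 (j = k), 1/(π(k−j)) otherwise.  The maps are computed by matrix
algebra (ỹᵀỹ/(m−1) and ỹᵀNỹ/(m−1)) and are verified in the test suite
against a direct double-loop summation oracle to 10⁻¹² relative tolerance.
The dynamic-spectra reference defaults to the series mean (so Φ's diagonal
is exactly the per-wavelength sample variance); "first spectrum" and an
external reference are exposed as options because the choice is a genuine
degree of freedom in published 2D-COS work.  Correlation is restricted to a
wavelength window (default 1100–2500 nm, the overtone/combination region)
with an optional decimation stride, since full-grid n² maps are wasteful.

Autopeaks are local maxima of the synchronous diagonal with a default
prominence threshold of 10× the diagonal's median.  The rationale: for a
real band series the diagonal is near zero between bands, so every
responding band clears the threshold, while for a noise-dominated series
the diagonal is a roughly flat variance estimate whose spurious wiggles
have prominence well below ten times its median.  This one rule makes the
autopeak count a usable suitability statistic: the concentration screen
simulates a candidate series per concentration set (per-set derived seeds),
counts autopeaks, and reports whether the count reaches the expected band
number.  Concentration suitability is reported against relative
concentration spans rather than absolute units.  The Noda sign rules for
sequential ordering are deliberately not encoded as typed claims; the maps
are used for band positions and counts.

## Band library and attribution

The packaged YAML library holds closed intervals [low, high] nm with a
group attribution, a band class (fundamental/overtones/combination) and a
compound class for the natural-product rows.  Broad table-derived intervals
are opaque: no attempt is made to recompute them from quantum theory.
Single-position attributions from measured spectra are stored as ±20 nm
intervals, a package choice.  A peak matches an entry if the interval,
widened by the assignment tolerance (default 10 nm — the largest
second-overtone displacement observed in the methylbenzene series),
contains it; the score 1 − d/(halfwidth + tolerance) (d the distance to the
interval midpoint, clamped to [0, 1]) grades how central the hit is.  The
score formula is invented here so ambiguity is quantifiable: a record is
`ambiguous` when two different groups tie within 0.1 of the top score,
`unassigned` with no match, else `assigned`.  Widening the tolerance can
never turn an assigned peak unassigned (tested as a property).

## Substituent statistics

- **Methyl C–H linearity**: ordinary least squares (scipy) of band
  intensity on methyl C–H count, with ratios to the smallest-count
  compound.  Ethylbenzene is excluded from the fit — its two methylene H
  are not methyl H — but its intensity falls between toluene and the
  xylenes, which the ratio table shows (1.5 after 0.5-rounding).  Constant
  intensities return slope 0 and r² 0 rather than NaN.
- **Shift report**: each reference band pairs with the compound's nearest
  detected band within a tolerance (default 35 nm, covering the largest
  30 nm skeleton displacement); displacement > 0 means a shift to longer
  wavelength, and compounds are ordered by displacement at a named band.
- **Width ordering**: FWHM by half-maximum crossings after removing a
  linear baseline through the local window edges; a band whose crossings
  leave the window is flagged, never silently measured; exact ties are
  reported as ties.

## Synthetic data: what it emulates and what it does not

The generator encodes the statistical structure the analysis assumes, with
magnitudes chosen once:

- The methylbenzene family (benzene, toluene, ortho/meta/para-xylene,
  mesitylene) carries a ring-C–H first overtone near 1670 nm, a
  second-overtone echo near 1140 nm (one third of the displacement, as the
  measured 10 vs 30 nm shifts suggest), ring combination bands at 2130 and
  2460 nm, and — except benzene — a methyl combination band at 2330 nm
  whose ε is exactly 0.16 AU·L·mol⁻¹·cm⁻¹ per methyl C–H, so the 3:6:9
  count gives intensity ratios exactly 1:2:3.  Skeleton shifts are
  {0, 5, 10, 15, 20, 30} nm and FWHMs {20, 24, 40, 32, 26, 28} nm, encoding
  the observed displacement ordering (toluene < ortho < meta < para <
  mesitylene) and steric width ordering (ortho > meta > para > benzene).
  The 1670 nm ε values encode the symmetry rule (higher symmetry, lower
  skeleton intensity: ortho 0.34 > meta 0.31 > para 0.28); 2130/2460 nm ε
  values follow the measured 1 mol/L peak absorbances.  No published molar
  absorptivities or widths exist for these bands; these are constructed
  magnitudes, and passing tests demonstrate that the pipeline recovers
  exactly what was encoded — not that real spectra behave this simply.
- The 12-band analog places Gaussian bands (FWHM 20 nm) evenly in
  1100–2500 nm with spacing ≥ 4× FWHM and distinct ε ∈ [0.4, 1.5]; a
  packing that cannot keep that spacing is rejected.
- The default concentration series is six levels at volume fractions
  0.2, 0.4, 0.6, 9.6, 9.8, 10.0 %, mirroring a serial-dilution design.
- Noise is additive homoscedastic Gaussian on absorbance, drawn from one
  seeded generator per spectrum (series spectra derive independent
  sub-seeds); identical seeds give bit-identical arrays.  Real NIR noise is
  heteroscedastic and includes baseline drift, scatter and solvent
  absorption, none of which are modelled; baseline/scatter correction is
  explicitly out of scope.

Band shapes default to Gaussian (closed-form derivative oracles);
Lorentzian and pseudo-Voigt are available for stress tests.

## Pipeline and numerical choices

The pipeline writes plain CSV/JSON artifacts; plotting is optional and
never required.  The manifest contains the package version, seed, full
configuration and a SHA-256 per artifact, and no timestamps, so two runs
with the same configuration are byte-identical (tested).  A stage failure
removes the files created by that run and raises an error naming the
stage.  Problem sizes used by the test suite and the acceptance script —
the 3441-point synthetic grid, stride-4 correlation windows (≈700-point
maps), m = 6 series, 20-replicate suitability screens — are the package's
own defaults for routine analysis of this kind.

Degenerate inputs are rejected rather than guessed at: fewer than two
spectra for correlation, non-uniform grids for differentiation (resample
first), missing concentration metadata for normalization, duplicate
wavelengths on parse, extrapolating resample targets, all-equal counts in
the linearity fit.

## Known limitations

- Linear interpolation everywhere; no band-fitting (Voigt deconvolution)
  of overlapped experimental bands.
- The band library's broad intervals make multi-class ambiguity common for
  combination-region peaks; the score separates candidates but cannot
  resolve genuinely overlapping attributions.
- 2T2D and hetero-spectral correlation, moving-window 2D-COS, baseline and
  scatter correction, and any ab-initio frequency computation are out of
  scope.
- The suitability screen's autopeak threshold (10× diagonal median) is a
  heuristic validated on the synthetic noise model; instruments with
  structured noise may need an explicit threshold.
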