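"""Band-library attribution and substituent-effect statistics.

The linearity check carries its own closed-form least-squares oracle so the
frozen slope/r-squared come from an independent computation."""

import io
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirassign.assignment import (assign_peak, ch_linearity, intensity_ratio,
                                  load_band_library, shift_report,
                                  width_ordering)
from nirassign.preprocess import Peak
from nirassign.spectra import Spectrum, load_intensity_table

FOUR_LN2 = 4.0 * np.log(2.0)

# Peak absorbances of the methyl combination band against methyl C-H count
# (toluene 3; ortho/meta/para-xylene 6; mesitylene 9).
CH_POINTS = [(3, 0.4775), (6, 1.0287), (6, 1.0546), (6, 1.0237), (9, 1.6218)]


def ols_oracle(points):
    """Closed-form simple least squares (independent of scipy)."""
    x = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean(), sxy ** 2 / (sxx * syy)


class TestBandLibrary:
    def test_anthraquinone_intervals(self):
        lib = load_band_library()
        got = {(e.low_nm, e.high_nm) for e in lib
               if e.compound_class == "Anthraquinones"}
        assert got == {(1371, 1470), (1620, 1838), (1976, 2020), (2094, 2200)}

    def test_alkaloid_intervals_start_at_second_overtone(self):
        lib = load_band_library()
        got = sorted((e.low_nm, e.high_nm) for e in lib
                     if e.compound_class == "Alkaloids")
        assert got[0] == (1110, 1260)
        assert got == [(1110, 1260), (1370, 1495), (1620, 1820),
                       (2040, 2195), (2300, 2460)]

    def test_all_seven_compound_classes_present(self):
        lib = load_band_library()
        classes = {e.compound_class for e in lib if e.source == "Table 3"}
        assert classes == {"Anthraquinones", "Lignins", "Coumarins",
                           "Simple Phenylalanines", "Terpenes", "Alkaloids",
                           "Flavones"}

    def test_malformed_interval_rejected(self):
        bad = io.StringIO(
            "entries:\n- {group: x, band_nm: [1500, 1400], "
            "band_class: combination, source: 'Table 2'}\n")
        with pytest.raises(ValueError, match="malformed"):
            load_band_library(bad)

    def test_duplicate_entry_warns(self):
        dup = io.StringIO(
            "entries:\n"
            "- {group: x, band_nm: [1400, 1500], band_class: combination, source: 'Table 2'}\n"
            "- {group: x, band_nm: [1400, 1500], band_class: combination, source: 'Table 2'}\n")
        with pytest.warns(UserWarning, match="duplicate"):
            load_band_library(dup)


@pytest.fixture(scope="module")
def measured_library():
    """The theoretical + measured single-band attributions."""
    return [e for e in load_band_library()
            if e.source in ("Table 2", "Results text")]


class TestAssignPeak:

    def test_methylene_combination_at_1400(self, measured_library):
        entries = [e for e in measured_library if "methylene" in e.group]
        rec = assign_peak(1400.0, entries)
        assert rec.status == "assigned"
        top = rec.matches[0][0]
        assert top.band_class == "combination" and "C-H" in top.group

    def test_methyl_combination_at_2330(self, measured_library):
        rec = assign_peak(2330.0, measured_library)
        assert rec.status == "assigned"
        top = rec.matches[0][0]
        assert top.group == "C-H of methyl" and top.band_class == "combination"
        assert rec.matches[0][1] == pytest.approx(1.0)

    def test_out_of_library_peak_unassigned(self):
        rec = assign_peak(3000.0, load_band_library())
        assert rec.status == "unassigned" and rec.matches == ()

    def test_empty_library_unassigned(self):
        assert assign_peak(1400.0, []).status == "unassigned"

    @given(st.floats(800, 2600), st.floats(0, 30), st.floats(0, 30))
    def test_widening_tolerance_never_unassigns(self, pos, tol_a, tol_b):
        lib = load_band_library()
        lo, hi = sorted((tol_a, tol_b))
        before = assign_peak(pos, lib, lo).status
        after = assign_peak(pos, lib, hi).status
        if before in ("assigned", "ambiguous"):
            assert after in ("assigned", "ambiguous")

    def test_scores_clamped_to_unit_interval(self):
        for pos in (900.0, 1400.0, 1670.0, 2330.0, 2460.0):
            rec = assign_peak(pos, load_band_library(), tolerance_nm=25.0)
            assert all(0.0 <= s <= 1.0 for _, s in rec.matches)


class TestIntensityRatio:
    def test_table_ratios_round_to_printed_granularity(self):
        table = load_intensity_table()
        ratios = intensity_ratio(table, 2330, "toluene", round_to=0.5)
        assert ratios["Mesitylene"] == pytest.approx(3.5)
        xylene_mean = np.mean([1.0287, 1.0546, 1.0237]) / 0.4775
        assert round(xylene_mean / 0.5) * 0.5 == pytest.approx(2.0)
        assert ratios["Toluene"] == pytest.approx(1.0)

    def test_missing_cells_propagate(self):
        table = load_intensity_table()
        assert np.isnan(intensity_ratio(table, 2330, "toluene")["Benzene"])

    def test_reference_self_ratio_is_one_unrounded(self):
        table = load_intensity_table()
        for ref in ("Toluene", "Mesitylene", "Ortho-xylene"):
            assert intensity_ratio(table, 2330, ref)[ref] == 1.0

    def test_missing_reference_is_error(self):
        table = load_intensity_table()
        with pytest.raises(ValueError, match="no value"):
            intensity_ratio(table, 2330, "benzene")


class TestChLinearity:
    def test_measured_points_match_closed_form_oracle(self):
        slope_o, intercept_o, r2_o = ols_oracle(CH_POINTS)
        rep = ch_linearity(CH_POINTS)
        assert rep.slope == pytest.approx(slope_o, rel=1e-12)
        assert rep.intercept == pytest.approx(intercept_o, rel=1e-9)
        assert rep.r_squared == pytest.approx(r2_o, rel=1e-12)
        assert rep.slope == pytest.approx(0.1907, abs=2e-4)
        assert rep.r_squared >= 0.99

    def test_exact_proportionality(self):
        rep = ch_linearity([(3, 1.0), (6, 2.0), (9, 3.0)])
        assert rep.slope == pytest.approx(1 / 3)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.ratios_to_reference == (1.0, 2.0, 3.0)

    @given(st.floats(0.01, 100))
    def test_recovers_any_proportional_slope(self, k):
        rep = ch_linearity([(3, 3 * k), (6, 6 * k), (9, 9 * k)])
        assert rep.slope == pytest.approx(k, rel=1e-9)
        assert rep.r_squared == pytest.approx(1.0)

    def test_constant_intensity_degenerate(self):
        rep = ch_linearity([(3, 0.5), (6, 0.5), (9, 0.5)])
        assert rep.slope == 0.0 and rep.r_squared == 0.0

    def test_single_count_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ch_linearity([(6, 1.0), (6, 2.0)])


def peak(pos):
    return Peak(pos, 1.0, 1.0)


class TestShiftReport:
    def test_thirty_nm_skeleton_displacement(self):
        rep = shift_report([peak(1670.0)], {"mesitylene": [peak(1700.0)]})
        assert rep.pairs[0][3] == pytest.approx(30.0)

    def test_identical_peaks_zero_displacement(self):
        ref = [peak(1140.0), peak(1670.0)]
        rep = shift_report(ref, {"same": ref})
        assert all(p[3] == 0.0 for p in rep.pairs)

    def test_constructed_family_ordering(self):
        shifts = {"toluene": 5, "ortho-xylene": 10, "meta-xylene": 15,
                  "para-xylene": 20, "mesitylene": 30}
        comp = {name: [peak(1670.0 + d)] for name, d in shifts.items()}
        rep = shift_report([peak(1670.0)], comp)
        assert rep.ordering == ("toluene", "ortho-xylene", "meta-xylene",
                                "para-xylene", "mesitylene")

    def test_antisymmetric_under_swap(self):
        fwd = shift_report([peak(1670.0)], {"x": [peak(1700.0)]})
        rev = shift_report([peak(1700.0)], {"x": [peak(1670.0)]})
        assert fwd.pairs[0][3] == -rev.pairs[0][3]

    def test_unpaired_compound_flagged(self):
        rep = shift_report([peak(1670.0)], {"far": [peak(1900.0)]},
                           pairing_tolerance_nm=35.0)
        assert rep.unpaired == ("far",) and rep.pairs == ()


class TestWidthOrdering:
    @staticmethod
    def band_spectrum(center, fwhm, lo=1500.0, hi=1900.0):
        g = np.arange(lo, hi + 0.25, 0.5)
        return Spectrum(g, np.exp(-FOUR_LN2 * (g - center) ** 2 / fwhm ** 2))

    def test_constructed_steric_hindrance_ordering(self):
        widths = {"ortho-xylene": 40.0, "meta-xylene": 32.0,
                  "para-xylene": 26.0, "benzene": 20.0}
        spectra = {n: self.band_spectrum(1670.0, w) for n, w in widths.items()}
        rep = width_ordering(spectra, 1670.0, search_halfwidth_nm=80.0)
        assert rep.ordering == ("ortho-xylene", "meta-xylene",
                                "para-xylene", "benzene")
        for name, measured in rep.widths_nm:
            assert measured == pytest.approx(widths[name], abs=0.5)

    def test_identical_bands_reported_as_tie(self):
        spectra = {"a": self.band_spectrum(1670.0, 30.0),
                   "b": self.band_spectrum(1670.0, 30.0)}
        rep = width_ordering(spectra, 1670.0)
        assert rep.ties and set(rep.ties[0]) == {"a", "b"}

    def test_clipped_band_flagged_not_measured(self):
        spectra = {"clipped": self.band_spectrum(1730.0, 40.0)}
        rep = width_ordering(spectra, 1670.0, search_halfwidth_nm=50.0)
        assert rep.flagged == ("clipped",)
        assert rep.widths_nm == ()
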