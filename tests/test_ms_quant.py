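"""Unit tests for internal-standard MALDI quantification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import detbelt as db
from detbelt.ms_quant import ISOTOPE_ABUNDANCES, parse_formula


# ----------------------------------------------------------------------
# Spectrum I/O
# ----------------------------------------------------------------------


class TestReadSpectrum:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("100,5\n101,7\n")
        s = db.read_spectrum(p)
        assert s.mz.tolist() == [100, 101]
        assert s.intensity.tolist() == [5, 7]

    def test_sorting_and_duplicate_merge(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("101,7\n100,5\n100,2\n")
        s = db.read_spectrum(p)
        assert s.mz.tolist() == [100, 101]
        assert s.intensity.tolist() == [7, 7]

    def test_tsv_and_comments(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("# header\n100\t5\n101\t7\n\n")
        s = db.read_spectrum(p)
        assert len(s) == 2

    @pytest.mark.parametrize(
        "content, match",
        [
            ("", "no data rows"),
            ("# only comments\n", "no data rows"),
            ("100,abc\n", "non-numeric"),
            ("100,-5\n", "negative intensity"),
            ("100\n", "two columns"),
        ],
    )
    def test_parse_errors(self, tmp_path, content, match):
        p = tmp_path / "bad.csv"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            db.read_spectrum(p)

    def test_error_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("100,5\nx,y\n")
        with pytest.raises(ValueError, match=":2"):
            db.read_spectrum(p)


class TestSpectrumInvariants:
    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            db.Spectrum([2.0, 1.0], [1.0, 1.0])

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            db.Spectrum([1.0, 2.0], [1.0, -1.0])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            db.Spectrum([], [])


# ----------------------------------------------------------------------
# Isotope patterns
# ----------------------------------------------------------------------


def brute_force_pattern(formula: str, max_offset: int) -> np.ndarray:
    """Enumerate all isotopologue combinations atom by atom (oracle)."""
    atoms = []
    for el, n in parse_formula(formula).items():
        atoms.extend([el] * n)
    probs = np.zeros(max_offset + 1)
    choices = [range(len(ISOTOPE_ABUNDANCES[el])) for el in atoms]
    for combo in itertools.product(*choices):
        off = sum(combo)
        p = 1.0
        for el, c in zip(atoms, combo):
            p *= ISOTOPE_ABUNDANCES[el][c]
        if off <= max_offset:
            probs[off] += p
    return probs / probs.sum()


class TestIsotopePattern:
    @pytest.mark.parametrize("formula", ["CH4", "C2H2O", "H2O", "C3S", "CD3", "C2Cl2"])
    def test_matches_brute_force_enumeration(self, formula):
        pat = db.isotope_pattern(formula, max_offset=4)
        oracle = brute_force_pattern(formula, max_offset=4)
        assert np.allclose(pat.probs, oracle, atol=1e-12)

    def test_ch4_m_plus_1(self):
        # single 13C dominates the M+1 peak of methane
        pat = db.isotope_pattern("CH4", max_offset=3)
        expected_ratio = (
            0.0107 * 0.999885**4 + 0.9893 * 4 * 0.000115 * 0.999885**3
        ) / (0.9893 * 0.999885**4)
        assert pat.probs[1] / pat.probs[0] == pytest.approx(expected_ratio, rel=1e-9)

    @pytest.mark.parametrize("formula", ["C24H46O11", "C17H38NO4P", "C24H21D25O11"])
    def test_normalized(self, formula):
        pat = db.isotope_pattern(formula, max_offset=8)
        assert pat.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pat.probs >= 0)

    def test_deuterium_is_monoisotopic(self):
        # a pure-label formula has all mass in the first bin
        pat = db.isotope_pattern("D10", max_offset=3)
        assert pat.probs[0] == pytest.approx(1.0)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            db.isotope_pattern("Xx4", max_offset=2)

    def test_ddm_sodium_adduct_mz(self, ddm):
        # DDM flies as M+Na at m/z ~533; the deuterated form at ~558
        assert ddm.monoisotopic_mz == pytest.approx(533.3, abs=0.05)

    def test_fc12_proton_adduct_mz(self, fc12, fc12_d):
        assert fc12.monoisotopic_mz == pytest.approx(352.3, abs=0.05)
        assert fc12_d.monoisotopic_mz == pytest.approx(390.5, abs=0.05)


# ----------------------------------------------------------------------
# Peak integration
# ----------------------------------------------------------------------


class TestClusterAbundance:
    def test_flat_zero_spectrum(self):
        s = db.Spectrum(np.linspace(100, 110, 201), np.zeros(201))
        c = db.cluster_abundance(s, 105.0, window=0.5)
        assert c.abundance == 0.0
        assert c.sn == 0.0

    def test_gaussian_area(self):
        # windowed sum of a fine-grid Gaussian approximates area / step
        step = 0.001
        mz = np.arange(99.0, 101.0, step)
        area = 50.0
        sigma = 0.05
        inten = area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((mz - 100.0) / sigma) ** 2
        )
        c = db.cluster_abundance(db.Spectrum(mz, inten), 100.0, window=0.5)
        assert c.abundance * step == pytest.approx(area, rel=0.01)

    def test_sn_by_construction(self):
        rng = np.random.default_rng(0)
        mz = np.linspace(100, 120, 2001)
        noise = np.abs(rng.normal(0, 10.0, mz.size))
        sigma = float(np.std(noise[(mz >= 110) & (mz <= 120)]))
        inten = noise.copy()
        peak = 30.0 * sigma
        inten[np.argmin(np.abs(mz - 105.0))] += peak
        c = db.cluster_abundance(
            db.Spectrum(mz, inten), 105.0, window=0.5, noise_region=(110, 120)
        )
        assert c.sn == pytest.approx(30.0, rel=0.15)

    def test_noise_region_overlap_rejected(self):
        s = db.Spectrum(np.linspace(100, 110, 101), np.ones(101))
        with pytest.raises(ValueError, match="disjoint"):
            db.cluster_abundance(s, 105.0, window=1.0, noise_region=(104, 106))

    def test_empty_noise_region_rejected(self):
        s = db.Spectrum(np.linspace(100, 110, 101), np.ones(101))
        with pytest.raises(ValueError, match="no spectrum points"):
            db.cluster_abundance(s, 105.0, window=0.5, noise_region=(200, 210))


# ----------------------------------------------------------------------
# Unmixing
# ----------------------------------------------------------------------


class TestUnmixRatio:
    def test_block_diagonal_equals_window_sum_ratio(self):
        pat = db.IsotopePattern([0, 1], [0.8, 0.2])
        # standard envelope starts 5 bins later: no overlap
        observed = np.zeros(7)
        observed[0:2] = 3.0 * np.array([0.8, 0.2])
        observed[5:7] = 1.5 * np.array([0.8, 0.2])
        ratio = db.unmix_ratio(observed, pat, pat, offset_std=5)
        assert ratio == pytest.approx(observed[0:2].sum() / observed[5:7].sum(), rel=1e-12)

    def test_symmetric_overlap_gives_unity(self):
        pat = db.IsotopePattern([0, 1, 2], [0.6, 0.3, 0.1])
        observed = np.zeros(5)
        for off, p in zip(pat.offsets, pat.probs):
            observed[off] += 2.0 * p
            observed[off + 2] += 2.0 * p
        assert db.unmix_ratio(observed, pat, pat, offset_std=2) == pytest.approx(1.0, abs=1e-9)

    def test_constructed_overlap_recovers_planted_amplitudes(self):
        # ~20% of the measured envelope overlaps the standard's bins
        pat_m = db.IsotopePattern([0, 1, 2], [0.7, 0.2, 0.1])
        pat_s = db.IsotopePattern([0, 1], [0.9, 0.1])
        a_m, a_s = 4.2, 1.7
        observed = np.zeros(4)
        for off, p in zip(pat_m.offsets, pat_m.probs):
            observed[off] += a_m * p
        for off, p in zip(pat_s.offsets, pat_s.probs):
            observed[off + 2] += a_s * p
        ratio = db.unmix_ratio(observed, pat_m, pat_s, offset_std=2)
        assert ratio == pytest.approx(a_m / a_s, rel=1e-6)

    def test_missing_standard_rejected(self):
        pat = db.IsotopePattern([0], [1.0])
        observed = np.array([5.0, 0.0])
        with pytest.raises(ValueError, match="standard not detected"):
            db.unmix_ratio(observed, pat, pat, offset_std=1)


# ----------------------------------------------------------------------
# Calibration, quantification, conversions
# ----------------------------------------------------------------------

DESIGN_POINTS = [(0.0, 0.0), (0.3, 0.03), (1.0, 0.1), (3.0, 0.3)]


class TestCalibration:
    def test_standard_design_slope(self):
        curve = db.fit_calibration(DESIGN_POINTS, standard_conc=0.1)
        assert curve.slope == pytest.approx(0.1, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0)

    def test_lmng_slope(self):
        # LMNG desorbs less efficiently than its DMNG standard: slope 0.143
        pts = [(r, 0.143 * r) for r in (0.0, 0.3, 1.0, 3.0)]
        curve = db.fit_calibration(pts, standard_conc=0.1)
        assert curve.slope == pytest.approx(0.143, abs=1e-12)

    def test_two_points_interpolate(self):
        curve = db.fit_calibration([(0.0, 0.0), (2.0, 0.5)], standard_conc=0.1)
        assert curve.slope == pytest.approx(0.25)
        assert curve.r2 == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            db.fit_calibration([(1.0, 0.1), (1.0, 0.2)], standard_conc=0.1)

    def test_design_points_round_trip(self):
        # quantify(fit(points)) returns each design concentration exactly
        curve = db.fit_calibration(DESIGN_POINTS, standard_conc=0.1)
        for ratio, conc in DESIGN_POINTS:
            assert db.quantify(ratio, curve).conc_pct == pytest.approx(conc, abs=1e-12)


class TestQuantify:
    def test_unit_ratio_returns_standard_conc(self):
        curve = db.CalibrationCurve(slope=0.1, intercept=0.0, r2=1.0, standard_conc=0.1)
        assert db.quantify(1.0, curve).conc_pct == pytest.approx(0.1)
        assert db.quantify(3.0, curve).conc_pct == pytest.approx(0.3)
        assert db.quantify(0.0, curve).conc_pct == 0.0

    def test_negative_concentration_clipped_with_warning(self):
        curve = db.CalibrationCurve(slope=0.1, intercept=-0.05, r2=0.99, standard_conc=0.1)
        with pytest.warns(UserWarning, match="clipped"):
            res = db.quantify(0.0, curve)
        assert res.conc_pct == 0.0

    def test_sn_flags(self):
        curve = db.CalibrationCurve(slope=0.1, intercept=0.0, r2=1.0, standard_conc=0.1)
        res = db.quantify(1.0, curve, sn=5.0)
        assert res.above_lod and not res.above_loq
        res = db.quantify(1.0, curve, sn=50.0)
        assert res.above_lod and res.above_loq


class TestConversions:
    @pytest.mark.parametrize(
        "pct, mw, expected",
        [(0.2, 510.6, 3.9169), (0.0, 510.6, 0.0), (1.0, 1000.0, 10.0)],
    )
    def test_pct_to_molar(self, pct, mw, expected):
        assert db.pct_to_molar(pct, mw) == pytest.approx(expected, rel=1e-4)

    def test_baseline_correct(self):
        assert db.baseline_correct(3.7, 0.0) == 3.7
        assert db.baseline_correct(5.0, 1.2) == pytest.approx(3.8)

    def test_baseline_floor_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            assert db.baseline_correct(1.0, 1.5) == 0.0


# ----------------------------------------------------------------------
# Stoichiometry
# ----------------------------------------------------------------------


class TestStoichiometry:
    @pytest.mark.parametrize(
        "det_mm, prot_um, expected",
        [(0.934, 6.03, 155), (11.4, 38.0, 300), (5.7, 12.3, 463), (1.0, 1000.0, 1)],
    )
    def test_rounded_ratio(self, det_mm, prot_um, expected):
        assert db.stoichiometry(det_mm, prot_um).ratio_rounded == expected

    def test_raw_ratio(self):
        rec = db.stoichiometry(0.934, 6.03)
        assert rec.ratio == pytest.approx(0.934 * 1000 / 6.03)

    def test_half_rounds_away_from_zero(self):
        assert db.stoichiometry(0.0105, 21.0).ratio_rounded == 1  # ratio 0.5

    def test_nonpositive_protein_rejected(self):
        with pytest.raises(ValueError):
            db.stoichiometry(1.0, 0.0)


# ----------------------------------------------------------------------
# Detection limits, QC, CV, SEC
# ----------------------------------------------------------------------


class TestDetectionLimits:
    def test_constructed_dilution_series(self):
        # S/N = 100/dilution; concentration = 1/dilution
        series = [(1.0 / d, 100.0 / d) for d in range(1, 101)]
        lim = db.detection_limits(series)
        assert lim.loq == pytest.approx(1.0 / 10)
        assert lim.lod == pytest.approx(1.0 / 33)

    def test_all_below_threshold(self):
        lim = db.detection_limits([(1.0, 2.0), (0.5, 1.0)])
        assert lim.lod is None and lim.loq is None

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        series = [(c, 50.0 * c + rng.uniform(0, 1)) for c in np.linspace(0.01, 1, 40)]
        prev = -np.inf
        for thr in (1.0, 3.0, 10.0, 30.0):
            lim = db.detection_limits(series, lod_sn=thr, loq_sn=thr).lod
            if lim is None:
                lim = np.inf
            assert lim >= prev
            prev = lim


class TestQC:
    @pytest.mark.parametrize(
        "peak, window, expected",
        [
            (15_000, (1_000, 30_000), True),   # DDM auto-acquisition window
            (500, (1_000, 30_000), False),
            (1_000, (1_000, 30_000), True),    # inclusive lower bound
            (30_000, (1_000, 30_000), True),   # inclusive upper bound
            (20_000, (10_000, 40_000), True),  # FC12 window
        ],
    )
    def test_window(self, peak, window, expected):
        assert db.qc_accept(peak, window) is expected

    def test_accepts_cluster(self):
        c = db.PeakCluster(abundance=100.0, sn=20.0, peak_max=15_000.0)
        assert db.qc_accept(c, (1_000, 30_000))

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            db.qc_accept(10, (5, 5))


class TestReplicateCV:
    def test_identical_values(self):
        intra, inter = db.replicate_cv([[5.0, 5.0, 5.0]] * 3)
        assert intra == 0.0 and inter == 0.0

    def test_single_day_definition(self):
        vals = [9.0, 10.0, 11.0]
        intra, _ = db.replicate_cv([vals])
        assert intra == pytest.approx(np.std(vals, ddof=1) / np.mean(vals) * 100)

    def test_inter_day_hand_computed(self):
        groups = [[9.9, 10.1], [11.9, 12.1], [13.9, 14.1]]
        _, inter = db.replicate_cv(groups)
        means = np.array([10.0, 12.0, 14.0])
        assert inter == pytest.approx(means.std(ddof=1) / means.mean() * 100)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            db.replicate_cv([[1.0]])


class TestSecMw:
    CAL = [(10.0, 400.0), (12.0, 100.0), (14.0, 25.0), (16.0, 6.25)]

    def test_query_at_standard(self):
        assert db.sec_mw(12.0, self.CAL) == pytest.approx(100.0, rel=1e-9)

    def test_midpoint_geometric_mean(self):
        mw = db.sec_mw(11.0, self.CAL)
        assert mw == pytest.approx(math.sqrt(400.0 * 100.0), rel=1e-9)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            db.sec_mw(20.0, self.CAL)

    def test_too_few_standards(self):
        with pytest.raises(ValueError):
            db.sec_mw(12.0, [(10.0, 400.0)])


# ----------------------------------------------------------------------
# Property: windowed-sum ratio equals unmix on non-overlapping envelopes
# ----------------------------------------------------------------------


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a_m=st.floats(0.1, 100),
    a_s=st.floats(0.1, 100),
    gap=st.integers(4, 20),
)
def test_unmix_block_diagonal_property(a_m, a_s, gap):
    """Non-overlapping envelopes reduce unmixing to the simple sum ratio."""
    pat = db.IsotopePattern([0, 1, 2], [0.7, 0.2, 0.1])
    observed = np.zeros(gap + 3)
    for off, p in zip(pat.offsets, pat.probs):
        observed[off] += a_m * p
        observed[off + gap] += a_s * p
    ratio = db.unmix_ratio(observed, pat, pat, offset_std=gap)
    assert ratio == pytest.approx(a_m / a_s, rel=1e-9)
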