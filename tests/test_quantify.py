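"""EIC extraction, stoichiometry recovery, adduct fallback and table statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypquant.peptides import HINGE_PEPTIDE
from hypquant.quantify import (
    EIC,
    average_hyp,
    detect_adduct_overlap,
    extract_eic,
    integrate_peak,
    percent_change,
    quantify_stoichiometry,
    quantify_stoichiometry_monoiso,
)
from hypquant.synthetic_data import GroundTruth, ScanSet, simulate_lcms_run


def make_scanset(rts, peak_lists):
    return ScanSet(
        tuple(
            (rt, np.array([m for m, _ in peaks]), np.array([i for _, i in peaks]))
            for rt, peaks in zip(rts, peak_lists)
        )
    )


class TestEic:
    def test_peak_at_target_fully_captured(self):
        scans = make_scanset([1.0, 2.0, 3.0], [[(500.0, 10.0)], [(500.0, 20.0)], [(500.0, 5.0)]])
        eic = extract_eic(scans, 500.0, 10.0)
        np.testing.assert_array_equal(eic.intensity, [10.0, 20.0, 5.0])

    def test_peak_outside_window_excluded(self):
        offset = 500.0 * 20e-6  # 2x a 10 ppm window
        scans = make_scanset([1.0, 2.0], [[(500.0 + offset, 10.0)], [(500.0 + offset, 10.0)]])
        eic = extract_eic(scans, 500.0, 10.0)
        assert eic.intensity.sum() == 0.0

    def test_co_eluting_species_one_mz_apart_independent(self):
        scans = make_scanset(
            [1.0, 2.0], [[(500.0, 10.0), (501.0, 7.0)], [(500.0, 10.0), (501.0, 7.0)]]
        )
        assert extract_eic(scans, 500.0, 10.0).intensity.tolist() == [10.0, 10.0]
        assert extract_eic(scans, 501.0, 10.0).intensity.tolist() == [7.0, 7.0]


class TestIntegratePeak:
    def test_rectangle(self):
        eic = EIC(500.0, 10.0, np.array([0.0, 1.0, 2.0]), np.array([3.0, 3.0, 3.0]))
        assert integrate_peak(eic) == pytest.approx(6.0)

    def test_gaussian_area(self):
        rt = np.arange(0, 10, 0.01)
        sigma, area = 0.3, 123.0
        trace = area * np.exp(-0.5 * ((rt - 5.0) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        eic = EIC(500.0, 10.0, rt, trace)
        assert integrate_peak(eic) == pytest.approx(area, rel=1e-3)

    def test_zero_width_window(self):
        eic = EIC(500.0, 10.0, np.array([0.0, 1.0, 2.0]), np.array([3.0, 3.0, 3.0]))
        assert integrate_peak(eic, (1.0, 1.0)) == 0.0

    def test_inverted_window_raises(self):
        eic = EIC(500.0, 10.0, np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="inverted"):
            integrate_peak(eic, (1.0, 0.0))


class TestStoichiometryRecovery:
    def test_noiseless_recovery(self, noiseless_run, control_fractions):
        _, scans = noiseless_run
        dist = quantify_stoichiometry(scans, HINGE_PEPTIDE, 6)
        np.testing.assert_allclose(
            np.array(dist.fractions_percent) / 100, control_fractions, atol=1e-3
        )

    def test_single_species_is_100_percent(self):
        truth = GroundTruth(peptide=HINGE_PEPTIDE, stoichiometry=(1.0, 0.0, 0.0), seed=0)
        dist = quantify_stoichiometry(simulate_lcms_run(truth), HINGE_PEPTIDE, 2)
        assert dist.fractions_percent[0] == pytest.approx(100.0, abs=1e-6)

    def test_monoiso_agrees_without_adducts(self, noiseless_run):
        _, scans = noiseless_run
        four = quantify_stoichiometry(scans, HINGE_PEPTIDE, 6)
        mono = quantify_stoichiometry_monoiso(scans, HINGE_PEPTIDE, 6)
        np.testing.assert_allclose(
            np.array(four.fractions_percent), np.array(mono.fractions_percent), atol=0.1
        )

    def test_empty_run_raises(self):
        scans = make_scanset([1.0, 2.0], [[(100.0, 5.0)], [(100.0, 5.0)]])
        with pytest.raises(ValueError, match="empty quantification"):
            quantify_stoichiometry(scans, HINGE_PEPTIDE, 6)

    def test_noisy_recovery_stays_within_two_points(self, control_fractions):
        errors = []
        for seed in range(1, 21):
            truth = GroundTruth(
                peptide=HINGE_PEPTIDE, stoichiometry=tuple(control_fractions),
                noise_cv=0.02, seed=seed,
            )
            dist = quantify_stoichiometry(simulate_lcms_run(truth), HINGE_PEPTIDE, 6)
            rec = np.array(dist.fractions_percent) / 100
            errors.append(np.abs(rec - control_fractions).mean())
        assert np.mean(errors) < 0.02

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=7),
        st.integers(0, 2**16),
    )
    @settings(max_examples=5, deadline=None)
    def test_recovery_for_random_stoichiometries(self, raw, seed):
        f = np.array(raw) / np.sum(raw)
        truth = GroundTruth(peptide=HINGE_PEPTIDE, stoichiometry=tuple(f), seed=seed)
        dist = quantify_stoichiometry(simulate_lcms_run(truth), HINGE_PEPTIDE, len(f) - 1)
        np.testing.assert_allclose(np.array(dist.fractions_percent) / 100, f, atol=1e-3)


class TestAdductFallback:
    def test_overlap_flagged_at_wide_tolerance(self):
        # adduct vs +1 isotope gap is ~0.014 m/z at charge 2; the hinge
        # peptide sits near m/z 2069 where 10 ppm ≈ 0.021 m/z
        flags = detect_adduct_overlap(HINGE_PEPTIDE, 6, (2,), tolerance_ppm=10.0)
        assert (1, 2) in flags

    def test_no_overlap_at_one_ppm(self):
        assert detect_adduct_overlap(HINGE_PEPTIDE, 6, (2, 3), tolerance_ppm=1.0) == []

    def test_monoiso_beats_four_peak_under_adducts(self, control_fractions):
        """With 20% ammonium-adduct signal the monoisotopic-only mode must
        recover the truth while four-peak summation is biased upward for
        the contaminated species — on every seed."""
        for seed in range(1, 11):
            truth = GroundTruth(
                peptide=HINGE_PEPTIDE, stoichiometry=tuple(control_fractions),
                adduct_fraction=0.2, noise_cv=0.02, seed=seed,
            )
            scans = simulate_lcms_run(truth)
            four = np.array(quantify_stoichiometry(scans, HINGE_PEPTIDE, 6).fractions_percent)
            mono = np.array(
                quantify_stoichiometry_monoiso(scans, HINGE_PEPTIDE, 6).fractions_percent
            )
            err_four = np.abs(four / 100 - control_fractions).max()
            err_mono = np.abs(mono / 100 - control_fractions).max()
            assert err_mono < err_four
            assert err_mono < 0.02


class TestTableStatistics:
    # printed percentage rows and their published statistics
    ROWS = [
        ((26.3, 27.9, 23.9, 16.0, 4.8, 1.1, 0.1), 1.49),
        ((9.6, 12.5, 17.2, 25.4, 25.5, 8.0, 1.7), 2.75),
        ((32.0, 28.4, 19.9, 13.7, 4.8, 1.2, 0.1), 1.35),
        ((20.7, 23.5, 21.8, 20.9, 9.7, 2.9, 0.3), 1.85),
        ((18.0, 23.1, 27.4, 19.6, 8.3, 3.1, 0.5), 1.88),
        ((35.2, 31.0, 19.7, 6.6, 4.0, 1.9, 1.7), 1.26),
        ((31.5, 31.0, 20.5, 10.8, 4.2, 1.4, 0.7), 1.32),
        ((32.2, 30.7, 18.8, 11.4, 5.2, 1.5, 0.3), 1.33),
        ((23.1, 30.5, 23.6, 14.4, 6.1, 1.9, 0.4), 1.57),
        ((36.9, 31.5, 17.1, 8.9, 4.1, 1.3, 0.2), 1.17),
        ((50.5, 27.0, 13.7, 6.0, 2.5, 0.4, 0.0), 0.84),
    ]

    @pytest.mark.parametrize("fractions,expected", ROWS)
    def test_average_hyp_reproduces_published_values(self, fractions, expected):
        assert average_hyp(fractions) == expected

    def test_average_uses_percentages_as_printed(self):
        # the overexpression row sums to 99.9; renormalizing would give 2.76
        assert average_hyp((9.6, 12.5, 17.2, 25.4, 25.5, 8.0, 1.7)) == 2.75

    def test_rounding_half_away_from_zero(self):
        assert average_hyp((0.0, 100.0 * 1.165 / 1.0)) != 1.16  # 1.165 -> 1.17
        assert average_hyp((100, 0, 0)) == 0.0

    def test_negative_fraction_raises(self):
        with pytest.raises(ValueError):
            average_hyp((-1.0, 101.0))

    @pytest.mark.parametrize(
        "av,control,expected", [(0.844, 1.326, 64), (1.572, 1.326, 119), (1.165, 1.326, 88), (1.0, 1.0, 100)]
    )
    def test_percent_change(self, av, control, expected):
        assert percent_change(av, control) == expected

    def test_percent_change_zero_control_raises(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=7).filter(lambda f: sum(f) > 0))
    @settings(max_examples=60, deadline=None)
    def test_average_bounded_by_species_range(self, fractions):
        total = sum(fractions)
        scaled = [100.0 * f / total for f in fractions]
        av = average_hyp(scaled)
        assert 0.0 <= av <= len(fractions) - 1
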