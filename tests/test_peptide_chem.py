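"""Peptide mass arithmetic, isotope envelopes, digestion and oxoforms.

Masses are cross-checked against pyteomics (an independent implementation
over its own constants table); isotope envelopes against a naive per-atom
convolution oracle written here.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyteomics_mass
from pyteomics import parser as pyteomics_parser

from hypquant.constants import ISOTOPES, PROTON_MASS, WATER_MASS
from hypquant.peptide_chem import (
    CARBAMIDOMETHYL,
    OXIDATION,
    ElementalComposition,
    Modification,
    Peptidoform,
    elemental_composition,
    enumerate_oxoforms,
    isotope_distribution,
    monoisotopic_mass,
    mz,
    proline_sites,
    tryptic_digest,
)
from hypquant.peptides import HINGE_PEPTIDE, IGA1, INTERNAL_STANDARD

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=30)


class TestElementalComposition:
    def test_glycine_is_residue_plus_water(self):
        comp = elemental_composition(Peptidoform("G"))
        assert comp.counts == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_diproline_matches_per_atom_summation(self):
        # independent oracle: add atom counts residue-by-residue
        expect = {"C": 10, "H": 16, "N": 2, "O": 3}  # 2×C5H7NO + H2O
        assert elemental_composition(Peptidoform("PP")).counts == expect

    def test_carbamidomethyl_adds_c2h3no(self):
        plain = elemental_composition(Peptidoform("C"))
        modded = elemental_composition(Peptidoform("C", ((1, CARBAMIDOMETHYL),)))
        assert (modded - plain).counts == {"C": 2, "H": 3, "N": 1, "O": 1}

    def test_unknown_residue_names_letter_and_position(self):
        with pytest.raises(ValueError, match="'B' at position 2"):
            Peptidoform("ABC")

    def test_subtraction_below_zero_raises(self):
        with pytest.raises(ValueError, match="negative count"):
            ElementalComposition({"C": 1}) - {"C": 2}

    def test_modification_mass_must_match_composition(self):
        with pytest.raises(ValueError, match="differs"):
            Modification("bad", 16.5, {"O": 1}, frozenset("P"))


class TestMonoisotopicMass:
    def test_hinge_peptide_protonated_mass(self):
        """The carbamidomethylated hinge tryptic peptide weighs 4136.8899 Da as [M+H]+."""
        pf = Peptidoform.with_fixed_cam(HINGE_PEPTIDE)
        assert mz(monoisotopic_mass(pf), 1) == pytest.approx(4136.8899, abs=5e-5)

    @pytest.mark.parametrize("seq", [IGA1, INTERNAL_STANDARD, "GG", "PEPTIDE"])
    def test_agrees_with_pyteomics(self, seq):
        ours = monoisotopic_mass(Peptidoform(seq))
        theirs = pyteomics_mass.calculate_mass(sequence=seq, monoisotopic=True)
        assert ours == pytest.approx(theirs, abs=1e-4)

    @given(a=sequences, b=sequences)
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, a, b):
        total = monoisotopic_mass(Peptidoform(a + b))
        parts = monoisotopic_mass(Peptidoform(a)) + monoisotopic_mass(Peptidoform(b))
        assert total == pytest.approx(parts - WATER_MASS, abs=1e-9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            Peptidoform("")


class TestMz:
    def test_oxidation_shift_per_charge(self):
        """One oxidation shifts m/z by ~16, ~8 and ~5.3 at z = 1, 2, 3."""
        m = monoisotopic_mass(Peptidoform(IGA1))
        shifts = {z: mz(m + OXIDATION.mass_shift, z) - mz(m, z) for z in (1, 2, 3)}
        assert round(shifts[1]) == 16
        assert round(shifts[2]) == 8
        assert round(shifts[3], 1) == 5.3
        assert shifts[2] == pytest.approx(15.994915 / 2, abs=1e-9)

    def test_protonation_definition(self):
        assert mz(1000.0, 1) == pytest.approx(1000.0 + PROTON_MASS, abs=1e-9)

    def test_strictly_decreasing_in_charge(self):
        m = 2000.0
        values = [mz(m, z) for z in range(1, 6)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("charge", [0, -1])
    def test_nonpositive_charge_raises(self, charge):
        with pytest.raises(ValueError):
            mz(1000.0, charge)


def envelope_oracle(counts: dict[str, int], n_peaks: int) -> np.ndarray:
    """Brute-force per-atom polynomial expansion of the aggregated envelope."""
    poly = np.array([1.0])
    for element, n in counts.items():
        offsets = [o for o, _, _ in ISOTOPES[element]]
        single = np.zeros(max(offsets) + 1)
        for offset, _, abundance in ISOTOPES[element]:
            single[offset] = abundance
        for _ in range(n):  # one atom at a time, no exponentiation shortcuts
            poly = np.convolve(poly, single)
    out = np.zeros(n_peaks)
    head = poly[:n_peaks]
    out[: len(head)] = head
    return out / out.sum()


class TestIsotopeDistribution:
    def test_single_carbon(self):
        env = isotope_distribution(ElementalComposition({"C": 1}), 2)
        assert env.peaks == ((0, 0.9893), (1, 0.0107))

    @given(
        st.fixed_dictionaries(
            {},
            optional={el: st.integers(1, 8) for el in "CHNOS"},
        ).filter(bool)
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_bruteforce_oracle_on_small_compositions(self, counts):
        ours = isotope_distribution(ElementalComposition(counts), 5).abundances
        theirs = envelope_oracle(counts, 5)
        assert np.abs(ours - theirs).max() < 1e-9

    def test_iga1_envelope_matches_oracle(self):
        comp = elemental_composition(Peptidoform(IGA1))
        ours = isotope_distribution(comp, 6).abundances
        theirs = envelope_oracle(comp.counts, 6)
        assert np.abs(ours - theirs).max() < 1e-9

    def test_abundances_sum_to_one(self):
        comp = elemental_composition(Peptidoform.with_fixed_cam(HINGE_PEPTIDE))
        for n in (1, 4, 10):
            env = isotope_distribution(comp, n)
            assert env.abundances.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_element_raises(self):
        with pytest.raises(ValueError, match="no isotope table"):
            isotope_distribution(ElementalComposition({"Fe": 1}), 4)


class TestTrypticDigest:
    def test_proline_suppresses_cleavage(self):
        assert [f.sequence for f in tryptic_digest("AKPR")] == ["AKPR"]

    def test_basic_cleavage(self):
        frags = tryptic_digest("AKGR")
        assert [(f.sequence, f.start, f.end) for f in frags] == [("AK", 1, 2), ("GR", 3, 4)]

    def test_missed_cleavage_unions(self):
        got = {f.sequence for f in tryptic_digest("AKGR", missed_cleavages=1)}
        # oracle: enumerate unions of <=2 adjacent fully-cleaved fragments
        base = ["AK", "GR"]
        expect = {
            "".join(base[i : j + 1])
            for i, j in itertools.combinations_with_replacement(range(len(base)), 2)
            if j - i <= 1
        }
        assert got == expect

    @given(sequences)
    @settings(max_examples=60, deadline=None)
    def test_fragments_reconstruct_input(self, seq):
        frags = tryptic_digest(seq, 0)
        assert "".join(f.sequence for f in frags) == seq
        assert frags[0].start == 1 and frags[-1].end == len(seq)

    @given(sequences)
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_pyteomics_cleave(self, seq):
        ours = sorted(f.sequence for f in tryptic_digest(seq, 0))
        theirs = sorted(
            pyteomics_parser.cleave(seq, pyteomics_parser.expasy_rules["trypsin"], 0)
        )
        # pyteomics returns unique peptides; compare as sets with multiplicity folded
        assert set(ours) == set(theirs)


class TestEnumerateOxoforms:
    def test_zero_oxidations_single_form(self):
        forms = enumerate_oxoforms(IGA1, n_ox=0, fixed_cam=False)
        assert len(forms) == 1 and forms[0].mods == ()

    def test_iga1_two_of_seven_sites(self):
        sites = (9, 10, 12, 14, 17, 18, 20)
        forms = enumerate_oxoforms(IGA1, sites, n_ox=2)
        assert len(forms) == 21  # C(7, 2)
        placements = [f.mod_positions("ox") for f in forms]
        assert placements == sorted(placements)  # deterministic lexicographic

    def test_too_many_oxidations_raises(self):
        with pytest.raises(ValueError):
            enumerate_oxoforms(IGA1, (9, 10), n_ox=3)

    def test_non_proline_site_raises(self):
        with pytest.raises(ValueError, match="not a proline"):
            enumerate_oxoforms(IGA1, (1,), n_ox=1)

    def test_proline_site_census(self):
        assert len(proline_sites(IGA1)) == 10
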