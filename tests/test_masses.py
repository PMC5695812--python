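"""Exact-mass arithmetic: anchors, adduct shifts, peptides, and properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covkit.masses import (
    CARBAMIDOMETHYL,
    HCL,
    Formula,
    IonSpec,
    PeptideSpec,
    adduct_mass_shift,
    formula_mass,
    ion_mz,
    parse_formula,
    peptide_neutral_mass,
)
from covkit._masstables import ELEMENT_MASSES, PROTON_MASS, RESIDUE_MASSES

J02 = parse_formula("C21H19N2O5Cl")


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C21H19N2O5Cl", {"C": 21, "H": 19, "N": 2, "O": 5, "Cl": 1}),
            ("H2O", {"H": 2, "O": 1}),
            ("C9H11N2OCl", {"C": 9, "H": 11, "N": 2, "O": 1, "Cl": 1}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_compositions(self, text, expected):
        assert dict(parse_formula(text).composition) == expected

    @pytest.mark.parametrize("bad", ["", "Xx2", "C0", "c2h4", "C2Qz"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestFormulaMass:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C9H11N2OCl", 198.0560),  # free-amine intermediate, neutral
            ("H2O", 18.0106),
            ("C21H19N2O5Cl", 414.0983),  # the chloroacetamide lead itself
        ],
    )
    def test_monoisotopic_anchors(self, text, expected):
        assert formula_mass(parse_formula(text)) == pytest.approx(expected, abs=5e-4)

    def test_additivity_spot(self):
        a, b = parse_formula("C6H12O6"), parse_formula("H2O")
        assert formula_mass(a + b) == pytest.approx(formula_mass(a) + formula_mass(b), abs=1e-9)

    def test_subtraction_negative_count_raises(self):
        with pytest.raises(ValueError, match="negative"):
            parse_formula("CH4") - parse_formula("H5")


@st.composite
def formulas(draw):
    symbols = draw(
        st.lists(st.sampled_from(sorted(ELEMENT_MASSES)), min_size=1, max_size=5, unique=True)
    )
    return Formula({s: draw(st.integers(1, 40)) for s in symbols})


@settings(derandomize=True, max_examples=100)
@given(formulas(), formulas())
def test_formula_mass_additive(a, b):
    """Mass of a combined composition is the sum of part masses, both conventions."""
    for mass_type in ("monoisotopic", "average"):
        assert formula_mass(a + b, mass_type) == pytest.approx(
            formula_mass(a, mass_type) + formula_mass(b, mass_type), abs=1e-9
        )


class TestIonMz:
    def test_sodiated_lead_matches_hrms_calcd(self):
        assert ion_mz(formula_mass(J02), IonSpec.sodiated()) == pytest.approx(437.0880, abs=5e-4)

    def test_protonated_intermediate_matches_hrms_calcd(self):
        neutral = formula_mass(parse_formula("C12H10O5"))
        assert neutral == pytest.approx(234.0528, abs=5e-4)
        assert ion_mz(neutral, IonSpec.protonated()) == pytest.approx(235.0606, abs=5e-4)

    def test_triply_protonated(self):
        mz = ion_mz(1958.9423, IonSpec.protonated(3, bare_proton=True))
        assert mz == pytest.approx(653.9880, abs=5e-4)

    def test_charge_and_carrier_validation(self):
        with pytest.raises(ValueError):
            IonSpec(("H",), 0)
        with pytest.raises(ValueError):
            IonSpec(("H", "H"), 1)
        with pytest.raises(ValueError):
            ion_mz(-5.0, IonSpec.protonated())

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1.0, 1e5), st.integers(1, 6))
    def test_proton_arithmetic_inverts_exactly(self, neutral, z):
        """z * m/z - z * proton mass recovers the neutral mass exactly."""
        mz = ion_mz(neutral, IonSpec.protonated(z, bare_proton=True))
        assert z * mz - z * PROTON_MASS == pytest.approx(neutral, rel=1e-12)


class TestPeptideMass:
    def test_glycine(self):
        assert peptide_neutral_mass(PeptideSpec("G")) == pytest.approx(75.0320, abs=5e-4)

    def test_active_site_tryptic_peptide(self):
        assert peptide_neutral_mass(PeptideSpec("VVVFIKPTCPYCR")) == pytest.approx(
            1523.7992, abs=5e-4
        )

    def test_adducted_carbamidomethylated_peptide(self):
        spec = PeptideSpec("VVVFIKPTCPYCR", [(9, 378.1216), (12, 57.0215)])
        assert peptide_neutral_mass(spec) == pytest.approx(1958.9423, abs=1e-3)

    def test_formula_shifts_match_raw_deltas(self):
        raw = PeptideSpec("VVVFIKPTCPYCR", [(12, 57.02146)])
        frm = PeptideSpec("VVVFIKPTCPYCR", [(12, CARBAMIDOMETHYL)])
        assert peptide_neutral_mass(raw) == pytest.approx(peptide_neutral_mass(frm), abs=1e-4)

    @pytest.mark.parametrize(
        "seq,mods",
        [("VVB", []), ("VV", [(3, 1.0)]), ("VV", [(1, 1.0), (1, 2.0)]), ("", [])],
    )
    def test_invalid_specs_rejected(self, seq, mods):
        with pytest.raises(ValueError):
            PeptideSpec(seq, mods)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.text(alphabet=sorted(RESIDUE_MASSES), min_size=1, max_size=20),
        st.text(alphabet=sorted(RESIDUE_MASSES), min_size=1, max_size=20),
    )
    def test_concatenation_loses_one_water(self, left, right):
        water = formula_mass(parse_formula("H2O"))
        whole = peptide_neutral_mass(PeptideSpec(left + right))
        parts = peptide_neutral_mass(PeptideSpec(left)) + peptide_neutral_mass(PeptideSpec(right))
        assert whole == pytest.approx(parts - water, abs=1e-9)


class TestAdductShift:
    def test_dechlorinated_lead_on_cysteine(self):
        # chloroacetamide alkylation: the warhead adds the lead minus HCl
        assert adduct_mass_shift(J02, HCL) == pytest.approx(378.1216, abs=5e-4)

    def test_average_mass_shift(self):
        assert adduct_mass_shift(J02, HCL, "average") == pytest.approx(378.38, abs=5e-3)

    def test_empty_leaving_group_is_identity(self):
        assert adduct_mass_shift(J02, None) == formula_mass(J02)

    def test_impossible_leaving_group_raises(self):
        with pytest.raises(ValueError):
            adduct_mass_shift(parse_formula("CH4"), parse_formula("Cl2"))


def test_masses_agree_with_pyteomics_reference():
    """Independent cross-check of the shipped tables against pyteomics."""
    pyteomics_mass = pytest.importorskip("pyteomics.mass")
    assert peptide_neutral_mass(PeptideSpec("VVVFIKPTCPYCR")) == pytest.approx(
        pyteomics_mass.calculate_mass(sequence="VVVFIKPTCPYCR"), abs=1e-3
    )
    assert formula_mass(J02) == pytest.approx(
        pyteomics_mass.calculate_mass(formula="C21H19N2O5Cl"), abs=1e-3
    )


def test_observed_parent_ion_bracketed_by_mass_conventions():
    """The +3 parent ion of the modified active-site peptide: the observed
    654.3 lies between the monoisotopic and average m/z, each within 0.5."""
    shift_mono = adduct_mass_shift(J02, HCL, "monoisotopic")
    shift_avg = adduct_mass_shift(J02, HCL, "average")
    mono = ion_mz(
        peptide_neutral_mass(
            PeptideSpec("VVVFIKPTCPYCR", [(9, shift_mono), (12, CARBAMIDOMETHYL)])
        ),
        IonSpec.protonated(3),
        "monoisotopic",
    )
    avg = ion_mz(
        peptide_neutral_mass(
            PeptideSpec("VVVFIKPTCPYCR", [(9, shift_avg), (12, CARBAMIDOMETHYL)]), "average"
        ),
        IonSpec.protonated(3),
        "average",
    )
    assert mono <= 654.3 <= avg
    assert math.isclose(mono, 654.3, abs_tol=0.5)
    assert math.isclose(avg, 654.3, abs_tol=0.5)
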