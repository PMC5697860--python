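"""Elemental-composition arithmetic, masses and m/z with electron bookkeeping."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as ptmass

from liponom.chem import (
    ELECTRON_MASS,
    ChargeState,
    ElementalComposition,
    FormulaError,
    IsotopeLabelSpec,
    LabelError,
    apply_label,
    monoisotopic_mass,
    mz,
    nominal_mass,
    parse_formula,
)

# -- parsing ----------------------------------------------------------------


def test_parse_formula_counts():
    c = parse_formula("C5H15NO4P")
    assert {sym: c[sym] for sym in "CHNOP"} == {"C": 5, "H": 15, "N": 1, "O": 4, "P": 1}


def test_parse_empty_is_identity():
    assert parse_formula("") == ElementalComposition()
    assert monoisotopic_mass(parse_formula("")) == 0.0


def test_parse_signed_delta():
    delta = parse_formula("+C11H20N2O9P2S")
    assert delta["C"] == 11 and delta["S"] == 1 and delta["P"] == 2
    neg = parse_formula("-H2O")
    assert neg["H"] == -2 and neg["O"] == -1
    mixed = parse_formula("+O -C7H15")
    assert mixed["O"] == 1 and mixed["C"] == -7 and mixed["H"] == -15


def test_parse_bracketed_nuclides():
    c = parse_formula("[2]H3C2")
    assert c[("H", 2)] == 3 and c["C"] == 2


@pytest.mark.parametrize("bad", ["Xx5", "C5H#3", "[999]H2", "c5"])
def test_parse_errors_name_offender(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


# -- masses -----------------------------------------------------------------


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("NH3", 17.0265),        # printed as 17.0266 (rounds up at its precision)
        ("C2H4O2", 60.0211),     # methyl formate loss
        ("C2H8NO4P", 141.0191),  # phosphoethanolamine loss
    ],
)
def test_monoisotopic_printed_losses(formula, expected):
    assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(expected, abs=6e-5)


@pytest.mark.parametrize(
    "formula,expected",
    [("NH3", 17), ("C5H15NO4P", 184), ("C3H5NO2", 87), ("C3H6O5P", 153)],
)
def test_nominal_mass(formula, expected):
    assert nominal_mass(parse_formula(formula)) == expected


def test_nominal_counts_heavy_nuclides_by_mass_number():
    assert nominal_mass(parse_formula("[2]H13C5H2NO4P")) == 197
    assert nominal_mass(parse_formula("[13]C2[15]N")) == 41


def test_mass_cross_check_against_pyteomics():
    for formula in ("C5H15NO4P", "C44H76NO8P", "C55H102O6", "H2O"):
        ours = monoisotopic_mass(parse_formula(formula))
        theirs = ptmass.calculate_mass(formula=formula)
        assert ours == pytest.approx(theirs, abs=1e-9)


# -- m/z --------------------------------------------------------------------


def test_phosphocholine_cation_mz():
    assert mz(parse_formula("C5H15NO4P"), ChargeState(+1)) == pytest.approx(
        184.0733, abs=5e-5
    )


def test_acetate_adduct_of_pc36_6():
    ion = parse_formula("C44H76NO8P") + parse_formula("C2H3O2")
    assert mz(ion, -1) == pytest.approx(836.5447, abs=5e-5)


def test_doubly_charged_anion_brute_force():
    comp = parse_formula("C66H120O17P2")
    ion = comp - parse_formula("H2")
    expected = (ion.monoisotopic_mass() + 2 * ELECTRON_MASS) / 2
    assert mz(ion, ChargeState(-2)) == pytest.approx(expected, abs=1e-12)


def test_electron_bookkeeping_exact():
    comp = parse_formula("C5H15NO4P")
    m = comp.monoisotopic_mass()
    assert mz(comp, +1) == pytest.approx(m - ELECTRON_MASS, abs=1e-12)
    assert mz(comp, -1) == pytest.approx(m + ELECTRON_MASS, abs=1e-12)
    assert mz(comp, -1) - mz(comp, +1) == pytest.approx(2 * ELECTRON_MASS, abs=1e-12)


def test_zero_charge_rejected():
    with pytest.raises(ValueError):
        mz(parse_formula("H2O"), 0)
    with pytest.raises(ValueError):
        ChargeState(0)


# -- isotope labels ---------------------------------------------------------


def test_apply_label_mass_shift_d13():
    pc = parse_formula("C42H82NO8P")  # PC 34:2
    shift = monoisotopic_mass(apply_label(pc, IsotopeLabelSpec.parse("+[2]H13"))) - (
        monoisotopic_mass(pc)
    )
    d = ptmass.nist_mass["H"][2][0] - ptmass.nist_mass["H"][0][0]
    assert shift == pytest.approx(13 * d, abs=1e-9)
    assert shift == pytest.approx(13.0816, abs=2e-4)


def test_apply_label_c13_n15():
    cer = parse_formula("C44H89NO5")
    label = IsotopeLabelSpec.parse("+[13]C2[15]N")
    shift = monoisotopic_mass(apply_label(cer, label)) - monoisotopic_mass(cer)
    assert shift == pytest.approx(3.0037, abs=2e-4)


def test_empty_label_is_identity():
    comp = parse_formula("C10H20O2")
    assert apply_label(comp, None) == comp


def test_over_substitution_rejected():
    with pytest.raises(LabelError):
        apply_label(parse_formula("C44H76NO8P"), IsotopeLabelSpec.parse("+[2]H80"))


def test_label_render_order_hill_like():
    assert IsotopeLabelSpec.parse("+[15]N[13]C2").render() == "+[13]C2[15]N"


# -- formatting -------------------------------------------------------------


def test_hill_formula_and_metal_last():
    assert parse_formula("C5H15NO4P").hill_formula() == "C5H15NO4P"
    assert parse_formula("NaO").hill_formula() == "ONa"
    assert parse_formula("NaOH").hill_formula() == "HONa"
    assert parse_formula("H2O").hill_formula() == "H2O"


def test_signed_formula_mixed():
    assert (parse_formula("O") + parse_formula("-C7H15")).signed_formula() == "+O -C7H15"
    assert parse_formula("-HO").signed_formula() == "-HO"


# -- properties -------------------------------------------------------------

_ELEMENTS = ["C", "H", "N", "O", "P", "S"]
_compositions = st.builds(
    lambda counts: ElementalComposition(
        {(sym, 0): n for sym, n in zip(_ELEMENTS, counts)}
    ),
    st.lists(st.integers(min_value=0, max_value=30), min_size=6, max_size=6),
)


@settings(max_examples=100, derandomize=True)
@given(a=_compositions, b=_compositions)
def test_mass_linearity(a, b):
    assert (a + b).monoisotopic_mass() == pytest.approx(
        a.monoisotopic_mass() + b.monoisotopic_mass(), abs=1e-9
    )
    assert (a + b).nominal_mass() == a.nominal_mass() + b.nominal_mass()


@settings(max_examples=100, derandomize=True)
@given(c=_compositions)
def test_parse_format_round_trip(c):
    assert parse_formula(c.hill_formula()) == c


@settings(max_examples=100, derandomize=True)
@given(c=_compositions)
def test_nominal_tracks_monoisotopic(c):
    n_atoms = sum(abs(v) for _k, v in c.items())
    if n_atoms == 0:
        return
    assert abs(c.monoisotopic_mass() - c.nominal_mass()) <= 0.5 * max(1, n_atoms / 10)
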