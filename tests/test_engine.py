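"""Mass-balanced fragment enumeration, deduplication, MS3 chaining, validation."""

import pytest

from liponom.chem import parse_formula
from liponom.engine import (
    FragmentationRule,
    PartSpec,
    RuleApplicationError,
    enumerate_fragments,
    enumerate_ms3,
    load_rules,
    validate_rules,
)
from liponom.registry import default_registry
from liponom.structures import precursor_ion

from conftest import ppm


def _mlf_reactions(reactions):
    """Reactions instantiated from a chain-iterating (MLF) rule."""
    return [
        r
        for r in reactions
        if any(p.kind in ("chain", "dbf") for p in (r.charged, *r.neutrals))
    ]


def test_pc_acetate_combined_loss_reaction():
    prec = precursor_ion("PC 18:3-18:3", "+CH3COO")
    rxns = enumerate_fragments(prec)
    hits = [r for r in rxns if abs(r.mz - 502.2939) < 5e-4]
    assert len(hits) == 1
    neutrals = {p.composition.hill_formula() for p in hits[0].neutrals}
    assert neutrals == {"C3H6O2", "C18H28O"}  # methyl acetate + FA 18:3 ketene


def test_tag_mlf_cardinality_distinct_chains():
    rxns = enumerate_fragments(precursor_ion("TAG 16:0-18:0-18:2", "+NH4"))
    assert len(_mlf_reactions(rxns)) == 12


def test_tag_mlf_cardinality_after_dedup():
    rxns = enumerate_fragments(precursor_ion("TAG 16:0-18:1-18:1", "+NH4"))
    assert len(_mlf_reactions(rxns)) == 8


def test_ps_mlf_cardinality():
    rxns = enumerate_fragments(precursor_ion("PS 20:4-22:6", "-H"))
    assert len(_mlf_reactions(rxns)) == 8


def test_dedup_strictly_reduces_for_repeated_chains():
    distinct = enumerate_fragments(precursor_ion("TAG 16:0-18:0-18:2", "+NH4"))
    repeated = enumerate_fragments(precursor_ion("TAG 16:0-18:1-18:1", "+NH4"))
    assert len(repeated) < len(distinct)


def test_dedup_merges_chain_evidence():
    rxns = enumerate_fragments(precursor_ion("PE 17:0-17:0", "-H"))
    ketene = [r for r in rxns if r.rule_id == "pe_neg_ketene_loss"]
    assert len(ketene) == 1
    assert ketene[0].chain_indices == frozenset({0, 1})


def test_atom_and_mass_balance_all_probes():
    """The central invariant: exact atom balance, mass balance < 1e-9 Da."""
    registry = default_registry()
    checked = 0
    for lipid, adduct in [
        ("PC 16:0-18:1", "+H"),
        ("PC 16:0-18:1", "+CH3COO"),
        ("PE 17:0-17:0", "-H"),
        ("PE O-18:1p/20:4", "+H"),
        ("PS 20:4-22:6", "-H"),
        ("PI 16:0-18:1", "-H"),
        ("PA 16:0-18:1", "-H"),
        ("TAG 16:0-18:0-18:2", "+NH4"),
        ("DAG 18:0-20:0", "+Na"),
        ("CL 14:1-14:1-14:1-15:1", "-2H"),
        ("SM 18:1;2/17:0", "+H"),
        ("Cer 18:1;2/17:0;1", "-H"),
        ("SE 27:1/19:0", "+NH4"),
        ("ACar 18:2", "+H"),
        ("ACoA 19:0", "-H"),
        ("FA 18:1(9)", "-H"),
    ]:
        prec = precursor_ion(lipid, adduct, registry)
        for rxn in enumerate_fragments(prec):
            total = rxn.charged.composition
            z = rxn.charged.z
            for part in rxn.neutrals:
                total = total + part.composition
                z += part.z
            assert total == prec.composition, (lipid, rxn.rule_id)
            assert z == prec.charge.z
            assert rxn.mass_balance_error < 1e-9
            checked += 1
    assert checked > 50


@pytest.mark.parametrize(
    "lipid,adduct",
    [
        ("PC(+[2]H13) 16:1-18:1", "+H"),
        ("PC 16:0(+[2]H3)-16:0(+[2]H3)", "+H"),
        ("PI(+[2]H6) 16:0-18:1", "-H"),
        ("Cer 18:0;3(+[13]C2[15]N)/26:0;1", "+HCOO"),
    ],
)
def test_heavy_nuclide_conservation(lipid, adduct):
    prec = precursor_ion(lipid, adduct)
    total_heavy = prec.composition.heavy_count()
    for rxn in enumerate_fragments(prec):
        heavy = rxn.charged.composition.heavy_count() + sum(
            p.composition.heavy_count() for p in rxn.neutrals
        )
        assert heavy == total_heavy, rxn.rule_id


def test_ms3_of_tag_dag_fragment():
    prec = precursor_ion("TAG 16:0-18:0-18:2", "+NH4")
    parents = {
        round(r.mz, 1): r
        for r in enumerate_fragments(prec)
        if r.rule_id == "glyceride_nh4_fa_ammonia_loss"
    }
    ms3 = enumerate_ms3(parents[575.5])  # loss of FA 18:0 + NH3
    mzs = sorted(round(r.mz, 4) for r in ms3)
    assert 239.2369 in mzs  # FA 16:0 acylium
    assert 263.2369 in mzs  # FA 18:2 acylium
    # balance against the parent fragment as the new precursor
    for rxn in ms3:
        total = rxn.charged.composition
        for p in rxn.neutrals:
            total = total + p.composition
        assert total == parents[575.5].charged.composition


def test_ms3_absent_rules_empty():
    prec = precursor_ion("SM 18:1;2/17:0", "+H")
    lcf = enumerate_fragments(prec)[0]  # charged phosphocholine, no chains
    assert enumerate_ms3(lcf) == []


def test_ms3_composability_oracle():
    """Two-level neutral losses compose to a directly written 2-step loss."""
    prec = precursor_ion("TAG 16:0-18:0-18:2", "+NH4")
    parent = [
        r
        for r in enumerate_fragments(prec)
        if r.rule_id == "glyceride_nh4_fa_ammonia_loss" and abs(r.mz - 575.5034) < 0.01
    ][0]
    acylium = [r for r in enumerate_ms3(parent) if abs(r.mz - 239.2369) < 1e-3][0]
    # oracle: precursor - (FA 18:0 + NH3) - MS3 neutrals == FA 16:0 acylium
    expected = prec.composition - parse_formula("C18H36O2") - parse_formula("NH3")
    for p in acylium.neutrals:
        expected = expected - p.composition
    assert expected == acylium.charged.composition == parse_formula("C16H31O")


def test_dbf_reaction_printed_mz():
    prec = precursor_ion("FA 18:1(9)", "-H")
    rxns = enumerate_fragments(prec)
    assert len(rxns) == 1
    assert ppm(rxns[0].mz, 182.1305) <= 6.0
    assert rxns[0].charged.ftype == "DBF"


def test_no_rules_warns_and_returns_empty():
    prec = precursor_ion("PS 20:4-22:6", "+H")  # no positive-mode PS rules
    with pytest.warns(UserWarning):
        assert enumerate_fragments(prec) == []


def test_packaged_rules_validate_clean():
    report = validate_rules()
    assert report.ok, report.violations
    assert report.checked > 100


def test_constructed_bad_rule_flagged():
    bad = FragmentationRule(
        id="bad_overcount",
        classes=["TAG"],
        adducts=["+NH4"],
        ms_level=2,
        charged=PartSpec(kind="remainder"),
        neutrals=(PartSpec(kind="fixed", formula="N5H20"),),  # more N than present
    )
    report = validate_rules([bad])
    assert not report.ok
    assert report.violations[0][0] == "bad_overcount"


def test_rule_loader_rejects_two_iterating_parts():
    with pytest.raises(ValueError):
        load_rules(
            {
                "rules": [
                    {
                        "id": "x",
                        "classes": ["PC"],
                        "adducts": ["+H"],
                        "ms_level": 2,
                        "charged": {"kind": "chain"},
                        "neutrals": [{"kind": "chain"}],
                    }
                ]
            }
        )


def test_species_level_only_chain_free_rules():
    rxns = enumerate_fragments(precursor_ion("TAG 52:2", "+NH4"))
    assert len(rxns) == 1  # only the ammonia loss; MLFs need known chains
    assert abs(rxns[0].mz - 859.7749) < 5e-4
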