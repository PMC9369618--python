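"""Molecule-table parsing, curation rules and tier assembly."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dsscreen import (
    ClassFrame,
    CurationConfig,
    MoleculeRecord,
    assemble_tiers,
    curate,
    read_molecule_table,
    split_validation,
    write_molecule_table,
)
from dsscreen.errors import ContractError, SchemaError, ValidationError


def _rec(i, smiles="CCO", roles=("analgesic",), flags=()):
    return MoleculeRecord(
        id=f"m{i}", name=f"mol{i}", smiles=smiles, roles=tuple(roles), flags=frozenset(flags)
    )


# ---------------------------------------------------------------------------
# reading


def test_read_molecule_table_roundtrip(tmp_path, frame7):
    path = tmp_path / "mols.csv"
    pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "name": ["x", "y", "z"],
            "smiles": ["CCO", "CCN", "c1ccccc1"],
            "roles": ["analgesic", "antiviral;antibacterial", "antifungal"],
            "flags": ["", "adjuvant_or_healthcare", ""],
        }
    ).to_csv(path, index=False)
    records = read_molecule_table(path, frame7)
    assert len(records) == 3
    assert records[1].roles == ("antiviral", "antibacterial")
    assert records[1].flags == frozenset({"adjuvant_or_healthcare"})

    out = tmp_path / "out.csv"
    write_molecule_table(records, out)
    assert [r.id for r in read_molecule_table(out, frame7)] == ["a", "b", "c"]


def test_read_rejects_unknown_class_label_with_row_number(tmp_path, frame7):
    path = tmp_path / "mols.csv"
    path.write_text("id,name,smiles,roles\na,x,CCO,analgesic\nb,y,CCN,antihelmintic\n")
    with pytest.raises(ValidationError, match="row 3.*antihelmintic"):
        read_molecule_table(path, frame7)


def test_read_missing_column_names_it(tmp_path, frame7):
    path = tmp_path / "mols.csv"
    path.write_text("id,name,roles\na,x,analgesic\n")
    with pytest.raises(SchemaError, match="smiles"):
        read_molecule_table(path, frame7)


def test_read_header_only_gives_empty_list(tmp_path, frame7):
    path = tmp_path / "mols.csv"
    path.write_text("id,name,smiles,roles\n")
    assert read_molecule_table(path, frame7) == []


def test_read_tsv_delimiter(tmp_path, frame7):
    path = tmp_path / "mols.tsv"
    path.write_text("id\tname\tsmiles\troles\na\tx\tCCO\tanalgesic\n")
    assert len(read_molecule_table(path, frame7)) == 1


# ---------------------------------------------------------------------------
# curation


def test_curate_mass_limit():
    big = _rec(1, smiles="C" * 130)  # C130 alkane, ~1823 g/mol
    kept, report = curate([big, _rec(2)], CurationConfig(mass_limit=1800))
    assert report.mass_over_limit == 1
    assert [r.id for r in kept] == ["m2"]


def test_curate_duplicate_structures_keep_first():
    # same structure written two ways, different names
    a = _rec(1, smiles="OCC")
    b = _rec(2, smiles="CCO")
    kept, report = curate([a, b])
    assert [r.id for r in kept] == ["m1"]
    assert report.duplicate_structure == 1


def test_curate_toy_hand_count():
    records = [
        _rec(1, smiles="xyz"),  # unparseable
        _rec(2, smiles="CC(=O)[O-].[Na+]"),  # two-fragment salt
        _rec(3, smiles="CCO"),
        _rec(4, smiles="CCN"),
        _rec(5, smiles="c1ccccc1"),
    ]
    kept, report = curate(records)
    assert len(kept) == 3
    assert report.parse_failure == 1 and report.multi_fragment == 1
    assert report.kept + sum(report.removals.values()) == 5


def test_curate_is_idempotent(toy_records):
    kept, _ = curate(toy_records)
    kept2, report2 = curate(kept)
    assert [r.id for r in kept2] == [r.id for r in kept]
    assert sum(report2.removals.values()) == 0


def test_curate_isomer_pairs_opt_in():
    cis = _rec(1, smiles="C/C=C\\C")
    trans = _rec(2, smiles="C/C=C/C")
    kept, report = curate([cis, trans], CurationConfig(remove_isomer_pairs=True))
    assert kept == [] and report.isomer_pair == 2
    kept_default, _ = curate([cis, trans])
    assert len(kept_default) == 2  # stereo-distinct, not duplicates


# ---------------------------------------------------------------------------
# tiers and validation split


def test_tiers_no_flags_identity():
    tiers = assemble_tiers([_rec(i) for i in range(10)])
    assert tiers.sizes() == {"S1": 10, "S2": 10, "S3": 10, "S4": 10}


def test_tiers_hand_counts():
    recs = (
        [_rec(i, flags={"adjuvant_or_healthcare"}) for i in range(2)]
        + [_rec(i + 2, flags={"potential_other_use"}) for i in range(3)]
        + [_rec(5, flags={"no_mechanism_or_veterinary_or_trial"})]
        + [_rec(i + 6) for i in range(4)]
    )
    assert assemble_tiers(recs).sizes() == {"S1": 10, "S2": 8, "S3": 5, "S4": 4}


def test_tiers_reject_multi_role():
    with pytest.raises(ContractError):
        assemble_tiers([_rec(1, roles=("analgesic", "antiviral"))])


@given(
    st.lists(
        st.sets(
            st.sampled_from(
                ["adjuvant_or_healthcare", "potential_other_use", "no_mechanism_or_veterinary_or_trial"]
            )
        ),
        min_size=1,
        max_size=30,
    )
)
def test_tiers_nest_for_any_flags(flag_sets):
    recs = [_rec(i, flags=f) for i, f in enumerate(flag_sets)]
    tiers = assemble_tiers(recs)
    ids = {t: {r.id for r in tiers[t]} for t in ("S1", "S2", "S3", "S4")}
    assert ids["S4"] <= ids["S3"] <= ids["S2"] <= ids["S1"]


def test_split_validation_partition():
    recs = [_rec(i) for i in range(4)] + [
        _rec(10, roles=("antibacterial", "antineoplastic")),
        _rec(11, roles=("analgesic", "antiviral", "antifungal")),
    ]
    single, multi = split_validation(recs)
    assert len(single) == 4 and len(multi) == 2
    assert [r.id for r in multi] == ["m10", "m11"]
    single_only, none_multi = split_validation(single)
    assert none_multi == [] and len(single_only) == 4


def test_read_sdf_structures(tmp_path):
    from rdkit import Chem
    from dsscreen.molecules import read_sdf_structures

    writer = Chem.SDWriter(str(tmp_path / "mols.sdf"))
    for title, smi in [("drug_a", "CCO"), ("drug_b", "c1ccccc1")]:
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", title)
        writer.write(mol)
    writer.close()
    structures = read_sdf_structures(tmp_path / "mols.sdf")
    assert set(structures) == {"drug_a", "drug_b"}
    assert structures["drug_a"] == "CCO"
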