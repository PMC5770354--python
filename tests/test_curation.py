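import random

import pytest
from rdkit import Chem

from qsarflow import CompoundRecord, canonicalize_and_desalt, curate, parse_input
from qsarflow.curation import DROP_RULES, Rejection
from qsarflow.errors import ConfigurationError, EmptyDatasetError, InputError


def _rec(cid, smiles="CCO", atype="Ki", value=10.0, year=None):
    return CompoundRecord(cid, smiles, atype, value, year)


class TestParseInput:
    def test_csv_row_count_and_fields(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(
            "compound_id,smiles,activity_type,activity_value,year\n"
            "a,CCO,Ki,12.5,2015\n"
            "b,CCN,Ki,,2016\n"
            "c,CCC,IC50,bogus,\n"
        )
        records = parse_input(path, "csv")
        assert len(records) == 3
        assert records[0].activity_value == 12.5 and records[0].year == 2015
        # empty and unparsable values become absent, not coerced
        assert records[1].activity_value is None
        assert records[2].activity_value is None and records[2].year is None

    def test_missing_required_column_names_it(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("compound_id,activity_type,activity_value\na,Ki,5\n")
        with pytest.raises(ConfigurationError, match="smiles"):
            parse_input(path, "csv")

    def test_missing_file_and_bad_format(self, tmp_path):
        with pytest.raises(InputError):
            parse_input(tmp_path / "nope.csv", "csv")
        (tmp_path / "x.csv").write_text("compound_id,smiles,activity_type,activity_value\n")
        with pytest.raises(ConfigurationError):
            parse_input(tmp_path / "x.csv", "xlsx")

    def test_smi_with_optional_ids(self, tmp_path):
        path = tmp_path / "in.smi"
        path.write_text("CCO mol_a\nCCN\n")
        records = parse_input(path, "smi")
        assert [r.compound_id for r in records] == ["mol_a", "mol2"]

    def test_sdf_roundtrip(self, tmp_path):
        path = tmp_path / "in.sdf"
        writer = Chem.SDWriter(str(path))
        for smi, cid in [("CCO", "m1"), ("c1ccccc1", "m2")]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("compound_id", cid)
            mol.SetProp("activity_type", "Ki")
            mol.SetProp("activity_value", "42")
            writer.write(mol)
        writer.close()
        records = parse_input(path, "sdf")
        assert [r.compound_id for r in records] == ["m1", "m2"]
        assert all(r.activity_value == 42.0 for r in records)


class TestDesalting:
    def test_salt_reduced_to_largest_organic_fragment(self):
        out = canonicalize_and_desalt(_rec("a", "CCN.Cl"))
        assert out.smiles == Chem.MolToSmiles(Chem.MolFromSmiles("CCN"))

    def test_canonical_single_fragment_unchanged(self):
        canon = Chem.MolToSmiles(Chem.MolFromSmiles("c1ccccc1O"))
        out = canonicalize_and_desalt(_rec("a", canon))
        assert out.smiles == canon
        # idempotence
        assert canonicalize_and_desalt(out).smiles == canon

    def test_invalid_and_inorganic_rejections(self):
        bad = canonicalize_and_desalt(_rec("a", "notasmiles"))
        assert isinstance(bad, Rejection) and bad.reason == "invalid_structure"
        salt = canonicalize_and_desalt(_rec("b", "[Na+].[Cl-]"))
        assert isinstance(salt, Rejection) and salt.reason == "inorganic_only"


class TestCurate:
    def test_most_recent_year_kept(self):
        records = [
            _rec("old", "CCO", year=2010, value=5.0),
            _rec("new", "CCO", year=2015, value=9.0),
        ]
        ds = curate(records, "Ki")
        assert [r.compound_id for r in ds.records] == ["new"]

    def test_activity_type_filter(self):
        records = [_rec("a", "CCO", "Ki"), _rec("b", "CCN", "IC50")]
        ds = curate(records, "Ki")
        assert [r.compound_id for r in ds.records] == ["a"]
        assert ds.curation_log["dropped_activity_type"] == 1

    def test_nonpositive_treated_as_missing(self):
        records = [_rec("a", "CCO", value=-5.0), _rec("b", "CCN", value=3.0)]
        ds = curate(records, "Ki")
        assert [r.compound_id for r in ds.records] == ["b"]
        assert ds.curation_log["dropped_missing"] == 1

    def test_all_dropped_raises_empty(self):
        with pytest.raises(EmptyDatasetError):
            curate([_rec("a", "CCO", value=None)], "Ki")
        with pytest.raises(ConfigurationError):
            curate([_rec("a")], "")

    def test_log_reconciles_with_counts(self, fixture_records):
        ds = curate(fixture_records, "Ki")
        dropped = sum(ds.curation_log[rule] for rule in DROP_RULES)
        assert dropped + len(ds.records) == len(fixture_records)

    def test_idempotent(self, fixture_records):
        once = curate(fixture_records, "Ki")
        twice = curate(once.records, "Ki")
        assert twice.records == once.records

    def test_dedup_order_independent_with_distinct_years(self):
        records = [
            _rec("r2008", "CCO", year=2008, value=1.0),
            _rec("r2019", "CCO", year=2019, value=2.0),
            _rec("r2013", "CCO", year=2013, value=3.0),
            _rec("other", "CCN", year=2010, value=4.0),
        ]
        expected = {"r2019", "other"}
        for seed in range(5):
            shuffled = records[:]
            random.Random(seed).shuffle(shuffled)
            ds = curate(shuffled, "Ki")
            assert {r.compound_id for r in ds.records} == expected

    def test_tied_years_keep_median_activity(self):
        records = [
            _rec("lo", "CCO", year=2015, value=100.0),
            _rec("mid", "CCO", year=2015, value=200.0),
            _rec("hi", "CCO", year=2015, value=400.0),
        ]
        ds = curate(records, "Ki")
        assert [r.compound_id for r in ds.records] == ["mid"]
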