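"""Standardization workflow, InChIKey deduplication, and label invariants."""

import math

import pandas as pd
import pytest

from purscreen import (
    EmptyDatasetError,
    FlagCode,
    GeneratorConfig,
    RawRecord,
    binarize,
    curate_dataset,
    deduplicate_and_average,
    generate_bioactivity_dataset,
    standardize_molecule,
    to_pactivity,
)
from purscreen.curation import ERROR_FLAGS

EXCLUDING = ERROR_FLAGS | {FlagCode.CENSORED_ACTIVITY}

ADVERSARIAL = GeneratorConfig(
    n_records=50,
    seed=11,
    p_duplicate=0.30,
    p_salt=0.20,
    p_charged=0.15,
    p_isotope=0.10,
    p_invalid=0.10,
    p_censored=0.10,
)


class TestStandardize:
    def test_salt_is_stripped_and_neutralized(self):
        mol = standardize_molecule("[Na+].CC(=O)[O-]")
        assert mol.canonical_structure == "CC(=O)O"
        assert {f.code for f in mol.flags} == {FlagCode.MULTICOMPONENT}
        assert mol.inchikey == "QTBSBXVTEAMEQO-UHFFFAOYSA-N"  # acetic acid

    def test_isotope_labels_are_removed(self):
        assert standardize_molecule("[13CH4]").canonical_structure == "C"

    def test_pentavalent_carbon_flags_valence_error(self):
        mol = standardize_molecule("C(C)(C)(C)(C)C")
        assert mol.has_error
        assert {f.code for f in mol.flags} == {FlagCode.ERR_VALENCE}

    def test_unparseable_input_flags_parse_fail_without_raising(self):
        assert standardize_molecule("not-a-molecule((").flags[0].code == FlagCode.PARSE_FAIL
        assert standardize_molecule("").flags[0].code == FlagCode.PARSE_FAIL

    def test_quaternary_nitrogen_is_permanent_not_erroneous(self):
        mol = standardize_molecule("C[N+](C)(C)C.[Cl-]")
        assert not mol.has_error
        assert "[N+]" in mol.canonical_structure

    def test_unremovable_charge_is_flagged(self):
        # a sulfonium cation has no proton to strip and is not treated as a
        # permanent quaternary center, so its charge is reported as erroneous
        mol = standardize_molecule("C[S+](C)C")
        assert mol.has_error
        assert any(f.code == FlagCode.ERR_CHARGE for f in mol.flags)

    def test_carbanion_is_neutralized(self):
        mol = standardize_molecule("[CH3-]")
        assert not mol.has_error
        assert mol.canonical_structure == "C"

    @pytest.mark.parametrize(
        "smiles",
        ["c1ccccc1", "CC(=O)Nc1ccc(O)cc1", "[Na+].CC(=O)[O-]", "C[13CH2]O.Cl",
         "C[NH3+].[Cl-]", "O=C(O)c1cc(CCO)ccc1Cc1cc2ccccc2[nH]1"],
    )
    def test_idempotence(self, smiles):
        once = standardize_molecule(smiles)
        twice = standardize_molecule(once.canonical_structure)
        assert twice.canonical_structure == once.canonical_structure
        assert twice.inchikey == once.inchikey
        assert twice.flags == ()  # no rule fires a second time


class TestPActivity:
    @pytest.mark.parametrize(
        "value, units, expected",
        [(1, "µM", 6.0), (100, "nM", 7.0), (5, "µM", 5.30103), (1, "M", 0.0),
         (2, "mM", 2.69897)],
    )
    def test_log_molar_conversion(self, value, units, expected):
        assert to_pactivity(value, units) == pytest.approx(expected, abs=1e-5)

    def test_unit_alias(self):
        assert to_pactivity(1, "uM") == to_pactivity(1, "µM")

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            to_pactivity(0, "nM")
        with pytest.raises(Exception):
            to_pactivity(1, "furlongs")


class TestDeduplicate:
    def test_two_copies_average(self):
        a = standardize_molecule("CCO")
        b = standardize_molecule("OCC")
        merged, log = deduplicate_and_average([(a, 6.0), (b, 7.0)])
        assert len(merged) == 1
        assert merged[0].p_activity == pytest.approx(6.5)
        assert merged[0].n_merged == 2
        assert len(log) == 1 and log[0][1].code == FlagCode.DUPLICATE
        assert "CCO" in log[0][1].detail  # member SMILES are logged

    def test_distinct_keys_pass_through(self):
        mols = [standardize_molecule(s) for s in ("CCO", "CCN", "CCC")]
        merged, log = deduplicate_and_average([(m, 5.0) for m in mols])
        assert [r.n_merged for r in merged] == [1, 1, 1]
        assert log == []

    def test_group_means_match_brute_force_oracle(self):
        records, _ = generate_bioactivity_dataset(ADVERSARIAL)
        pairs = []
        for rec in records:
            mol = standardize_molecule(rec.structure)
            if mol.has_error or rec.activity_value is None:
                continue
            mol.parent_record_ids = (rec.record_id,)
            pairs.append((mol, to_pactivity(rec.activity_value, rec.activity_units)))
        merged, _ = deduplicate_and_average(pairs)
        oracle = (
            pd.DataFrame(
                {"key": [m.inchikey for m, _ in pairs], "p": [p for _, p in pairs]}
            )
            .groupby("key")["p"]
            .mean()
        )
        assert len(merged) == len(oracle)
        for rec in merged:
            assert rec.p_activity == pytest.approx(
                oracle[rec.molecule.inchikey], abs=1e-12
            )


class TestBinarize:
    @pytest.mark.parametrize(
        "p, cutoff, label",
        [(6.0, 5e-6, 1), (-math.log10(5e-6), 5e-6, 1), (4.0, 5e-6, 0),
         (6.0, 1e-6, 1), (5.9999, 1e-6, 0)],
    )
    def test_cutoff_rule_with_boundary_active(self, p, cutoff, label):
        assert binarize(p, cutoff) == label


class TestCurateDataset:
    def test_counted_example_duplicates_and_invalid(self):
        smiles = ["CCO", "CCN", "CCC", "CCCC", "c1ccccc1", "CC(=O)O", "CCS"]
        records = [
            RawRecord(f"r{i}", s, 1.0, "µM") for i, s in enumerate(smiles)
        ]
        records.append(RawRecord("dup1", "OCC", 2.0, "µM"))   # duplicate of CCO
        records.append(RawRecord("dup2", "C(C)O", 4.0, "µM"))  # duplicate of CCO
        records.append(RawRecord("bad", "C1CC(", 1.0, "µM"))   # invalid
        ds = curate_dataset(records, cutoff_molar=5e-6)
        assert len(ds) == 7
        assert len(ds.curation_log) == 3  # 2 duplicate entries + 1 parse failure
        ethanol = next(r for r in ds.records if r.molecule.canonical_structure == "CCO")
        assert ethanol.n_merged == 3
        # mean of pEC50(1µM)=6, pEC50(2µM)=5.69897, pEC50(4µM)=5.39794
        assert ethanol.p_activity == pytest.approx((6 + 5.69897 + 5.39794) / 3, abs=1e-5)

    def test_total_collapse_of_identical_records(self):
        records = [RawRecord(f"r{i}", "CCO", 1.0, "µM") for i in range(6)]
        ds = curate_dataset(records, 5e-6)
        assert len(ds) == 1 and ds.records[0].n_merged == 6

    def test_censored_records_are_excluded_and_logged(self):
        records = [
            RawRecord("a", "CCO", 1.0, "µM"),
            RawRecord("b", "CCN", 10.0, "µM", activity_qualifier=">"),
            RawRecord("c", "CCC"),  # no activity at all
        ]
        ds = curate_dataset(records, 5e-6)
        assert len(ds) == 1
        codes = [fl.code for _, fl in ds.curation_log]
        assert codes.count(FlagCode.CENSORED_ACTIVITY) == 2

    def test_all_rejected_raises_with_log_attached(self):
        records = [RawRecord("a", "((("), RawRecord("b", "C1CC(")]
        with pytest.raises(EmptyDatasetError) as exc:
            curate_dataset(records, 5e-6)
        assert len(exc.value.curation_log) == 2

    def test_loosening_cutoff_never_deactivates(self, default_bioactivity):
        records, _ = default_bioactivity
        tight = curate_dataset(records, cutoff_molar=1e-6)
        loose = curate_dataset(records, cutoff_molar=5e-6)
        keys_tight = {r.molecule.inchikey: l for r, l in zip(tight.records, tight.labels)}
        keys_loose = {r.molecule.inchikey: l for r, l in zip(loose.records, loose.labels)}
        assert keys_tight.keys() == keys_loose.keys()
        for key, label in keys_tight.items():
            assert keys_loose[key] >= label
        assert loose.n_active >= tight.n_active


@pytest.fixture(scope="module")
def adversarial_dataset():
    records, truth = generate_bioactivity_dataset(ADVERSARIAL)
    return records, truth, curate_dataset(records, 5e-6)


class TestDatasetInvariants:
    def test_inchikey_uniqueness(self, adversarial_dataset):
        _, _, ds = adversarial_dataset
        keys = [r.molecule.inchikey for r in ds.records]
        assert len(set(keys)) == len(keys)

    def test_record_count_conservation(self, adversarial_dataset):
        records, _, ds = adversarial_dataset
        merged = sum(r.n_merged for r in ds.records)
        excluded_ids = {
            rid for rid, fl in ds.curation_log if fl.code in EXCLUDING
        }
        assert merged + len(excluded_ids) == len(records)

    def test_standardization_idempotent_on_curated_output(self, adversarial_dataset):
        _, _, ds = adversarial_dataset
        for rec in ds.records:
            again = standardize_molecule(rec.molecule.canonical_structure)
            assert again.canonical_structure == rec.molecule.canonical_structure
            assert again.inchikey == rec.molecule.inchikey
            assert again.flags == ()

    def test_salt_variants_collapse_onto_parent_key(self):
        # the same parent reported as free base, HCl salt, and sodium salt
        variants = ["O=C(O)c1cc(C)ccc1CC", "O=C(O)c1cc(C)ccc1CC.Cl",
                    "O=C([O-])c1cc(C)ccc1CC.[Na+]"]
        keys = {standardize_molecule(v).inchikey for v in variants}
        assert len(keys) == 1
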