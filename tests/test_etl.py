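"""ETL value normalizers (frozen truth tables) and the harmonization engine."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammocdm.etl import (
    DatasetId,
    MappingSpec,
    MappingSpecError,
    SourceLoadError,
    coverage_report,
    default_mapping_spec,
    derive_hr_status,
    encode_multivalue,
    harmonize,
    load_source_table,
    parse_laterality,
    parse_tumor_position,
    recode_generic,
)
from mammocdm.fixtures import FixtureConfig, generate_source_csv
from mammocdm.registry import NOT_PROVIDED

ERP, ERN = 4167696, 4261933
PRP, PRN = 4085345, 4078166
POS, NEG, NP = 9191, 9189, NOT_PROVIDED

UOQ, LOQ, LIQ, UIQ, NOS = 36402335, 36402336, 36402334, 36402333, 36402339
LEFT, RIGHT = 4300877, 4229870


class TestHormoneReceptorDerivation:
    """HR status is the clinical disjunction of ER and PR."""

    @pytest.mark.parametrize(
        "er,pr,expected",
        [
            (ERP, PRP, POS),
            (ERP, PRN, POS),
            (ERP, NP, POS),
            (ERN, PRP, POS),
            (ERN, PRN, NEG),
            (ERN, NP, NP),
            (NP, PRP, POS),
            (NP, PRN, NP),
            (NP, NP, NP),
        ],
    )
    def test_truth_table(self, er, pr, expected):
        assert derive_hr_status(er, pr) == expected

    def test_unregistered_input_is_spec_error(self):
        with pytest.raises(MappingSpecError):
            derive_hr_status(123, PRP)


# Patient-facing clock convention, boundary hours to the clockwise-
# following sector; hand-enumerated from the documented sector table.
CLOCK_EXPECTED = {
    ("left", 12): UOQ, ("left", 1): UOQ, ("left", 2): UOQ,
    ("left", 3): LOQ, ("left", 4): LOQ, ("left", 5): LOQ,
    ("left", 6): LIQ, ("left", 7): LIQ, ("left", 8): LIQ,
    ("left", 9): UIQ, ("left", 10): UIQ, ("left", 11): UIQ,
    ("right", 12): UIQ, ("right", 1): UIQ, ("right", 2): UIQ,
    ("right", 3): LIQ, ("right", 4): LIQ, ("right", 5): LIQ,
    ("right", 6): LOQ, ("right", 7): LOQ, ("right", 8): LOQ,
    ("right", 9): UOQ, ("right", 10): UOQ, ("right", 11): UOQ,
}


class TestTumorPositionParser:
    @pytest.mark.parametrize("side,hour", list(CLOCK_EXPECTED))
    def test_all_24_clock_positions(self, side, hour):
        text = f"{side[0].upper()} {hour}"
        assert parse_tumor_position(text) == CLOCK_EXPECTED[(side, hour)]

    @pytest.mark.parametrize(
        "noisy,clean",
        [
            ("L 2 with calcs", "L 2"),
            ("l 2", "L 2"),
            ("  R 10  ", "R 10"),
            ("Left 7 posterior", "L 7"),
        ],
    )
    def test_trailing_noise_and_case_are_ignored(self, noisy, clean):
        assert parse_tumor_position(noisy) == parse_tumor_position(clean)

    def test_half_hour_and_range_notations(self):
        # 11:30 on the left is still the upper-inner sector
        assert parse_tumor_position("L 11:30") == UIQ
        # midpoint of R4-5 is 4:30, right breast -> lower-inner
        assert parse_tumor_position("R4-5") == LIQ

    def test_laterality_without_clock_is_breast_nos(self):
        assert parse_tumor_position("L with calcs") == NOS
        assert parse_tumor_position("right") == NOS

    @pytest.mark.parametrize("junk", ["", None, "unknown", "2", "13 L"])
    def test_degenerate_input_is_not_provided(self, junk):
        assert parse_tumor_position(junk) == NOT_PROVIDED

    @given(
        side=st.sampled_from(["left", "right"]),
        hour=st.integers(1, 12),
        suffix=st.text(
            alphabet="abcdefghijklmnopqrstuvwxyz ,", min_size=0, max_size=12
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_non_clock_suffix_never_changes_result(self, side, hour, suffix):
        base = f"{side[0].upper()} {hour}"
        assert parse_tumor_position(f"{base} {suffix}") == parse_tumor_position(base)

    def test_laterality_extraction(self):
        assert parse_laterality("L 2 with calcs") == LEFT
        assert parse_laterality("R4-5") == RIGHT
        assert parse_laterality("nothing here") == NOT_PROVIDED


# Frozen detailed -> generic map for the pN category (full enumeration).
PN_GENERIC = {
    1633440: 1633440,  # pNX
    1634200: 1634200,  # pN0
    1635020: 1634200, 1635064: 1634200, 1633272: 1634200,
    1634434: 1634434,  # pN1
    1635102: 1634434, 1633982: 1634434, 1634619: 1634434, 1635320: 1634434,
    1634119: 1634119,  # pN2
    1633401: 1634119, 1635704: 1634119,
    1635420: 1635420,  # pN3
    1633235: 1635420, 1634877: 1635420, 1635618: 1635420,
    NOT_PROVIDED: NOT_PROVIDED,
}


class TestGenericRecode:
    def test_pn_full_enumeration(self, cdm):
        ids = cdm["pn_category"].value_ids()
        assert ids == set(PN_GENERIC)
        for vid, generic in PN_GENERIC.items():
            assert recode_generic(vid, "pn_category", cdm) == generic

    def test_duke_numeric_minus_one_is_nx(self, cdm):
        spec = default_mapping_spec(DatasetId.DUKE)
        rule = spec.rule_for("pn_category")
        (nx,) = rule.value_map["-1"]
        assert nx == 1633440  # pNX
        assert recode_generic(nx, "pn_category", cdm) == nx

    def test_idempotent_on_every_coded_field(self, cdm):
        for concept in cdm:
            if not concept.is_coded:
                continue
            for v in concept.value_set:
                once = recode_generic(v.omop_id, concept.field_name, cdm)
                assert recode_generic(once, concept.field_name, cdm) == once

    def test_unregistered_value_is_spec_error(self, cdm):
        with pytest.raises(MappingSpecError):
            recode_generic(42, "pn_category", cdm)


class TestMultivalueEncoding:
    def test_canonical_examples(self):
        assert encode_multivalue([20, 10]) == "10|20"
        assert encode_multivalue([]) == "763013"
        assert encode_multivalue([7, 7]) == "7"
        assert encode_multivalue([NOT_PROVIDED, 5]) == "5"

    @given(st.lists(st.integers(1, 10**7), max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_permutation_invariant_sorted_unique(self, values):
        cell = encode_multivalue(values)
        assert cell == encode_multivalue(list(reversed(values)))
        if values:
            parts = [int(p) for p in cell.split("|")]
            assert parts == sorted(set(parts) )


class TestSourceLoading:
    def test_fixture_round_row_count(self, tmp_path):
        src, _ = generate_source_csv(
            FixtureConfig(DatasetId.DUKE, n_subjects=10, seed=3, out_dir=tmp_path)
        )
        table = load_source_table(src, DatasetId.DUKE)
        assert len(table) == 10

    def test_missing_file(self, tmp_path):
        with pytest.raises(SourceLoadError, match="not found"):
            load_source_table(tmp_path / "nope.csv", DatasetId.ISPY1)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(SourceLoadError):
            load_source_table(p, DatasetId.ISPY1)

    def test_duplicate_subject_id_named(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("SUBJECTID,AGE\n7,50\n7,60\n")
        with pytest.raises(SourceLoadError, match="7"):
            load_source_table(p, DatasetId.ISPY1)

    def test_missing_subject_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ID,AGE\n1,50\n")
        with pytest.raises(SourceLoadError, match="SUBJECTID"):
            load_source_table(p, DatasetId.ISPY1)


class TestHarmonize:
    def _run(self, dataset, tmp_path, cdm, n=20, seed=5, mess=0.0):
        src, truth = generate_source_csv(
            FixtureConfig(dataset, n_subjects=n, mess_rate=mess, seed=seed,
                          out_dir=tmp_path)
        )
        spec = default_mapping_spec(dataset)
        table = load_source_table(src, dataset)
        harmonized, cov = harmonize(table, spec, cdm)
        return harmonized, cov, truth

    def test_nact_protocol_radiotherapy_with_subject_27_override(self, tmp_path, cdm):
        harmonized, _, _ = self._run(DatasetId.NACT, tmp_path, cdm, n=30)
        yes, no = "4188539", "4188540"
        for sid, row in zip(harmonized.subject_ids, harmonized.rows):
            expected = no if sid == "27" else yes
            assert row["adjuvant_radiotherapy"] == expected
            assert row["adjuvant_hormone_therapy"] == expected if sid == "27" else True
        assert harmonized.provenance[("27", "adjuvant_radiotherapy")] == "override"

    def test_ispy2_arm_implies_cyclophosphamide(self, tmp_path, cdm):
        harmonized, _, _ = self._run(DatasetId.ISPY2, tmp_path, cdm, n=25)
        cyclo = "1310317"
        for row in harmonized.rows:
            assert row["neoadjuvant_chemotherapy"] == "4188539"
            assert cyclo in row["neoadjuvant_chemo_medication"].split("|")

    def test_empty_spec_imputes_everything(self, tmp_path, cdm):
        src, _ = generate_source_csv(
            FixtureConfig(DatasetId.ISPY1, n_subjects=4, seed=1, out_dir=tmp_path)
        )
        table = load_source_table(src, DatasetId.ISPY1)
        empty = MappingSpec(
            dataset_id=DatasetId.ISPY1, subject_column="SUBJECTID", rules=()
        )
        harmonized, cov = harmonize(table, empty, cdm)
        assert cov.concepts_mapped == 0
        assert all(
            cell == "763013" for row in harmonized.rows for cell in row.values()
        )

    def test_dataset_mismatch_rejected(self, tmp_path, cdm):
        src, _ = generate_source_csv(
            FixtureConfig(DatasetId.ISPY1, n_subjects=2, seed=1, out_dir=tmp_path)
        )
        table = load_source_table(src, DatasetId.ISPY1)
        with pytest.raises(MappingSpecError, match="ISPY1"):
            harmonize(table, default_mapping_spec(DatasetId.DUKE), cdm)

    def test_parser_failure_demotes_cell_not_run(self, tmp_path, cdm):
        src, _ = generate_source_csv(
            FixtureConfig(DatasetId.ISPY1, n_subjects=3, seed=2, out_dir=tmp_path)
        )
        frame = pd.read_csv(src, dtype=str, keep_default_na=False)
        frame.loc[0, "AGE"] = "forty-two"
        frame.to_csv(src, index=False)
        table = load_source_table(src, DatasetId.ISPY1)
        harmonized, _ = harmonize(table, default_mapping_spec(DatasetId.ISPY1), cdm)
        assert harmonized.rows[0]["age"] == "763013"
        sid = harmonized.subject_ids[0]
        assert harmonized.provenance[(sid, "age")] == "imputed_parse_failure"

    def test_deterministic_byte_identical_output(self, tmp_path, cdm):
        h1, _, _ = self._run(DatasetId.TCGA_BRCA, tmp_path / "a", cdm, mess=0.4)
        h2, _, _ = self._run(DatasetId.TCGA_BRCA, tmp_path / "b", cdm, mess=0.4)
        p1 = h1.write_csv(tmp_path / "x.csv")
        p2 = h2.write_csv(tmp_path / "y.csv")
        assert p1.read_bytes() == p2.read_bytes()


class TestCoverage:
    EXPECTED = {
        DatasetId.ISPY2: (12, 9, 133),
        DatasetId.DUKE: (36, 74, 49),
        DatasetId.ISPY1: (14, 17, 82),
        DatasetId.TCGA_BRCA: (27, 110, 25),
        DatasetId.NACT: (23, 41, 56),
    }

    @pytest.mark.parametrize("dataset", list(DatasetId))
    def test_shipped_specs_mapped_concepts(self, dataset, cdm):
        mapped, n_source, pct = self.EXPECTED[dataset]
        cov = coverage_report(default_mapping_spec(dataset), cdm)
        assert cov.concepts_mapped == mapped
        assert cov.source_concept_count == n_source
        assert cov.percent_concepts_display == pct

    def test_detailed_plus_generic_can_exceed_100_percent(self, cdm):
        cov = coverage_report(default_mapping_spec(DatasetId.ISPY2), cdm)
        assert cov.percent_concepts > 100

    def test_empty_spec_is_zero(self, cdm):
        cov = coverage_report(
            MappingSpec(dataset_id=DatasetId.NACT, subject_column="PatientID",
                        rules=()),
            cdm,
        )
        assert cov.concepts_mapped == 0 and cov.percent_concepts == 0.0
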