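"""Patient-table I/O, mutation-frequency tables and visit screening."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dystrokit import (
    PatientRecord,
    ScreeningConfig,
    mutation_frequency,
    read_patient_table,
    smart_screen,
)
from dystrokit.cohort import ScreeningConfigError, TableFormatError


class TestPatientTable:
    def _write(self, tmp_path, rows, header="patient_id\tmutation\tphenotype"):
        p = tmp_path / "patients.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return p

    def test_reads_rows_and_phenotypes(self, tmp_path):
        p = self._write(
            tmp_path,
            ["P1\texon45-47del\tBMD", "P2\texon45del\tDMD", "P3\tc.100A>G\t"],
        )
        records = read_patient_table(p)
        assert len(records) == 3
        assert records[0].observed_phenotype == "BMD"
        assert records[2].observed_phenotype == "unknown"
        assert not any(r.filtered for r in records)

    def test_unparseable_row_flagged_filtered(self, tmp_path, caplog):
        p = self._write(tmp_path, ["P1\tc.1335ins680\tDMD", "P2\texon2dup\tBMD"])
        with caplog.at_level("WARNING"):
            records = read_patient_table(p)
        assert records[0].filtered and not records[1].filtered
        assert "c.1335ins680" in caplog.text

    def test_missing_mutation_column(self, tmp_path):
        p = self._write(tmp_path, ["P1\tBMD"], header="patient_id\tphenotype")
        with pytest.raises(TableFormatError, match="mutation"):
            read_patient_table(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(TableFormatError):
            read_patient_table(p)

    def test_empty_patient_id_rejected(self):
        with pytest.raises(TableFormatError):
            PatientRecord(patient_id="", mutation_text="exon2del")


class TestMutationFrequency:
    def _cohort(self):
        texts = (
            ["exon45del"] * 3 + ["exon45-47del"] * 2 + ["exon2dup"] * 1
            + ["c.100A>G"] * 2
        )
        return [
            PatientRecord(patient_id=f"P{i}", mutation_text=t)
            for i, t in enumerate(texts)
        ]

    def test_deletion_counts_sorted_descending(self):
        freq = mutation_frequency(self._cohort(), kind="del", top_n=10)
        assert list(freq["mutation"]) == ["45del", "45-47del"]
        assert list(freq["count"]) == [3, 2]

    def test_duplication_counts(self):
        freq = mutation_frequency(self._cohort(), kind="dup", top_n=5)
        assert freq.to_dict("records") == [{"mutation": "2dup", "count": 1}]

    def test_top_one_returns_mode(self):
        freq = mutation_frequency(self._cohort(), kind="all", top_n=1)
        assert len(freq) == 1
        assert freq.iloc[0]["mutation"] == "45del"

    def test_count_ties_break_by_5prime_exon(self):
        records = [
            PatientRecord(patient_id=f"P{i}", mutation_text=t)
            for i, t in enumerate(["exon50del", "exon3del", "exon50del", "exon3del"])
        ]
        freq = mutation_frequency(records, kind="del", top_n=10)
        assert list(freq["mutation"]) == ["3del", "50del"]

    def test_total_counts_bounded_by_unfiltered_records(self):
        cohort = self._cohort() + [
            PatientRecord(patient_id="PX", mutation_text="bogus", filtered=True)
        ]
        freq = mutation_frequency(cohort, kind="all", top_n=100)
        assert freq["count"].sum() <= sum(not r.filtered for r in cohort)

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            mutation_frequency(self._cohort(), kind="del", top_n=0)
        with pytest.raises(ValueError):
            mutation_frequency(self._cohort(), kind="inversions")


def _visits():
    # one DMD boy, three visits, four indicators with holes
    return pd.DataFrame(
        {
            "id": [1, 1, 1],
            "visit": [1, 2, 3],
            "Age": [8.5, 9.2, 10.5],
            "BMI": [19.5, None, 13.9],
            "LVEDD": [37.0, 41.0, None],
            "SNIP": [11.3, 51.0, 25.8],
            "WISC": [None, None, 85.0],
        }
    )


class TestSmartScreen:
    def test_unit_weights_score_completeness(self):
        out = smart_screen(_visits())
        scores = dict(zip(out["visit"], out["score"]))
        assert scores == {1: 4.0, 2: 3.0, 3: 4.0}
        # most informative visits first
        assert list(out["score"]) == sorted(out["score"], reverse=True)

    def test_indispensable_discards_incomplete_visits(self):
        cfg = ScreeningConfig(indispensable={"WISC"})
        out = smart_screen(_visits(), cfg)
        assert list(out["visit"]) == [3]

    def test_custom_weights(self):
        cfg = ScreeningConfig(weights={"LVEDD": 2.0})
        out = smart_screen(_visits(), cfg)
        scores = dict(zip(out["visit"], out["score"]))
        # visit 1: Age+BMI+SNIP (1 each) + LVEDD (2) = 5
        assert scores[1] == 5.0
        assert scores[3] == 4.0  # LVEDD missing

    def test_value_mode_sums_measurements(self):
        cfg = ScreeningConfig(mode="value")
        out = smart_screen(_visits(), cfg)
        scores = dict(zip(out["visit"], out["score"]))
        assert scores[1] == pytest.approx(8.5 + 19.5 + 37.0 + 11.3)

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ScreeningConfigError):
            smart_screen(_visits(), ScreeningConfig(weights={"CK": 1.0}))
        with pytest.raises(ScreeningConfigError):
            ScreeningConfig(weights={"Age": -1.0})

    def test_scores_invariant_to_column_order(self):
        df = _visits()
        shuffled = df[["WISC", "visit", "SNIP", "id", "Age", "BMI", "LVEDD"]]
        a = smart_screen(df).set_index("visit")["score"]
        b = smart_screen(shuffled).set_index("visit")["score"]
        assert a.to_dict() == b.to_dict()

    def test_discarding_is_idempotent(self):
        cfg = ScreeningConfig(indispensable={"BMI"})
        once = smart_screen(_visits(), cfg)
        twice = smart_screen(once.drop(columns="score"), cfg)
        assert list(once["visit"]) == list(twice["visit"])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        present=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=1,
            max_size=8,
        )
    )
    def test_presence_score_equals_row_sum(self, present):
        df = pd.DataFrame(
            [
                {
                    "id": 1,
                    "visit": i + 1,
                    "a": 1.0 if pa else None,
                    "b": 2.0 if pb else None,
                    "c": 3.0 if pc else None,
                }
                for i, (pa, pb, pc) in enumerate(present)
            ]
        )
        out = smart_screen(df).set_index("visit")
        for i, (pa, pb, pc) in enumerate(present):
            assert out.loc[i + 1, "score"] == float(pa + pb + pc)
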