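"""Record parsing, validation, and reproductive-status classification."""

import datetime as dt
import math

import pytest

from cetrepro.records import (
    Maturity,
    NecropsyRecord,
    RecordError,
    ReproductiveClass,
    classify_maturity,
    classify_records,
    classify_reproductive_class,
    parse_age,
    read_records,
    records_to_frame,
    summarize_by_class,
    write_records,
)

HEADER = ("id,event_date,event_type,tbl_cm,age_years,corpora_left,corpora_right,"
          "cl_left,cl_right,cl_diameter_mm,ovary_weight_left_g,ovary_weight_right_g,"
          "lactating,foetus_tbl_cm,foetus_sex,largest_follicle_mm,decomposition")


def make_record(**kw):
    base = dict(id="X1", event_date=dt.date(2010, 3, 15))
    base.update(kw)
    return NecropsyRecord(**base)


def write_csv(tmp_path, rows, name="r.csv"):
    p = tmp_path / name
    p.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadRecords:
    def test_censored_age_parsed_as_bound_plus_flag(self, tmp_path):
        p = write_csv(tmp_path, ["A,2005-06-01,stranding,183,≥9,,,,,,,,,,,,"])
        (rec,) = read_records(p)
        assert rec.age_years == 9.0 and rec.age_censored
        assert rec.tbl_cm == 183.0

    @pytest.mark.parametrize("cell,expected", [
        ("8.5", (8.5, False)), (">=9", (9.0, True)), (">20", (20.0, True)),
        ("≥ 12", (12.0, True)), ("", (None, False)),
    ])
    def test_age_syntax(self, cell, expected):
        assert parse_age(cell) == expected

    def test_empty_foetus_cell_is_missing(self, tmp_path):
        p = write_csv(tmp_path, ["A,2005-06-01,stranding,120,2,0,0,false,false,,,,false,,,,fresh"])
        (rec,) = read_records(p)
        assert rec.foetus_tbl_cm is None
        assert rec.foetus_sex is None

    def test_negative_tbl_rejected_with_row_number(self, tmp_path):
        p = write_csv(tmp_path, ["A,2005-06-01,stranding,-5,2,,,,,,,,,,,,"])
        with pytest.raises(RecordError, match="row 1"):
            read_records(p)

    def test_unparseable_date_rejected(self, tmp_path):
        p = write_csv(tmp_path, ["A,06/01/2005,stranding,120,2,,,,,,,,,,,,"])
        with pytest.raises(RecordError, match="row 1"):
            read_records(p)

    def test_duplicate_id_rejected(self, tmp_path):
        rows = ["A,2005-06-01,stranding,120,2,,,,,,,,,,,,",
                "A,2006-06-01,stranding,130,3,,,,,,,,,,,,"]
        with pytest.raises(RecordError, match="duplicate"):
            read_records(write_csv(tmp_path, rows))

    def test_schema_mapping_renames_columns(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("ID,Date,Length\nA,2005-06-01,150\n")
        recs = read_records(p, {"id": "ID", "event_date": "Date", "tbl_cm": "Length"})
        assert recs[0].tbl_cm == 150.0

    def test_roundtrip_write_read_identical(self, tmp_path, sim_default):
        records, _ = sim_default
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_records(records, p1)
        again = read_records(p1)
        write_records(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert records_to_frame(records).equals(records_to_frame(again))


class TestClassification:
    def test_no_corpora_no_evidence_of_breeding_is_immature(self):
        rec = make_record(corpora_left=0, corpora_right=0, lactating=False)
        assert classify_maturity(rec) is Maturity.immature

    def test_any_corpora_is_mature(self):
        rec = make_record(corpora_left=9, corpora_right=3, lactating=False)
        assert classify_maturity(rec) is Maturity.mature

    def test_lactation_alone_is_mature_without_ovaries(self):
        rec = make_record(lactating=True)
        assert classify_maturity(rec) is Maturity.mature

    def test_all_evidence_missing_is_undetermined_not_immature(self):
        rec = make_record(tbl_cm=190.0)
        assert classify_maturity(rec) is Maturity.undetermined

    def test_foetus_plus_milk_is_pregnant_lactating(self):
        rec = make_record(foetus_tbl_cm=6.1, lactating=True, corpora_left=3)
        assert classify_reproductive_class(rec) is ReproductiveClass.pregnant_lactating

    def test_corpora_only_is_resting_mature(self):
        rec = make_record(corpora_left=10, corpora_right=4, lactating=False)
        assert classify_reproductive_class(rec) is ReproductiveClass.resting_mature

    def test_milk_without_foetus_is_lactating(self):
        rec = make_record(lactating=True, corpora_left=5, corpora_right=0)
        assert classify_reproductive_class(rec) is ReproductiveClass.lactating

    def test_mammary_state_unassessed_is_indeterminate(self):
        rec = make_record(corpora_left=5)
        assert classify_reproductive_class(rec) is ReproductiveClass.indeterminate_mature

    def test_classifying_immature_record_is_contract_error(self):
        rec = make_record(corpora_left=0, corpora_right=0, lactating=False)
        with pytest.raises(ValueError):
            classify_reproductive_class(rec)

    def test_partition_conserved_on_simulated_population(self, sim_default):
        records, _ = sim_default
        cls = classify_records(records)
        mature = cls[cls["maturity"] == "mature"]
        assert len(mature) == mature["repro_class"].notna().sum()
        counts = mature["repro_class"].value_counts()
        assert counts.sum() == len(mature)
        assert set(counts.index) <= {c.value for c in ReproductiveClass} - {"immature"}


class TestSummary:
    def test_three_record_class_mean_and_se(self):
        recs = [make_record(id=f"R{i}", tbl_cm=t, corpora_left=5, lactating=False)
                for i, t in enumerate((190.0, 200.0, 210.0))]
        df = summarize_by_class(recs)
        row = df[(df.repro_class == "resting_mature") & (df.variable == "tbl_cm")].iloc[0]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(200.0)
        assert row["se"] == pytest.approx(10.0 / math.sqrt(3), abs=1e-6)
        assert (row["min"], row["max"]) == (190.0, 210.0)

    def test_single_record_class_has_null_se(self):
        df = summarize_by_class([make_record(tbl_cm=200.0, corpora_left=4, lactating=False)])
        row = df[(df.repro_class == "resting_mature") & (df.variable == "tbl_cm")].iloc[0]
        assert row["n"] == 1 and math.isnan(row["se"])

    def test_per_class_counts_sum_to_total_classified(self, sim_default):
        records, _ = sim_default
        df = summarize_by_class(records)
        per_class = df[df.variable == "tbl_cm"].set_index("repro_class")["n_class"]
        classified = classify_records(records)["repro_class"].notna().sum()
        classes = [c.value for c in ReproductiveClass]
        assert per_class.loc[classes].sum() == classified
        assert per_class.loc["total"] == classified

    def test_censored_ages_excluded_from_age_statistics(self):
        recs = [make_record(id="A", age_years=9.0, age_censored=True,
                            corpora_left=0, corpora_right=0, lactating=False),
                make_record(id="B", age_years=4.0, corpora_left=0, corpora_right=0,
                            lactating=False)]
        df = summarize_by_class(recs)
        row = df[(df.repro_class == "immature") & (df.variable == "age_years")].iloc[0]
        assert row["n"] == 1 and row["mean"] == pytest.approx(4.0)
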