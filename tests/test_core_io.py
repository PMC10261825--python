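"""Sample CSV parsing, unit conversion, censoring substitution and config loading."""

import io
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggrisk import (
    ConfigError,
    FormatError,
    SampleRecord,
    SampleTable,
    ValidationError,
    load_config,
    read_samples,
    substitute_loq,
    write_samples,
)

HEADER = "sample_id,brand,analyte,concentration,censored,loq\n"


def read_csv_text(text, unit="µg/kg"):
    return read_samples(io.StringIO(HEADER + text), unit=unit)


class TestReadSamples:
    @pytest.mark.parametrize(
        "row,unit,conc,censored,loq",
        [
            ("E01,B1,Pb,7.2,,", "µg/kg", 7.2, False, None),
            ("E02,B1,Cd,0.005,,", "mg/kg", 5.0, False, None),
            ("E03,B2,Cd,<LOQ,,1.0", "µg/kg", 0.0, True, 1.0),
            ("E04,B2,Pb,,,0.4", "µg/kg", 0.0, True, 0.4),
            ("E05,B3,Pb,3.5,true,1.0", "µg/kg", 3.5, True, 1.0),
            ("E06,B3,Pb,7.2,,", "ppb", 7.2, False, None),
        ],
    )
    def test_row_parsing(self, row, unit, conc, censored, loq):
        rec = read_csv_text(row, unit=unit).records[0]
        assert rec.concentration == pytest.approx(conc)
        assert rec.censored is censored
        assert rec.loq == (pytest.approx(loq) if loq is not None else None)

    def test_loq_converted_with_unit(self):
        rec = read_csv_text("E01,B1,Cd,<LOQ,,0.001", unit="mg/kg").records[0]
        assert rec.loq == pytest.approx(1.0)

    def test_missing_column_names_the_column(self):
        stream = io.StringIO("sample_id,brand,concentration\nE01,B1,7.2\n")
        with pytest.raises(FormatError, match="analyte"):
            read_samples(stream)

    def test_negative_concentration_reports_row(self):
        with pytest.raises(ValidationError, match="row 3"):
            read_csv_text("E01,B1,Pb,7.2,,\nE02,B1,Pb,-1.0,,")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ConfigError, match="unit"):
            read_csv_text("E01,B1,Pb,7.2,,", unit="mol/L")

    def test_row_order_preserved(self):
        table = read_csv_text("E2,B1,Pb,2,,\nE1,B1,Pb,1,,\nE3,B1,Pb,3,,")
        assert [r.sample_id for r in table] == ["E2", "E1", "E3"]

    def test_duplicate_sample_analyte_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            read_csv_text("E1,B1,Pb,2,,\nE1,B1,Pb,3,,")


class TestRoundTrip:
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1e4,
                          allow_nan=False, allow_infinity=False),
                st.booleans(),
                st.floats(min_value=1e-3, max_value=10,
                          allow_nan=False, allow_infinity=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_write_read_roundtrip_exact(self, rows):
        records = tuple(
            SampleRecord(f"E{i}", "B1", "Pb", conc if not cens else 0.0,
                         censored=cens, loq=loq if cens else None)
            for i, (conc, cens, loq) in enumerate(rows)
        )
        table = SampleTable(records=records)
        buf = io.StringIO()
        write_samples(table, buf)
        buf.seek(0)
        back = read_samples(buf)
        for a, b in zip(table, back):
            assert a.concentration == b.concentration  # full precision via repr
            assert a.censored == b.censored
            assert a.loq == b.loq

    def test_roundtrip_after_substitution(self, tmp_path):
        table = substitute_loq(SampleTable(records=(
            SampleRecord("E1", "B1", "Pb", 0.0, censored=True, loq=0.3),
        )))
        path = tmp_path / "s.csv"
        write_samples(table, path)
        back = read_samples(path)
        assert back.records[0].concentration == pytest.approx(0.15)
        assert back.records[0].censored


class TestSubstituteLoq:
    def test_censored_gets_half_loq_and_stays_flagged(self):
        table = SampleTable(records=(
            SampleRecord("E1", "B1", "Cd", 0.0, censored=True, loq=1.0),
            SampleRecord("E2", "B1", "Cd", 2.400),
        ))
        out = substitute_loq(table)
        assert out.records[0].concentration == pytest.approx(0.5)
        assert out.records[0].censored
        assert out.records[1].concentration == pytest.approx(2.400)

    def test_elementwise_rule(self):
        loqs = (0.2, 0.4, 0.6)
        table = SampleTable(records=tuple(
            SampleRecord(f"E{i}", "B1", "Pb", 0.0, censored=True, loq=q)
            for i, q in enumerate(loqs)
        ))
        out = substitute_loq(table)
        assert [r.concentration for r in out] == pytest.approx([0.1, 0.2, 0.3])

    def test_input_not_mutated_and_idempotent(self):
        table = SampleTable(records=(
            SampleRecord("E1", "B1", "Pb", 0.0, censored=True, loq=1.0),
        ))
        once = substitute_loq(table)
        assert table.records[0].concentration == 0.0
        twice = substitute_loq(once)
        assert [r.concentration for r in twice] == [r.concentration for r in once]

    def test_censored_without_loq_rejected(self):
        with pytest.raises(ValidationError):
            SampleRecord("E1", "B1", "Pb", 0.0, censored=True, loq=None)


class TestLoadConfig:
    def test_empty_config_gives_study_defaults(self):
        ep, analytes = load_config(None)
        assert (ep.fir, ep.wab, ep.ef, ep.ed, ep.ta) == (25.4, 70, 365, 70, 25550)
        pb, cd = analytes["Pb"], analytes["Cd"]
        assert (pb.rfd, pb.csf, pb.ptwi) == (0.004, 0.0085, 25)
        assert (pb.ml_faowho, pb.ml_isiri) == (500, 100)
        assert (cd.rfd, cd.csf, cd.ptwi, cd.ptmi) == (0.001, None, 7, 25)
        assert (cd.ml_faowho, cd.ml_isiri) == (50, 50)

    def test_override_single_field(self):
        ep, _ = load_config({"exposure": {"wab_kg": 60}})
        assert ep.wab == 60
        assert ep.fir == 25.4

    def test_consistent_short_duration_accepted_silently(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ep, _ = load_config(
                {"exposure": {"ed_years": 1, "ef_days_per_year": 365, "ta_days": 365}}
            )
        assert ep.ta == 365

    def test_inconsistent_averaging_time_warns(self):
        with pytest.warns(UserWarning, match="ef\\*ed"):
            load_config({"exposure": {"ta_days": 1000}})

    def test_unknown_key_warns_not_fatal(self):
        with pytest.warns(UserWarning, match="unknown"):
            ep, _ = load_config({"exposure": {"shoe_size": 43}})
        assert ep.fir == 25.4

    def test_yaml_stream(self):
        ep, analytes = load_config(io.StringIO(
            "exposure:\n  wab_kg: 60\nanalyte:\n  Pb:\n    rfd: 0.005\n"
        ))
        assert ep.wab == 60
        assert analytes["Pb"].rfd == 0.005
        assert analytes["Pb"].csf == 0.0085  # untouched defaults retained
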