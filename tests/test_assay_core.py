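import math

import pandas as pd
import pytest

from uvtox.assay_core import (
    REQUIRED_COLUMNS,
    AssaySeries,
    Compound,
    Observation,
    load_assay_table,
    series_to_frame,
    validate_series,
    write_results_table,
)
from uvtox.dose_response import PotencyEstimate, RegressionFit
from uvtox.errors import SchemaError, ValidationError
from uvtox.mixtures import MixtureComponent, ToxicUnitResult


def make_row(**kw):
    row = {
        "compound": "BP-2", "organism": "artemia_franciscana",
        "endpoint": "mortality", "exposure_time": 48, "time_unit": "h",
        "concentration": 10.0, "conc_unit": "mg_per_L", "replicate": 1,
        "response_kind": "affected_count", "value": 5,
    }
    row.update(kw)
    return row


def write_csv(tmp_path, rows):
    path = tmp_path / "obs.csv"
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)
    return path


class TestLoadAssayTable:
    def test_empty_data_section_gives_empty_list(self, tmp_path):
        path = write_csv(tmp_path, [])
        assert load_assay_table(path) == []

    def test_groups_by_exposure_time(self, tmp_path):
        rows = [make_row(exposure_time=t, concentration=c,
                         response_kind="inhibition_pct", value=30)
                for t in (24, 48) for c in (1.0, 2.0, 4.0)]
        series = load_assay_table(write_csv(tmp_path, rows))
        assert len(series) == 2
        assert all(len(s.observations) == 3 for s in series)
        assert {s.exposure_time for s in series} == {24, 48}

    def test_grouping_is_a_partition_of_input_rows(self, tmp_path):
        rows = [make_row(exposure_time=t, concentration=c, replicate=r,
                         response_kind="inhibition_pct", value=10)
                for t in (24, 48) for c in (1.0, 2.0) for r in (1, 2, 3)]
        series = load_assay_table(write_csv(tmp_path, rows))
        assert sum(len(s.observations) for s in series) == len(rows)

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame([{"compound": "X", "value": 1}]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="conc_unit"):
            load_assay_table(path)

    def test_affected_exceeding_total_rejected(self, tmp_path):
        rows = [make_row(response_kind="affected_count", value=7),
                make_row(response_kind="total_count", value=5)]
        path = write_csv(tmp_path, rows)
        with pytest.raises(ValidationError, match="affected_count"):
            load_assay_table(path)
        report = load_assay_table(path, errors="collect")
        assert report.series == []
        assert len(report.rejected) == 2
        assert "affected_count" in report.rejected["reason"].iloc[0]

    def test_mixed_conc_units_rejected(self, tmp_path):
        rows = [make_row(conc_unit="mg_per_L", response_kind="inhibition_pct"),
                make_row(conc_unit="percent_of_stock", concentration=50,
                         response_kind="inhibition_pct")]
        with pytest.raises(ValidationError, match="mixed conc_unit"):
            load_assay_table(write_csv(tmp_path, rows))

    def test_tidy_frame_round_trip(self, tmp_path):
        rows = [make_row(concentration=c, replicate=r,
                         response_kind=k, value=v)
                for c in (0.0, 5.0) for r in (1, 2)
                for k, v in [("affected_count", 3), ("total_count", 10)]]
        path = write_csv(tmp_path, rows)
        series = load_assay_table(path)
        back = series_to_frame(series)
        path2 = tmp_path / "again.csv"
        back.to_csv(path2, index=False)
        again = load_assay_table(path2)
        assert [s.key for s in again] == [s.key for s in series]
        assert series_to_frame(again).equals(back)


class TestDomainTypes:
    def test_compound_code_required(self):
        with pytest.raises(ValidationError):
            Compound("")

    def test_compound_log_kow_finite(self):
        with pytest.raises(ValidationError):
            Compound("X", log_kow=math.inf)

    @pytest.mark.parametrize("kw", [
        {"value": math.nan},
        {"concentration": -1.0},
        {"replicate": 0},
        {"response_kind": "frond_area_day1", "value": -2.0},
        {"response_kind": "inhibition_pct", "value": 120.0},
        {"conc_unit": "molar"},
    ])
    def test_observation_invariants(self, kw):
        base = dict(concentration=1.0, conc_unit="mg_per_L", replicate=1,
                    response_kind="inhibition_pct", value=10.0)
        base.update(kw)
        with pytest.raises(ValidationError):
            Observation(**base)

    def test_series_rejects_mixed_units_and_bad_time(self):
        obs = [Observation(1.0, "mg_per_L", 1, "inhibition_pct", 10.0),
               Observation(50.0, "percent_of_stock", 1, "inhibition_pct", 10.0)]
        with pytest.raises(ValidationError):
            AssaySeries(Compound("X"), "aliivibrio_fischeri",
                        "luminescence_inhibition", 30, "min", obs)
        with pytest.raises(ValidationError):
            AssaySeries(Compound("X"), "aliivibrio_fischeri",
                        "luminescence_inhibition", -5, "min", [])

    def test_time_normalisation_to_minutes(self):
        s = AssaySeries(Compound("X"), "daphnia_magna", "immobilization",
                        48, "h", [])
        assert s.exposure_time_minutes == 48 * 60


class TestValidateSeries:
    def make_series(self, obs):
        return AssaySeries(Compound("X"), "aliivibrio_fischeri",
                           "luminescence_inhibition", 30, "min", obs)

    def test_single_concentration_flagged(self):
        obs = [Observation(5.0, "mg_per_L", r, "inhibition_pct", 20.0)
               for r in (1, 2)]
        codes = [f.code for f in validate_series(self.make_series(obs))]
        assert "too_few_concentrations" in codes

    def test_missing_control_for_raw_luminescence(self):
        obs = [Observation(c, "mg_per_L", 1, "luminescence_t", 90.0)
               for c in (1.0, 2.0)]
        codes = [f.code for f in validate_series(self.make_series(obs))]
        assert "missing_control" in codes

    def test_well_formed_series_has_no_findings(self):
        obs = [Observation(c, "mg_per_L", 1, "inhibition_pct", 20.0)
               for c in (1.0, 2.0, 4.0)]
        assert validate_series(self.make_series(obs)) == []


class TestWriteResultsTable:
    def test_empty_results_write_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results_table([], path, kind="tu")
        df = pd.read_csv(path)
        assert list(df.columns) == ["mixture_id", "components", "tu_mix",
                                    "interaction"]
        assert df.empty

    def test_tu_row_joins_component_codes(self, tmp_path):
        comp = (MixtureComponent("BP-1", 10, 9.47),
                MixtureComponent("BP-2", 10, 4.52))
        res = ToxicUnitResult("m1", comp, (1.0560, 2.2124), 3.2684,
                              "antagonism")
        path = tmp_path / "out.csv"
        write_results_table([res], path)
        df = pd.read_csv(path)
        assert df.loc[0, "components"] == "BP-1+BP-2"
        assert df.loc[0, "tu_mix"] == 3.27  # rendered at 2 dp

    def test_potency_round_trip_to_rendered_precision(self, tmp_path):
        fit = RegressionFit("linear", 10.0, 4.0, 0.987654, 4, 0.77)
        est = PotencyEstimate("EC", 50.0, 9.4712, fit, compound="BP-1",
                              organism="aliivibrio_fischeri",
                              exposure_time=30, time_unit="min")
        path = tmp_path / "out.csv"
        write_results_table([est], path, decimals=2)
        df = pd.read_csv(path)
        assert df.loc[0, "value"] == round(est.value, 2)
        assert df.loc[0, "r2"] == round(fit.r_squared, 2)

    def test_heterogeneous_results_rejected(self, tmp_path):
        fit = RegressionFit("linear", 0.0, 1.0, 1.0, 3, 0.77)
        est = PotencyEstimate("EC", 50.0, 1.0, fit)
        res = ToxicUnitResult("m", (MixtureComponent("A", 1, 1),), (1.0,),
                              1.0, "additive")
        with pytest.raises(ValidationError):
            write_results_table([est, res], tmp_path / "x.csv")
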