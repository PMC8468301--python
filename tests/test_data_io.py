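import numpy as np
import pandas as pd
import pytest

from ifxmipd.data_io import (CleaningConfig, EventTable, RecordError,
                             SchemaError, apply_exclusion_cascade,
                             covariate_value_at, parse_event_table)
from ifxmipd.synthetic_cohort import generate_cohort

from conftest import single_patient_table


def write_csv(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParsing:
    def test_single_dose_and_observation(self, tmp_path):
        p = write_csv(tmp_path,
                      "ID,TIME,EVID,AMT,DUR,DV,MDV\n"
                      "1,0,1,350,2,,1\n"
                      "1,672,0,,,12.1,0\n")
        t = parse_event_table(p)
        assert t.n_patients == 1
        assert t.n_observations == 1
        assert len(t.doses(1)) == 1
        assert t.observations(1)["DV"].iloc[0] == 12.1

    def test_ng_per_ml_unit_conversion(self, tmp_path):
        p = write_csv(tmp_path, "ID,TIME,EVID,AMT,DUR,DV,MDV\n1,0,1,350,2,,1\n"
                                "1,672,0,,,12100,0\n")
        t = parse_event_table(p, dv_unit="ng/mL")
        assert t.observations(1)["DV"].iloc[0] == pytest.approx(12.1)

    def test_missing_dv_with_mdv_is_kept_not_an_error(self, tmp_path):
        p = write_csv(tmp_path, "ID,TIME,EVID,AMT,DUR,DV,MDV\n1,0,1,350,2,,1\n"
                                "1,672,0,,,,1\n")
        t = parse_event_table(p)
        assert t.n_observations == 0           # no measured DV
        assert len(t.observations(1, with_dv=False)) == 1

    def test_empty_dv_without_mdv_becomes_missing_record(self, tmp_path):
        p = write_csv(tmp_path, "ID,TIME,EVID,AMT,DUR,DV,MDV\n1,0,1,350,2,,1\n"
                                "1,672,0,,,,0\n")
        assert parse_event_table(p).n_observations == 0

    def test_rate_converted_to_duration(self, tmp_path):
        p = write_csv(tmp_path, "ID,TIME,EVID,AMT,RATE,DV,MDV\n1,0,1,350,175,,1\n"
                                "1,672,0,,,10,0\n")
        assert parse_event_table(p).doses(1)["DUR"].iloc[0] == pytest.approx(2.0)

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        p = write_csv(tmp_path, "ID,TIME,AMT,DV\n1,0,350,\n")
        with pytest.raises(SchemaError, match="EVID"):
            parse_event_table(p)

    def test_dose_without_time_is_record_error(self, tmp_path):
        p = write_csv(tmp_path, "ID,TIME,EVID,AMT,DUR,DV,MDV\n1,,1,350,2,,1\n"
                                "1,672,0,,,10,0\n")
        with pytest.raises(RecordError, match="dose row without time"):
            parse_event_table(p)
        t = parse_event_table(p, allow_missing_dose_times=True)
        assert t.n_patients == 1

    def test_column_map_renames(self, tmp_path):
        p = write_csv(tmp_path, "subj,t,evid,amt,dur,conc,mdv\n1,0,1,350,2,,1\n"
                                "1,672,0,,,10,0\n")
        t = parse_event_table(p, column_map={"subj": "ID", "t": "TIME",
                                             "evid": "EVID", "amt": "AMT",
                                             "dur": "DUR", "conc": "DV",
                                             "mdv": "MDV"})
        assert t.n_observations == 1


class TestExclusionCascade:
    def test_implausible_later_sample_removed(self):
        # 8 µg/mL on day 3 followed by 9 µg/mL on day 12 of the same interval
        t = single_patient_table([(3 * 24.0, 8.0), (12 * 24.0, 9.0)],
                                 doses=((0.0, 385.0, 2.0), (1344.0, 385.0, 2.0)))
        clean, rep = apply_exclusion_cascade(t)
        assert rep.implausible_samples == 1
        assert clean.observations("P1")["TIME"].tolist() == [3 * 24.0]

    def test_plausible_decrease_is_kept(self):
        t = single_patient_table([(3 * 24.0, 9.0), (12 * 24.0, 8.0)],
                                 doses=((0.0, 385.0, 2.0), (1344.0, 385.0, 2.0)))
        _, rep = apply_exclusion_cascade(t)
        assert rep.implausible_samples == 0

    def test_non_decreasing_across_intervals_is_kept(self):
        # the implausibility rule only applies within one dosing interval
        t = single_patient_table([(600.0, 5.0), (1400.0, 9.0)],
                                 doses=((0.0, 385.0, 2.0), (1344.0, 385.0, 2.0)))
        _, rep = apply_exclusion_cascade(t)
        assert rep.implausible_samples == 0

    def test_blq_removed_at_stage_two(self):
        t = single_patient_table([(600.0, 0.001), (700.0, 8.0)])
        clean, rep = apply_exclusion_cascade(t)
        assert rep.blq_samples == 1
        assert clean.n_observations == 1

    def test_patient_with_only_blq_is_uninformative(self):
        t = single_patient_table([(600.0, 0.001)])
        clean, rep = apply_exclusion_cascade(t)
        assert rep.blq_samples == 1
        assert rep.uninformative_patients == 1
        assert clean.n_patients == 0

    def test_empty_input_zero_report(self):
        t = EventTable(pd.DataFrame(columns=["ID", "TIME", "EVID", "DV"]))
        clean, rep = apply_exclusion_cascade(t)
        assert clean.n_patients == 0
        assert rep.to_dict()["removed_samples"] == 0

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_conservation_and_idempotence(self, seed):
        from ifxmipd.synthetic_cohort import SyntheticCohortConfig
        table, _ = generate_cohort(SyntheticCohortConfig(n_patients=25), seed=seed)
        n_in = table.n_observations
        clean, rep = apply_exclusion_cascade(table)
        assert rep.retained_samples + rep.removed_samples == n_in
        clean2, rep2 = apply_exclusion_cascade(clean)
        assert rep2.removed_samples == 0
        assert rep2.uninformative_patients == 0
        pd.testing.assert_frame_equal(clean.df, clean2.df)


class TestCovariateLookup:
    def test_single_value_any_policy(self):
        t = single_patient_table([(0.0, 10.0)], covs={"ALB": 4.0})
        assert covariate_value_at(t, "P1", "ALB", 5000.0, "full") == 4.0
        assert covariate_value_at(t, "P1", "ALB", 5000.0, "locf_at_anchor",
                                  anchor=672.0) == 4.0

    def test_locf_freezes_at_anchor_full_does_not(self):
        df = pd.DataFrame([
            {"ID": "P1", "TIME": 0.0, "EVID": 1, "AMT": 385.0, "DUR": 2.0,
             "DV": np.nan, "MDV": 1, "ALB": 4.0},
            {"ID": "P1", "TIME": 1344.0, "EVID": 0, "AMT": np.nan,
             "DUR": np.nan, "DV": 8.0, "MDV": 0, "ALB": 3.5},
        ])
        t = EventTable(df)
        kw = dict(policy="locf_at_anchor", anchor=672.0)
        assert covariate_value_at(t, "P1", "ALB", 1680.0, **kw) == 4.0
        assert covariate_value_at(t, "P1", "ALB", 1680.0, "full") == 3.5

    def test_full_at_anchor_equals_locf(self):
        df = pd.DataFrame([
            {"ID": "P1", "TIME": 0.0, "EVID": 1, "AMT": 385.0, "DUR": 2.0,
             "DV": np.nan, "MDV": 1, "ALB": 4.0},
            {"ID": "P1", "TIME": 500.0, "EVID": 0, "AMT": np.nan,
             "DUR": np.nan, "DV": 9.0, "MDV": 0, "ALB": 3.8},
        ])
        t = EventTable(df)
        for anchor in (0.0, 500.0, 700.0):
            assert (covariate_value_at(t, "P1", "ALB", anchor, "full")
                    == covariate_value_at(t, "P1", "ALB", anchor,
                                          "locf_at_anchor", anchor=anchor))

    def test_missing_measurement_errors_with_names(self):
        t = single_patient_table([(0.0, 10.0)], covs={"WT": 70.0})
        with pytest.raises((KeyError, ValueError), match="ALB"):
            covariate_value_at(t, "P1", "ALB", 100.0)


class TestAdaStatus:
    def test_sample_and_patient_level(self):
        t = single_patient_table([(100.0, 10.0), (900.0, 6.0)],
                                 ada=[1.0, 25.0])
        assert not t.ada_sample_positive("P1", 100.0)
        assert t.ada_sample_positive("P1", 900.0)
        assert t.ada_sample_positive("P1", 2000.0)   # carried forward
        assert t.ada_patient_positive("P1")
        assert t.first_ada_time("P1") == 900.0

    def test_never_measured_is_negative(self):
        t = single_patient_table([(100.0, 10.0)])
        assert not t.ada_patient_positive("P1")
        assert t.first_ada_time("P1") is None

    def test_threshold_is_strict(self):
        t = single_patient_table([(100.0, 10.0)], ada=[6.6])
        assert not t.ada_patient_positive("P1")


def test_cleaning_config_validation():
    with pytest.raises(ValueError):
        CleaningConfig(lloq_conc=-1.0)
    with pytest.raises(ValueError):
        CleaningConfig(ada_positive_threshold=1.0)  # below the ADA LLOQ
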