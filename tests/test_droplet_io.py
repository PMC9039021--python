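"""Amplitude/cohort table IO: dialects, round trips, schema and validation
errors, platform profiles."""

import pytest
import yaml

from raredrop import (
    DropletRecord,
    SimConfig,
    load_platform_profile,
    read_amplitude_csv,
    read_cohort_table,
    simulate_well,
    write_amplitude_csv,
)
from raredrop.droplet_io import DIALECT_COLUMNS, write_truth_sidecar
from raredrop.errors import InvalidParameterError, SchemaError, ValidationError


@pytest.mark.parametrize("dialect", ["droplet", "nanoplate"])
class TestAmplitudeRoundTrip:
    def test_simulated_well_round_trips(self, tmp_path, dialect):
        config = SimConfig(conc_mut=30, conc_wt=60, n_partitions=300, seed=11)
        records, _ = simulate_well(config)
        path = tmp_path / "well.csv"
        write_amplitude_csv(records, path, dialect=dialect)
        assert read_amplitude_csv(path, dialect=dialect) == records

    def test_header_only_file_gives_empty_list(self, tmp_path, dialect):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(DIALECT_COLUMNS[dialect].values()) + "\n")
        assert read_amplitude_csv(path, dialect=dialect) == []


class TestAmplitudeErrors:
    def test_other_dialect_header_raises_schema_error_naming_columns(self, tmp_path):
        path = tmp_path / "wrong.csv"
        path.write_text(",".join(DIALECT_COLUMNS["nanoplate"].values()) + "\n")
        with pytest.raises(SchemaError, match="ch1_amplitude"):
            read_amplitude_csv(path, dialect="droplet")

    def test_negative_amplitude_raises_with_row_index(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "well,sample,ch1_amplitude,ch2_amplitude\n"
            "A01,rep1,100,200\n"
            "A01,rep1,-5,200\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_amplitude_csv(path, dialect="droplet")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(InvalidParameterError):
            read_amplitude_csv(tmp_path / "x.csv", dialect="chip")

    def test_column_map_allows_renamed_exports(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text("well,sample,FAM,ch2_amplitude\nA01,rep1,10,20\n")
        records = read_amplitude_csv(path, dialect="droplet",
                                     column_map={"fam_rfu": "FAM"})
        assert records == [DropletRecord("A01", "rep1", 10.0, 20.0)]


class TestDropletRecord:
    @pytest.mark.parametrize("fam,hexv", [(-1.0, 0.0), (0.0, float("nan")),
                                          (float("inf"), 0.0)])
    def test_non_finite_or_negative_amplitudes_rejected(self, fam, hexv):
        with pytest.raises(ValidationError):
            DropletRecord("A01", "rep1", fam, hexv)


class TestCohortTable:
    def test_packaged_fixture_has_21_isolates(self, cohort_records):
        assert len(cohort_records) == 21

    def test_repeat_isolates_preserved_per_row(self, cohort_records):
        by_patient = {}
        for r in cohort_records:
            by_patient.setdefault(r.patient_id, []).append(r)
        assert len(by_patient["11"]) == 3
        assert len(by_patient["12"]) == 2

    def test_measured_zeros_survive_as_zeros(self, cohort_records):
        zeros = [r for r in cohort_records if r.conc_150 == 0.0]
        assert {r.patient_id for r in zeros} == {"6", "15", "16", "18"}

    def test_route_codes_parsed(self, cohort_records):
        routes = {r.collection_route for r in cohort_records}
        assert routes == {"VAD", "IO", "LP"}

    def test_unknown_route_rejected(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text(
            "patient_id\tisolate_id\tcollection_route\tcsf_volume_ml\t"
            "conc_37\tconc_150\tconc_300\ttissue_h3_status\n"
            "1\t1\tICV\t2\t10\t10\t10\tnegative\n"
        )
        with pytest.raises(ValidationError, match="route"):
            read_cohort_table(path)

    def test_negative_concentration_rejected(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text(
            "patient_id\tisolate_id\tcollection_route\tcsf_volume_ml\t"
            "conc_37\tconc_150\tconc_300\ttissue_h3_status\n"
            "1\t1\tLP\t2\t10\t-4\t10\tnegative\n"
        )
        with pytest.raises(ValidationError):
            read_cohort_table(path)

    def test_empty_cell_becomes_null_not_zero(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text(
            "patient_id\tisolate_id\tcollection_route\tcsf_volume_ml\t"
            "conc_37\tconc_150\tconc_300\ttissue_h3_status\n"
            "1\t1\tLP\t2\t10\t\t10\tnegative\n"
        )
        (rec,) = read_cohort_table(path)
        assert rec.conc_150 is None


class TestPlatformProfiles:
    def test_qx200_thresholds(self, qx200):
        assert (qx200.fam_threshold_rfu, qx200.hex_threshold_rfu) == (2000.0, 1500.0)

    def test_qiacuity_thresholds(self, qiacuity):
        assert (qiacuity.fam_threshold_rfu, qiacuity.hex_threshold_rfu) == (40.0, 20.0)

    def test_vpf_defaults_to_one(self):
        assert load_platform_profile("qx200").vpf == 1.0

    def test_config_overrides_vpf(self):
        profile = load_platform_profile("qiacuity", {"qiacuity": {"vpf": 1.05}})
        assert profile.vpf == 1.05
        assert profile.fam_threshold_rfu == 40.0

    def test_unknown_profile_rejected(self):
        with pytest.raises(InvalidParameterError, match="unknown platform profile"):
            load_platform_profile("raindance")


def test_truth_sidecar_is_readable_yaml(tmp_path):
    config = SimConfig(conc_mut=10, conc_wt=10, n_partitions=50, seed=3)
    _, truth = simulate_well(config)
    path = tmp_path / "truth.yaml"
    write_truth_sidecar(truth, path)
    loaded = yaml.safe_load(path.read_text())
    assert loaded["true_vaf"] == pytest.approx(truth.true_vaf)
    assert loaded["copies_mut_loaded"] == truth.copies_mut_loaded
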