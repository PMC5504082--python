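import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hospclimate.ingest import (Cohort, FileDialect, HospitalRecord,
                                MeasureObservation, cohort_summary,
                                filter_singleton_climates, filter_unavailable,
                                read_mortality_file)

DIALECT = FileDialect()


def write_hc_csv(tmp_path, rows):
    cols = ["Provider ID", "ZIP Code", "Measure ID", "Denominator", "Score"]
    path = tmp_path / "mort.csv"
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def obs(provider="P1", measure="MORT_30_HF", deaths=29, denom=200, rate=14.5,
        available=True):
    if not available:
        return MeasureObservation(provider_id=provider, measure_id=measure,
                                  deaths=None, denominator=None, rate=None,
                                  available=False)
    return MeasureObservation(provider_id=provider, measure_id=measure,
                              deaths=deaths, denominator=denom, rate=rate,
                              available=True)


def hospital(provider, climate, fips="01001", n_obs=1):
    return HospitalRecord(provider_id=provider, zip="10001", fips=fips,
                          climate=climate,
                          observations=[obs(provider=provider) for _ in range(n_obs)])


class TestReadMortalityFile:
    def test_score_and_denominator_reconstruct_deaths(self, tmp_path):
        # a 14.6% heart-failure score over 200 patients implies 29 deaths
        path = write_hc_csv(tmp_path, [["P1", "10001", "MORT_30_HF", "200", "14.6"]])
        observations, meta, rejected = read_mortality_file(path)
        (o,) = observations
        assert (o.deaths, o.denominator, o.rate, o.available) == (29, 200, 14.6, True)
        assert rejected == 0
        assert meta.iloc[0].tolist() == ["P1", "10001"]

    def test_not_available_sentinel(self, tmp_path):
        path = write_hc_csv(tmp_path, [
            ["P1", "10001", "MORT_30_HF", "Not Available", "Not Available"]])
        observations, _, _ = read_mortality_file(path)
        assert observations[0].available is False
        assert observations[0].deaths is None

    def test_readmission_rows_discarded(self, tmp_path):
        path = write_hc_csv(tmp_path, [
            ["P1", "10001", "READM_30_HF", "200", "20.0"],
            ["P1", "10001", "MORT_30_HF", "200", "14.6"]])
        observations, _, _ = read_mortality_file(path)
        assert [o.measure_id for o in observations] == ["MORT_30_HF"]

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        observations, meta, rejected = read_mortality_file(path)
        assert observations == [] and rejected == 0

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"Provider ID": ["P1"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="Measure ID"):
            read_mortality_file(path)

    def test_malformed_numeric_rejected_row_level(self, tmp_path):
        path = write_hc_csv(tmp_path, [
            ["P1", "10001", "MORT_30_HF", "200", "garbage"],
            ["P2", "10002", "MORT_30_HF", "100", "10.0"]])
        observations, _, rejected = read_mortality_file(path)
        assert rejected == 1
        assert [o.provider_id for o in observations] == ["P2"]

    @given(denom=st.integers(min_value=1, max_value=999),
           deaths_frac=st.floats(min_value=0.0, max_value=1.0))
    def test_one_decimal_score_reconstructs_counts_exactly(self, denom, deaths_frac):
        """Printing the rate with one decimal loses nothing for
        denominators under 1,000: rounding inverts exactly."""
        deaths = int(round(deaths_frac * denom))
        printed = float(f"{100.0 * deaths / denom:.1f}")
        assert int(round(printed * denom / 100.0)) == deaths


class TestFilters:
    def test_unavailable_count_conservation(self):
        observations = [obs() for _ in range(7)] + [obs(available=False)] * 3
        kept, removed = filter_unavailable(observations)
        assert (len(kept), removed) == (7, 3)
        assert len(observations) == len(kept) + removed

    def test_all_unavailable(self):
        kept, removed = filter_unavailable([obs(available=False)] * 4)
        assert kept == [] and removed == 4

    def test_known_sentinel_count(self):
        observations = [obs() for _ in range(83)] + [obs(available=False)] * 17
        kept, removed = filter_unavailable(observations)
        assert (len(kept), removed) == (83, 17)

    def test_unavailable_idempotent(self):
        observations = [obs(), obs(available=False)]
        once, n1 = filter_unavailable(observations)
        twice, n2 = filter_unavailable(once)
        assert twice == once and n2 == 0

    def test_singleton_climate_removed(self):
        cohort = Cohort(hospitals=[hospital(f"P{i}", "Cfa") for i in range(3)]
                        + [hospital("P9", "ET")])
        out = filter_singleton_climates(cohort)
        assert out.n_hospitals == 3
        assert {h.climate for h in out.hospitals} == {"Cfa"}
        assert out.provenance["singleton_climate"] == 1

    def test_no_singletons_identity_and_idempotence(self):
        cohort = Cohort(hospitals=[hospital(f"P{i}", c) for c in ("Cfa", "Dfa")
                                   for i in range(2)])
        once = filter_singleton_climates(cohort)
        twice = filter_singleton_climates(once)
        assert once.n_hospitals == cohort.n_hospitals == twice.n_hospitals

    def test_two_singletons_among_six_climates(self):
        hospitals = []
        for c in ("Cfa", "Dfa", "BSk", "Csb"):
            hospitals += [hospital(f"P{c}{i}", c) for i in range(2)]
        hospitals += [hospital("PX", "ET"), hospital("PY", "EF")]
        out = filter_singleton_climates(Cohort(hospitals=hospitals))
        assert out.provenance["singleton_climate"] == 2
        assert out.n_climates == 4


class TestCohortSummary:
    def test_empty(self):
        assert cohort_summary(Cohort(hospitals=[])) == (0, 0, 0)

    def test_single_hospital(self):
        assert cohort_summary(Cohort(hospitals=[hospital("P1", "Cfa")])) == (1, 1, 1)

    def test_synthetic_cohort_matches_generator_truth(self, small_data, small_cohort):
        expected = small_data.truth["expected_cohort"]
        assert cohort_summary(small_cohort) == (
            expected["n_hospitals"], expected["n_climates"], expected["n_counties"])


class TestConservation:
    def test_filter_conservation_through_pipeline(self, small_data, small_cohort):
        """Input hospitals = final + every logged hospital-level removal."""
        n_input = len(small_data.hospitals)
        hospital_stages = ("no_available_observations", "unmapped_zip",
                           "county_missing_climate", "county_missing_acs",
                           "singleton_climate")
        removed = sum(small_cohort.provenance[s] for s in hospital_stages)
        assert n_input == small_cohort.n_hospitals + removed

    def test_observation_conservation(self, small_data, small_cohort):
        n_cells = len(small_data.cells)
        kept = sum(h.n_available for h in small_cohort.hospitals)
        dropped_with_hospitals = sum(
            h_cells for provider, h_cells in
            small_data.cells[small_data.cells["available"]]
            .groupby("provider_id").size().items()
            if provider not in {h.provider_id for h in small_cohort.hospitals})
        unavailable = small_cohort.provenance["unavailable_observations"]
        assert n_cells == kept + unavailable + dropped_with_hospitals


class TestObservationValidation:
    def test_rate_must_match_counts(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MeasureObservation(provider_id="P1", measure_id="MORT_30_HF",
                               deaths=50, denominator=200, rate=14.6, available=True)

    def test_deaths_bounded_by_denominator(self):
        with pytest.raises(ValueError, match="deaths"):
            MeasureObservation(provider_id="P1", measure_id="MORT_30_HF",
                               deaths=300, denominator=200, rate=150.0, available=True)

    def test_unavailable_must_be_empty(self):
        with pytest.raises(ValueError):
            MeasureObservation(provider_id="P1", measure_id="MORT_30_HF",
                               deaths=1, denominator=10, rate=10.0, available=False)
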