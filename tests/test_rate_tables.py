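"""Lexis-table data engineering: loading, aggregation, cohorts, utilities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apcmodels import (
    AgeBand,
    PeriodBand,
    RateTable,
    StandardPopulation,
    Stratum,
    aggregate_periods,
    attributable_proportion,
    build_cohorts,
    direct_standardize,
    load_gbd_csv,
    read_wide_pair,
    restrict_ages,
    write_wide_pair,
)
from apcmodels.rate_tables import (
    AggregationError,
    AlignmentError,
    CoverageError,
    EmptySelectionError,
    GBDFormatError,
    parse_band_label,
)

from conftest import gbd_long_csv, noiseless_table
from apcmodels.synthetic import preset_lung_cancer_like


def study_table():
    return noiseless_table(preset_lung_cancer_like())


# ---------------------------------------------------------------------------
# bands
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "label,expected",
    [("20 to 24", (20, 5)), ("20-24", (20, 5)), ("1913–1917", (1913, 5)), ("5 to 9 years", (5, 5))],
)
def test_band_label_parsing(label, expected):
    assert parse_band_label(label) == expected


def test_band_properties():
    b = AgeBand(20, 5)
    assert (b.end, b.label, b.midpoint) == (24, "20-24", 22.0)
    with pytest.raises(ValueError):
        AgeBand(-5, 5)
    with pytest.raises(ValueError):
        PeriodBand(1990, 0)


# ---------------------------------------------------------------------------
# long-format loading
# ---------------------------------------------------------------------------

def test_gbd_load_conserves_rows(tmp_path):
    """30 years x 12 age bands for one stratum -> 360 annual records."""
    path = tmp_path / "gbd.csv"
    gbd_long_csv(path, study_table(), location="China", sex="Male")
    stratum = Stratum(location="China", sex="male", cause="Tracheal, bronchus, and lung cancer")
    rec = load_gbd_csv(path, stratum)
    assert len(rec) == 12 * 30
    assert set(rec.columns) == {"age_start", "age_width", "year", "deaths", "person_years"}


def test_gbd_load_empty_selection(tmp_path):
    path = tmp_path / "gbd.csv"
    gbd_long_csv(path, study_table(), sex="Female")
    with pytest.raises(EmptySelectionError):
        load_gbd_csv(path, Stratum(location="China", sex="male"))


def test_gbd_load_missing_column_named(tmp_path):
    path = tmp_path / "gbd.csv"
    gbd_long_csv(path, study_table())
    df = pd.read_csv(path).drop(columns=["year"])
    df.to_csv(path, index=False)
    with pytest.raises(GBDFormatError, match="year"):
        load_gbd_csv(path, Stratum(location="China", sex="male"))


def test_gbd_load_risk_factor_filter(tmp_path):
    """risk_factor='all' keeps unattributed rows; a named risk selects its own."""
    path = tmp_path / "gbd.csv"
    t = study_table()
    total = gbd_long_csv(path, t, sex="Male", risk=None)
    smoking = t
    df2 = gbd_long_csv(tmp_path / "tmp.csv", smoking, sex="Male", risk="Smoking")
    pd.concat([total, df2[df2.measure == "Deaths"]]).to_csv(path, index=False)
    base = dict(location="China", sex="male", cause="Tracheal, bronchus, and lung cancer")
    rec_all = load_gbd_csv(path, Stratum(**base, risk_factor="all"))
    rec_smk = load_gbd_csv(path, Stratum(**base, risk_factor="Smoking"))
    assert len(rec_all) == len(rec_smk) == 360


# ---------------------------------------------------------------------------
# period aggregation
# ---------------------------------------------------------------------------

def test_aggregation_study_grid_and_conservation(tmp_path):
    """1990-2019 annual records, width 5 -> the six study periods, with
    deaths and person-years totals conserved."""
    t = study_table()
    path = tmp_path / "gbd.csv"
    gbd_long_csv(path, t)
    rec = load_gbd_csv(path, Stratum(location="China", sex="male",
                                     cause="Tracheal, bronchus, and lung cancer"))
    agg = aggregate_periods(rec, 5, t.stratum)
    assert [p.label for p in agg.periods] == [
        "1990-1994", "1995-1999", "2000-2004", "2005-2009", "2010-2014", "2015-2019",
    ]
    assert np.isclose(agg.deaths.sum(), rec["deaths"].sum())
    assert np.isclose(agg.person_years.sum(), rec["person_years"].sum())
    np.testing.assert_allclose(agg.deaths, t.deaths, rtol=1e-12)


def test_aggregation_single_cell_sum():
    rec = pd.DataFrame(
        {
            "age_start": 20, "age_width": 5,
            "year": [1990, 1991, 1992, 1993, 1994],
            "deaths": [1.0, 2.0, 3.0, 4.0, 5.0],
            "person_years": [1e5] * 5,
        }
    )
    table = aggregate_periods(rec, 5)
    assert table.deaths[0, 0] == 15.0
    assert table.person_years[0, 0] == 5e5  # person-time is summed, not averaged


def test_aggregation_incomplete_period_lists_gap():
    rec = pd.DataFrame(
        {
            "age_start": 20, "age_width": 5,
            "year": [1990, 1991, 1992, 1993],
            "deaths": 1.0, "person_years": 1e5,
        }
    )
    with pytest.raises(AggregationError, match="1994"):
        aggregate_periods(rec, 5)


def test_aggregate_then_restrict_matches_restrict_then_aggregate(tmp_path):
    t = study_table()
    path = tmp_path / "gbd.csv"
    gbd_long_csv(path, t)
    rec = load_gbd_csv(path, Stratum(location="China", sex="male",
                                     cause="Tracheal, bronchus, and lung cancer"))
    a = restrict_ages(aggregate_periods(rec, 5), 30, 79)
    b = aggregate_periods(rec[rec.age_start >= 30], 5)
    assert [x.label for x in a.ages] == [x.label for x in b.ages]
    np.testing.assert_allclose(a.deaths, b.deaths, rtol=1e-12)
    np.testing.assert_allclose(a.person_years, b.person_years, rtol=1e-12)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def test_study_grid_cohort_labels():
    """12 ages x 6 periods -> 17 cohorts, 1913-1917 through 1993-1997."""
    t = study_table()
    assert t.C == 17
    assert t.cohorts[0].label == "1913-1917"
    assert t.cohorts[-1].label == "1993-1997"


def brute_force_cohort_midpoints(ages, periods):
    """Independent oracle: enumerate period-minus-age midpoints over all
    cells and collect the distinct values."""
    return sorted({p.midpoint - a.midpoint for a in ages for p in periods})


@pytest.mark.parametrize("A,P", [(1, 1), (3, 2), (12, 6), (2, 7)])
def test_cohort_count_and_midpoints_match_enumeration(A, P):
    ages = tuple(AgeBand(20 + 5 * i, 5) for i in range(A))
    periods = tuple(PeriodBand(1990 + 5 * j, 5) for j in range(P))
    cohorts, index = build_cohorts(ages, periods)
    assert len(cohorts) == A + P - 1
    expected_mids = brute_force_cohort_midpoints(ages, periods)
    assert [c.midpoint for c in cohorts] == expected_mids
    # every cell maps to exactly one cohort; anti-diagonals share a cohort
    for i in range(A):
        for j in range(P):
            assert periods[j].midpoint - ages[i].midpoint == cohorts[index[i, j]].midpoint


@settings(max_examples=30, deadline=None, derandomize=True)
@given(A=st.integers(1, 15), P=st.integers(1, 10))
def test_cohort_count_invariant(A, P):
    ages = tuple(AgeBand(5 * i, 5) for i in range(A))
    periods = tuple(PeriodBand(1950 + 5 * j, 5) for j in range(P))
    cohorts, index = build_cohorts(ages, periods)
    assert len(cohorts) == A + P - 1
    assert index.min() == 0 and index.max() == A + P - 2


def test_unequal_widths_rejected():
    with pytest.raises(ValueError, match="equal-width"):
        build_cohorts((AgeBand(20, 5),), (PeriodBand(1990, 10),))


# ---------------------------------------------------------------------------
# age restriction
# ---------------------------------------------------------------------------

def test_restrict_to_risk_factor_range():
    t = study_table()
    r = restrict_ages(t, 30, 79)
    assert r.A == 10 and r.ages[0].label == "30-34"
    assert r.C == 15
    identical = restrict_ages(t, 20, 79)
    np.testing.assert_array_equal(identical.deaths, t.deaths)
    with pytest.raises(AlignmentError):
        restrict_ages(t, 32, 79)


# ---------------------------------------------------------------------------
# rate utilities
# ---------------------------------------------------------------------------

def test_attributable_proportion_values():
    # printed-table arithmetic: smoking-attributable over total deaths
    assert round(attributable_proportion(430.46, 523.19), 2) == 82.28
    assert round(attributable_proportion(140.17, 177.93), 2) == 78.78
    assert attributable_proportion(0.0, 10.0) == 0.0


def test_attributable_proportion_overlap_warns_not_fails():
    with pytest.warns(UserWarning, match="exceed"):
        assert attributable_proportion(12.0, 10.0) == pytest.approx(120.0)
    with pytest.raises(ValueError):
        attributable_proportion(1.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.floats(0.0, 1e6), y=st.floats(1e-3, 1e6), k=st.floats(1e-3, 1e3),
)
def test_attributable_proportion_scale_invariant(x, y, k):
    a = attributable_proportion(min(x, y), y)
    b = attributable_proportion(k * min(x, y), k * y)
    assert a == pytest.approx(b, rel=1e-9)


def test_direct_standardization():
    bands = (AgeBand(20, 5), AgeBand(25, 5))
    std = StandardPopulation(bands, (0.25, 0.75))
    # hand arithmetic: 0.25*10 + 0.75*30 = 25 per 100k
    assert direct_standardize({bands[0]: 10e-5, bands[1]: 30e-5}, std) == pytest.approx(25.0)
    # constant rates pass through
    assert direct_standardize({b: 7e-5 for b in bands}, std) == pytest.approx(7.0)
    with pytest.raises(CoverageError):
        direct_standardize({AgeBand(80, 5): 1e-5}, std)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_rate_table_json_roundtrip(tmp_path):
    t = study_table()
    path = tmp_path / "table.json"
    t.to_json(path)
    back = RateTable.from_json(path)
    assert back.stratum == t.stratum
    assert back.ages == t.ages and back.periods == t.periods
    np.testing.assert_array_equal(back.deaths, t.deaths)


def test_wide_pair_roundtrip(tmp_path):
    t = study_table()
    write_wide_pair(t, tmp_path / "d.csv", tmp_path / "n.csv")
    back = read_wide_pair(tmp_path / "d.csv", tmp_path / "n.csv", t.stratum)
    np.testing.assert_allclose(back.deaths, t.deaths, rtol=1e-12)
    np.testing.assert_allclose(back.person_years, t.person_years, rtol=1e-12)
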