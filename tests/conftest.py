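import dataclasses

import numpy as np
import pandas as pd
import pytest

from apcmodels import APCModel, RateTable, Stratum
from apcmodels.synthetic import SimScenario, expected_rates, preset_lung_cancer_like


def noiseless_table(s: SimScenario) -> RateTable:
    """Deterministic table whose deaths equal their expectations exactly
    (non-integer counts are allowed everywhere)."""
    deaths = expected_rates(s) * s.person_years
    stratum = Stratum(location="synthetic", cause="noiseless", source="expected")
    return RateTable(stratum, s.ages, s.periods, deaths, s.person_years.copy())


def with_person_years(s: SimScenario, py) -> SimScenario:
    return dataclasses.replace(s, person_years=py)


def glm_results(model: APCModel):
    """Independent fitting route: iteratively reweighted least squares
    Poisson GLM (statsmodels) on the same canonical design, wrapped so the
    same estimable-function maps apply."""
    import statsmodels.api as sm

    from apcmodels.model import APCResults

    assert model.constraint == "orthogonal"
    t = model.table
    glm = sm.GLM(
        t.deaths.ravel(),
        model.design.matrix,
        family=sm.families.Poisson(),
        offset=np.log(t.person_years.ravel()),
    ).fit()
    return APCResults(
        model=model,
        params=np.asarray(glm.params),
        cov_params=np.asarray(glm.cov_params()),
        fitted_log_rates=(model.design.matrix @ glm.params).reshape(t.A, t.P),
        dispersion=float("nan"),
        dispersion_applied=1.0,
        n_zero_cells=0,
    )


def report_vector(res) -> np.ndarray:
    """Flatten every estimable output (estimates and CI bounds) into one
    vector for whole-report comparisons."""
    rep = res.report()
    parts = [
        [rep.net_drift.value, rep.net_drift.ci_low, rep.net_drift.ci_high],
        rep.local_drifts.values,
        rep.local_drifts.ci_low,
        rep.local_drifts.ci_high,
        rep.longitudinal_age_curve.rates,
        rep.longitudinal_age_curve.ci_low,
        rep.longitudinal_age_curve.ci_high,
        rep.cross_sectional_age_curve.rates,
        rep.cross_sectional_age_curve.ci_low,
        rep.cross_sectional_age_curve.ci_high,
        rep.period_rate_ratios.ratios,
        rep.period_rate_ratios.ci_low,
        rep.period_rate_ratios.ci_high,
        rep.cohort_rate_ratios.ratios,
        rep.cohort_rate_ratios.ci_low,
        rep.cohort_rate_ratios.ci_high,
    ]
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def log_report_vector(res) -> np.ndarray:
    """Every estimable output on its natural additive scale: log-slopes per
    year for drifts, log rates for age curves, log ratios for RRs (CI
    bounds included).  An absolute difference of x here is a relative
    difference of about x on the rate/ratio scale."""
    rep = res.report()
    pct = lambda seq: np.log1p(np.asarray(seq, dtype=float) / 100.0)
    parts = [
        pct([rep.net_drift.value, rep.net_drift.ci_low, rep.net_drift.ci_high]),
        pct(rep.local_drifts.values),
        pct(rep.local_drifts.ci_low),
        pct(rep.local_drifts.ci_high),
    ]
    for curve in (rep.longitudinal_age_curve, rep.cross_sectional_age_curve):
        parts += [np.log(curve.rates), np.log(curve.ci_low), np.log(curve.ci_high)]
    for series in (rep.period_rate_ratios, rep.cohort_rate_ratios):
        parts += [np.log(series.ratios), np.log(series.ci_low), np.log(series.ci_high)]
    return np.concatenate(parts)


def max_rel_diff(a: np.ndarray, b: np.ndarray, floor: float = 1e-9) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.max(np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)))


def random_scenario(rng: np.random.Generator, person_years: float = 2e6) -> SimScenario:
    """A seeded random 12x6 scenario with slopes and curvature in realistic
    ranges (used by the invariance and oracle sweeps)."""
    A, P = 12, 6
    C = A + P - 1
    mids = np.arange(A) * 5 + 22.5
    z = mids - mids.mean()
    age_curve = np.log(1e-4) + 0.09 * z - 5e-4 * z**2 + rng.normal(0, 0.05, A)
    return SimScenario(
        A=A,
        P=P,
        age_curve=age_curve,
        period_slope=rng.uniform(-0.02, 0.02),
        cohort_slope=rng.uniform(-0.02, 0.02),
        period_curvature=rng.normal(0, 0.03, P),
        cohort_curvature=rng.normal(0, 0.06, C),
        person_years=person_years,
        seed=int(rng.integers(2**31 - 1)),
    )


def gbd_long_csv(path, table: RateTable, location="China", sex="Male",
                 cause="Tracheal, bronchus, and lung cancer", risk=None) -> pd.DataFrame:
    """Write a long-format results-tool style CSV whose annual records sum
    back to ``table`` exactly (each period split uniformly over its years)."""
    rows = []
    for i, a in enumerate(table.ages):
        for j, p in enumerate(table.periods):
            for y in range(p.start, p.end + 1):
                base = {
                    "location": location,
                    "sex": sex,
                    "age": f"{a.start} to {a.end}",
                    "cause": cause,
                    "metric": "Number",
                    "year": y,
                    "upper": np.nan,
                    "lower": np.nan,
                }
                rows.append(
                    {**base, "measure": "Deaths", "rei": risk,
                     "val": table.deaths[i, j] / p.width}
                )
                rows.append(
                    {**base, "measure": "Population", "rei": None,
                     "val": table.person_years[i, j] / p.width}
                )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


@pytest.fixture(scope="session")
def preset() -> SimScenario:
    return preset_lung_cancer_like()


@pytest.fixture(scope="session")
def preset_table(preset):
    from apcmodels.synthetic import simulate_table

    return simulate_table(preset)
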