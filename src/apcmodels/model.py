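"""Weighted-least-squares fitting of the log-linear Poisson APC rate model.

The model for a Lexis cell with deaths ``d`` and person-years ``n`` is

    log(d / n) = alpha_age + pi_period + gamma_cohort

with cohort = period - age, fitted by a single pass of weighted least
squares on the observed log rates: the delta-method variance of a log rate
under the Poisson assumption is 1/d, so each cell gets weight ``d``.  The
exact collinearity of the three time scales is resolved by the canonical
estimable-function design (see :mod:`apcmodels.design`); every reported
output is a function of the fitted rate surface alone and is therefore
invariant to which full-rank parameterization was used.

Usage follows the Model/Results convention::

    model = APCModel(table)            # references default to median categories
    res = model.fit()
    res.net_drift()                    # DriftEstimate, percent per year
    res.period_rate_ratios()           # RateRatioSeries
    res.report()                       # full EstimableReport
    print(res.summary())
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .design import APCDesign, build_design, centered_index, corner_design_matrix
from .estimable import (
    Z95,
    AgeCurve,
    DriftEstimate,
    EstimableReport,
    LocalDriftSeries,
    RateRatioSeries,
    WaldResult,
)
from .rate_tables import RateTable, Stratum, aggregate_periods, read_wide_pair

__all__ = ["APCModel", "APCResults", "RankError", "ZeroCellError", "EstimabilityError"]

_RANK_RCOND = 1e-10  # singular values below rcond * s_max are treated as zero


class RankError(np.linalg.LinAlgError):
    """The weighted design is numerically rank deficient."""


class ZeroCellError(ValueError):
    """A cell has zero deaths and strict zero-cell mode is on."""


class EstimabilityError(ValueError):
    """A requested contrast is not an estimable function."""


class APCModel:
    """Age-period-cohort rate model for one :class:`RateTable`.

    Parameters
    ----------
    table : RateTable
    ref_period, ref_cohort : optional
        Reference categories (start year, label or band); default is the
        median category of each dimension.
    constraint : {"orthogonal", "corner"}
        Identifiability constraint used for fitting.  Both span the same
        model space and produce identical estimable outputs; "orthogonal"
        (orthonormal curvature deviations) is the default and the only one
        anyone needs — "corner" exists to demonstrate that invariance.
    zero_cell : {"substitute", "strict"}
        Cells with zero deaths have an undefined log rate.  The default
        substitutes ``zero_value`` deaths for both the log rate and the
        weight of such cells (with a warning); "strict" raises instead.
    """

    def __init__(
        self,
        table: RateTable,
        ref_period=None,
        ref_cohort=None,
        constraint: str = "orthogonal",
        zero_cell: str = "substitute",
        zero_value: float = 0.5,
    ):
        if constraint not in {"orthogonal", "corner"}:
            raise ValueError(f"unknown constraint {constraint!r}")
        if zero_cell not in {"substitute", "strict"}:
            raise ValueError(f"unknown zero_cell mode {zero_cell!r}")
        self.table = table
        self.design: APCDesign = build_design(table, ref_period, ref_cohort)
        self.constraint = constraint
        self.zero_cell = zero_cell
        self.zero_value = float(zero_value)
        self.exog = (
            self.design.matrix if constraint == "orthogonal" else corner_design_matrix(self.design)
        )

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_wide_csv(cls, deaths_path, population_path, stratum: Stratum | None = None, **kwargs):
        return cls(read_wide_pair(deaths_path, population_path, stratum), **kwargs)

    @classmethod
    def from_records(cls, records, period_width: int = 5, stratum: Stratum | None = None, **kwargs):
        """Build from annual records (the output of ``load_gbd_csv``)."""
        return cls(aggregate_periods(records, period_width, stratum), **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, overdispersion: bool = False) -> "APCResults":
        """Single-pass WLS fit of log crude rates with weights = deaths.

        The covariance of the coefficients is ``phi * (X'WX)^-1`` where the
        dispersion ``phi`` is the Pearson chi-square over the residual
        degrees of freedom; it is applied only when ``overdispersion`` is
        requested *and* exceeds 1, otherwise ``phi = 1`` (plain Poisson
        Wald intervals).
        """
        d = self.table.deaths.ravel().copy()
        n = self.table.person_years.ravel()
        zero = d == 0
        n_zero = int(zero.sum())
        if n_zero:
            if self.zero_cell == "strict":
                raise ZeroCellError(f"{n_zero} cell(s) with zero deaths (strict mode)")
            warnings.warn(
                f"zero-cell substitution d*={self.zero_value} applied to {n_zero} cell(s)",
                stacklevel=2,
            )
            d[zero] = self.zero_value
        y = np.log(d / n)
        w = d

        X = self.exog
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        U, s, Vt = np.linalg.svd(Xw, full_matrices=False)
        if len(s) < X.shape[1]:
            raise RankError(
                f"underdetermined design: {X.shape[0]} cells for {X.shape[1]} parameters"
            )
        if s[-1] <= _RANK_RCOND * s[0]:
            raise RankError(self._rank_message(Vt[-1]))
        beta = Vt.T @ ((U.T @ (y * sw)) / s)
        xtwx_inv = (Vt.T / s**2) @ Vt

        fitted = X @ beta
        mu_hat = n * np.exp(fitted)
        resid_df = self.design.residual_df
        pearson = float(np.sum((self.table.deaths.ravel() - mu_hat) ** 2 / mu_hat))
        dispersion = pearson / resid_df if resid_df > 0 else float("nan")
        phi = dispersion if (overdispersion and dispersion > 1) else 1.0
        cov_beta = phi * xtwx_inv

        return APCResults(
            model=self,
            params=beta,
            cov_params=cov_beta,
            fitted_log_rates=fitted.reshape(self.table.A, self.table.P),
            dispersion=dispersion,
            dispersion_applied=phi,
            n_zero_cells=n_zero,
        )

    def _rank_message(self, null_vec: np.ndarray) -> str:
        if self.constraint != "orthogonal":
            return "singular weighted design (corner parameterization)"
        col = int(np.argmax(np.abs(null_vec)))
        for name, sl in self.design.blocks.items():
            if sl.start <= col < sl.stop:
                return f"singular weighted design; offending block: {name}"
        return "singular weighted design"  # pragma: no cover


class APCResults:
    """Fitted APC model: coefficients, covariance, and estimable functions.

    All estimable outputs are computed from the fitted log-rate surface and
    its covariance through the canonical (orthogonal-deviation) basis, so
    they do not depend on the constraint used for fitting.
    """

    def __init__(
        self,
        model: APCModel,
        params: np.ndarray,
        cov_params: np.ndarray,
        fitted_log_rates: np.ndarray,
        dispersion: float,
        dispersion_applied: float,
        n_zero_cells: int,
    ):
        self.model = model
        self.design = model.design
        self.params = params
        self.cov_params = cov_params
        self.fitted_log_rates = fitted_log_rates
        self.dispersion = dispersion
        self.dispersion_applied = dispersion_applied
        self.n_zero_cells = n_zero_cells
        self.resid_df = self.design.residual_df

        # canonical parameters: project the fitted surface onto the
        # orthogonal-deviation basis (exact, since it spans the model space)
        Xc = self.design.matrix
        Pc = np.linalg.pinv(Xc)
        cov_fit = model.exog @ cov_params @ model.exog.T
        self.theta = Pc @ fitted_log_rates.ravel()
        self.cov_theta = Pc @ cov_fit @ Pc.T

    # -- low-level helpers ----------------------------------------------
    @property
    def fitted_rates(self) -> np.ndarray:
        """Fitted rates per person-year, (A, P)."""
        return np.exp(self.fitted_log_rates)

    def _estimate(self, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Point estimates and standard errors of linear functions of the
        canonical parameters."""
        L = np.atleast_2d(L)
        est = L @ self.theta
        var = np.einsum("ij,jk,ik->i", L, self.cov_theta, L)
        return est, np.sqrt(np.clip(var, 0.0, None))

    def _row(self) -> np.ndarray:
        return np.zeros(self.design.n_params)

    # -- estimable functions ---------------------------------------------
    def net_drift(self) -> DriftEstimate:
        """Net drift: annual percent change of the age-adjusted rate.

        The sum of the period and cohort log-linear slopes, estimated per
        5-year interval and converted to a per-year percent change.
        """
        bl = self.design.blocks
        r = self._row()
        r[bl["drift"]] = 1.0 / self.design.width
        (slope,), (se,) = self._estimate(r)
        lo, hi = slope - Z95 * se, slope + Z95 * se
        stat = (slope / se) ** 2 if se > 0 else 0.0
        test = WaldResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))
        return DriftEstimate(
            value=100.0 * np.expm1(slope),
            ci_low=100.0 * np.expm1(lo),
            ci_high=100.0 * np.expm1(hi),
            log_slope_per_year=float(slope),
            test=test,
        )

    def _local_drift_rows(self) -> np.ndarray:
        """Rows giving, per age band, the least-squares calendar-time slope
        of the fitted log rates along that row (per year).

        Equals the net drift plus the age-specific slope of the cohort
        deviations, since period deviations have zero linear trend by
        construction."""
        A, P = self.design.A, self.design.P
        t = centered_index(P)
        h = t / (t @ t)  # least-squares slope weights over period index
        Xc = self.design.matrix
        L = np.zeros((A, self.design.n_params))
        for i in range(A):
            for j in range(P):
                L[i] += h[j] * Xc[i * P + j]
        return L / self.design.width

    def local_drifts(self) -> LocalDriftSeries:
        """Per-age annual percent change of rates over calendar time."""
        est, se = self._estimate(self._local_drift_rows())
        lo, hi = est - Z95 * se, est + Z95 * se
        return LocalDriftSeries(
            labels=tuple(b.label for b in self.design.ages),
            values=tuple(100.0 * np.expm1(est)),
            ci_low=tuple(100.0 * np.expm1(lo)),
            ci_high=tuple(100.0 * np.expm1(hi)),
        )

    def _curve(self, kind: str) -> AgeCurve:
        d = self.design
        bl = d.blocks
        a_c = centered_index(d.A)
        p_c = centered_index(d.P)
        c_c = centered_index(d.C)
        rows = np.zeros((d.A, d.n_params))
        for i in range(d.A):
            r = rows[i]
            r[bl["intercept"]] = 1.0
            r[bl["age_dev"]] = d.age_basis[i]
            if kind == "longitudinal":
                # follow the reference cohort; period deviations set to zero
                r[bl["age_trend"]] = a_c[i]
                r[bl["drift"]] = c_c[d.ref_cohort]
                r[bl["cohort_dev"]] = d.cohort_basis[d.ref_cohort]
            else:
                # reference period cross-section; cohort deviations set to zero
                r[bl["age_trend"]] = a_c[i]
                r[bl["drift"]] = p_c[d.ref_period] - a_c[i]
                r[bl["period_dev"]] = d.period_basis[d.ref_period]
        est, se = self._estimate(rows)
        lo, hi = est - Z95 * se, est + Z95 * se
        ref = (
            d.cohorts[d.ref_cohort].label if kind == "longitudinal" else d.periods[d.ref_period].label
        )
        return AgeCurve(
            kind=kind,
            reference=ref,
            labels=tuple(b.label for b in d.ages),
            rates=tuple(np.exp(est) * 1e5),
            ci_low=tuple(np.exp(lo) * 1e5),
            ci_high=tuple(np.exp(hi) * 1e5),
        )

    def longitudinal_age_curve(self) -> AgeCurve:
        """Expected age-specific rates in the reference cohort, adjusted
        for period effects (per 100,000 person-years)."""
        return self._curve("longitudinal")

    def cross_sectional_age_curve(self) -> AgeCurve:
        """Expected age-specific rates in the reference period, adjusted
        for cohort effects (per 100,000 person-years)."""
        return self._curve("cross_sectional")

    def _rr_rows(self, dimension: str) -> tuple[np.ndarray, int]:
        d = self.design
        bl = d.blocks
        if dimension == "period":
            n, ref, basis, idx = d.P, d.ref_period, d.period_basis, centered_index(d.P)
            dev = "period_dev"
        else:
            n, ref, basis, idx = d.C, d.ref_cohort, d.cohort_basis, centered_index(d.C)
            dev = "cohort_dev"
        rows = np.zeros((n, d.n_params))
        for m in range(n):
            rows[m, bl["drift"]] = idx[m] - idx[ref]
            rows[m, bl[dev]] = basis[m] - basis[ref]
        return rows, ref

    def _rate_ratios(self, dimension: str) -> RateRatioSeries:
        d = self.design
        rows, ref = self._rr_rows(dimension)
        est, se = self._estimate(rows)
        est[ref], se[ref] = 0.0, 0.0  # reference is exactly 1 by construction
        lo, hi = est - Z95 * se, est + Z95 * se
        bands = d.periods if dimension == "period" else d.cohorts
        return RateRatioSeries(
            dimension=dimension,
            reference=bands[ref].label,
            labels=tuple(b.label for b in bands),
            ratios=tuple(np.exp(est)),
            ci_low=tuple(np.exp(lo)),
            ci_high=tuple(np.exp(hi)),
        )

    def period_rate_ratios(self) -> RateRatioSeries:
        """Rate ratios by period relative to the reference period,
        adjusted for age and cohort effects."""
        return self._rate_ratios("period")

    def cohort_rate_ratios(self) -> RateRatioSeries:
        """Rate ratios by cohort relative to the reference cohort,
        adjusted for age and period effects."""
        return self._rate_ratios("cohort")

    # -- Wald tests -------------------------------------------------------
    _NAMED_HYPOTHESES = ("net_drift", "local_drift_equality", "period_effects", "cohort_effects")

    def _hypothesis_matrix(self, name: str) -> np.ndarray:
        bl = self.design.blocks
        if name == "net_drift":
            r = self._row()
            r[bl["drift"]] = 1.0
            return r[None, :]
        if name == "local_drift_equality":
            L = self._local_drift_rows()
            return L[1:] - L[0]
        if name == "period_effects":
            rows, ref = self._rr_rows("period")
            return np.delete(rows, ref, axis=0)
        if name == "cohort_effects":
            rows, ref = self._rr_rows("cohort")
            return np.delete(rows, ref, axis=0)
        raise ValueError(f"unknown hypothesis {name!r}; named: {self._NAMED_HYPOTHESES}")

    def wald_test(self, hypothesis) -> WaldResult:
        """Wald chi-square test of ``L theta = 0``.

        ``hypothesis`` is a named hypothesis ("net_drift" — no drift;
        "local_drift_equality" — all local drifts equal the net drift;
        "period_effects"/"cohort_effects" — all rate ratios equal 1) or a
        contrast matrix over the canonical parameters.
        """
        L = self._hypothesis_matrix(hypothesis) if isinstance(hypothesis, str) else np.atleast_2d(hypothesis)
        if L.shape[1] != self.design.n_params:
            raise ValueError(f"contrast has {L.shape[1]} columns, expected {self.design.n_params}")
        df = int(np.linalg.matrix_rank(L)) if L.size else 0
        if df == 0:
            return WaldResult(0.0, 0, 1.0)
        v = L @ self.theta
        M = L @ self.cov_theta @ L.T
        stat = float(v @ np.linalg.pinv(M) @ v)
        return WaldResult(stat, df, float(stats.chi2.sf(stat, df)))

    def wald_test_categories(self, L: np.ndarray) -> WaldResult:
        """Wald test of a contrast over the raw category parameters
        ``(alpha_1..A, pi_1..P, gamma_1..C)``.

        Such contrasts are only meaningful when they are estimable, i.e.
        orthogonal to the null space of the category design; otherwise an
        :class:`EstimabilityError` is raised.
        """
        d = self.design
        L = np.atleast_2d(np.asarray(L, dtype=float))
        if L.shape[1] != d.A + d.P + d.C:
            raise ValueError(f"contrast has {L.shape[1]} columns, expected {d.A + d.P + d.C}")
        Xfull = np.zeros((d.A * d.P, d.A + d.P + d.C))
        for i in range(d.A):
            for j in range(d.P):
                r = i * d.P + j
                Xfull[r, i] = 1.0
                Xfull[r, d.A + j] = 1.0
                Xfull[r, d.A + d.P + d.cohort_index[i, j]] = 1.0
        _, s, Vt = np.linalg.svd(Xfull)
        null_basis = Vt[int(np.sum(s > 1e-9 * s[0])):]
        norms = np.linalg.norm(L, axis=1)
        bad = np.linalg.norm(L @ null_basis.T, axis=1) > 1e-8 * np.where(norms > 0, norms, 1.0)
        if bad.any():
            raise EstimabilityError(
                f"{int(bad.sum())} contrast row(s) are not estimable functions"
            )
        # express the contrast in terms of cell log-rates, then map to theta
        C = np.linalg.lstsq(Xfull.T, L.T, rcond=None)[0].T  # L = C @ Xfull
        return self.wald_test(C @ d.matrix)

    # -- reporting --------------------------------------------------------
    def report(self) -> EstimableReport:
        """All estimable outputs with 95% CIs plus the named Wald tests."""
        d = self.design
        return EstimableReport(
            stratum=self.model.table.stratum.to_dict(),
            references={
                "period": d.periods[d.ref_period].label,
                "cohort": d.cohorts[d.ref_cohort].label,
            },
            net_drift=self.net_drift(),
            local_drifts=self.local_drifts(),
            longitudinal_age_curve=self.longitudinal_age_curve(),
            cross_sectional_age_curve=self.cross_sectional_age_curve(),
            period_rate_ratios=self.period_rate_ratios(),
            cohort_rate_ratios=self.cohort_rate_ratios(),
            wald_tests={name: self.wald_test(name) for name in self._NAMED_HYPOTHESES},
            dispersion=self.dispersion,
        )

    def summary(self) -> str:
        """Plain-text summary in the Model/Results tradition."""
        d = self.design
        nd = self.net_drift()
        lines = [
            "Age-Period-Cohort Model (WLS, Poisson weights)",
            "=" * 54,
            f"Stratum:          {self.model.table.stratum.name}",
            f"Grid:             {d.A} ages x {d.P} periods ({d.C} cohorts), width {d.width} y",
            f"Reference period: {d.periods[d.ref_period].label}",
            f"Reference cohort: {d.cohorts[d.ref_cohort].label}",
            f"Free parameters:  {d.n_params}   Residual df: {self.resid_df}",
            f"Dispersion (Pearson chi2/df): {self.dispersion:.4g}"
            + ("  [applied]" if self.dispersion_applied != 1.0 else ""),
            f"Zero cells substituted: {self.n_zero_cells}",
            "-" * 54,
            f"Net drift: {nd.value:+.2f}%/yr  (95% CI {nd.ci_low:+.2f}, {nd.ci_high:+.2f})",
            "-" * 54,
            f"{'Wald test':<24}{'chi2':>10}{'df':>5}{'p':>12}",
        ]
        for name in self._NAMED_HYPOTHESES:
            t = self.wald_test(name)
            lines.append(f"{name:<24}{t.statistic:>10.2f}{t.df:>5}{t.pvalue:>12.3g}")
        return "\n".join(lines)
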