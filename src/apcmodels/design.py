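"""Design matrices for the age-period-cohort rate model.

The APC linear predictor is exactly collinear (cohort = period - age), so a
full-rank design needs a side condition.  The canonical design used here
follows the estimable-function parameterization: an intercept, two linear
terms (longitudinal age trend and net drift, in interval units), and three
blocks of *curvature deviations* — one per time scale — each constrained to
be orthogonal to both the constant and the linear index within its own
dimension.  Those constraints kill the degeneracy without touching any
estimable quantity, and the deviation blocks are orthonormalized for
numerical sharpness.

Free parameters: ``1 + 2 + (A-2) + (P-2) + (C-2)`` with ``C = A + P - 1``.

A corner-constrained dummy design spanning the same model space is also
provided; it exists so that invariance of every reported quantity to the
choice of identifiability constraint can be demonstrated, not because
anyone should fit with it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .rate_tables import CohortBand, PeriodBand, RateTable

__all__ = ["APCDesign", "build_design", "corner_design_matrix", "deviation_basis"]


class ReferenceError_(ValueError):
    """A requested reference category is not in the table."""


def centered_index(n: int) -> np.ndarray:
    """Category indices centred on their midpoint, in interval units."""
    return np.arange(n, dtype=float) - (n - 1) / 2.0


def deviation_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n, max(n-2, 0)) of the curvature space of a
    categorical dimension: the orthogonal complement of {1, linear index}."""
    if n < 3:
        return np.zeros((n, 0))
    X = np.column_stack([np.ones(n), centered_index(n)])
    Q, _ = np.linalg.qr(X)
    M = np.eye(n) - Q @ Q.T
    U, s, _ = np.linalg.svd(M)
    return U[:, : n - 2]


@dataclass
class APCDesign:
    """Centred index system and basis matrices for one rate table.

    Attributes
    ----------
    matrix : (A*P, n_params) ndarray
        Canonical design; cell order is row-major over (age, period).
    blocks : dict mapping block name to a column slice of ``matrix``;
        blocks are ``intercept``, ``age_trend`` (longitudinal age trend per
        interval), ``drift`` (net drift per interval), ``age_dev``,
        ``period_dev``, ``cohort_dev``.
    """

    A: int
    P: int
    C: int
    width: int
    ages: tuple
    periods: tuple
    cohorts: tuple
    cohort_index: np.ndarray
    ref_period: int
    ref_cohort: int
    matrix: np.ndarray
    blocks: dict
    age_basis: np.ndarray
    period_basis: np.ndarray
    cohort_basis: np.ndarray

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_cells(self) -> int:
        return self.A * self.P

    @property
    def residual_df(self) -> int:
        return self.n_cells - self.n_params

    def cell_rows(self) -> np.ndarray:
        """Alias for the canonical design matrix (one row per Lexis cell)."""
        return self.matrix


def _resolve_ref(bands, ref, kind: str) -> int:
    """Resolve a reference given as None (median category), start year,
    band, or label; return its index."""
    if ref is None:
        return (len(bands) - 1) // 2
    if hasattr(ref, "start"):
        ref = ref.start
    if isinstance(ref, str):
        for i, b in enumerate(bands):
            if b.label == ref or b.label.replace("-", "–") == ref:
                return i
        raise ReferenceError_(f"{kind} reference {ref!r} not found")
    for i, b in enumerate(bands):
        if b.start == int(ref):
            return i
    raise ReferenceError_(
        f"{kind} reference starting {ref} not found "
        f"(available: {bands[0].label} .. {bands[-1].label})"
    )


def build_design(
    table: RateTable,
    ref_period: "int | str | PeriodBand | None" = None,
    ref_cohort: "int | str | CohortBand | None" = None,
) -> APCDesign:
    """Build the canonical estimable-function design for a rate table.

    References default to the median category of each dimension (for the
    1990-2019 study grid this gives period 2000-2004; cohort 1953-1957 for
    the 20-79 tables and 1948-1952 for 30-79 risk-factor tables).  With
    fewer than three levels in a dimension its curvature block is empty and
    a reduced-model warning is emitted.
    """
    A, P, C = table.A, table.P, table.C
    if A < 3 or P < 3:
        warnings.warn(
            f"dimension with <3 levels (A={A}, P={P}): the corresponding "
            "curvature block is omitted (drift-only reduced model)",
            stacklevel=2,
        )
    j0 = _resolve_ref(table.periods, ref_period, "period")
    k0 = _resolve_ref(table.cohorts, ref_cohort, "cohort")

    Ba = deviation_basis(A)
    Bp = deviation_basis(P)
    Bc = deviation_basis(C)
    a_c = centered_index(A)
    c_c = centered_index(C)

    n_params = 3 + Ba.shape[1] + Bp.shape[1] + Bc.shape[1]
    X = np.zeros((A * P, n_params))
    blocks = {
        "intercept": slice(0, 1),
        "age_trend": slice(1, 2),
        "drift": slice(2, 3),
        "age_dev": slice(3, 3 + Ba.shape[1]),
        "period_dev": slice(3 + Ba.shape[1], 3 + Ba.shape[1] + Bp.shape[1]),
        "cohort_dev": slice(3 + Ba.shape[1] + Bp.shape[1], n_params),
    }
    kidx = table.cohort_index
    for i in range(A):
        for j in range(P):
            r = i * P + j
            k = kidx[i, j]
            X[r, 0] = 1.0
            X[r, 1] = a_c[i]
            X[r, 2] = c_c[k]
            X[r, blocks["age_dev"]] = Ba[i]
            X[r, blocks["period_dev"]] = Bp[j]
            X[r, blocks["cohort_dev"]] = Bc[k]

    return APCDesign(
        A=A,
        P=P,
        C=C,
        width=table.width,
        ages=table.ages,
        periods=table.periods,
        cohorts=table.cohorts,
        cohort_index=kidx,
        ref_period=j0,
        ref_cohort=k0,
        matrix=X,
        blocks=blocks,
        age_basis=Ba,
        period_basis=Bp,
        cohort_basis=Bc,
    )


def corner_design_matrix(design: APCDesign) -> np.ndarray:
    """A full-rank dummy-coded design spanning the same APC model space.

    Corner constraints: drop the first age, first period and first cohort
    indicator, plus the last cohort indicator (the extra drop pins the
    drift trade-off).  Same column count and span as the canonical design.
    """
    A, P, C = design.A, design.P, design.C
    kidx = design.cohort_index
    cols = []
    cols.append(np.ones(A * P))
    for i in range(1, A):
        v = np.zeros(A * P)
        for j in range(P):
            v[i * P + j] = 1.0
        cols.append(v)
    for j in range(1, P):
        v = np.zeros(A * P)
        for i in range(A):
            v[i * P + j] = 1.0
        cols.append(v)
    for k in range(1, C - 1):
        v = np.zeros(A * P)
        for i in range(A):
            for j in range(P):
                if kidx[i, j] == k:
                    v[i * P + j] = 1.0
        cols.append(v)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) != design.n_params:  # pragma: no cover - structural guard
        raise ValueError("corner design is rank deficient")
    return X
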