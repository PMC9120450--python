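"""Containers for the estimable functions of the APC model.

Every quantity here is a function of the model parameters that is invariant
to the arbitrary identifiability constraint: net drift, local drifts,
longitudinal and cross-sectional age curves, and period/cohort rate
ratios, each with a delta-method 95% CI on the log scale.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WaldResult",
    "DriftEstimate",
    "LocalDriftSeries",
    "AgeCurve",
    "RateRatioSeries",
    "EstimableReport",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _round12(x):
    """Pin floating-point output to 12 significant digits for byte-stable JSON."""
    if isinstance(x, float):
        return float(f"{x:.12g}")
    if isinstance(x, (list, tuple)):
        return [_round12(v) for v in x]
    if isinstance(x, dict):
        return {k: _round12(v) for k, v in x.items()}
    return x


@dataclass(frozen=True)
class WaldResult:
    """Wald chi-square test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    pvalue: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "pvalue": self.pvalue}

    @classmethod
    def from_dict(cls, d):
        return cls(d["statistic"], d["df"], d["pvalue"])


@dataclass(frozen=True)
class DriftEstimate:
    """Annual percent change of age-adjusted rates (net drift)."""

    value: float  # percent per year
    ci_low: float
    ci_high: float
    log_slope_per_year: float
    test: WaldResult | None = None

    def to_dict(self) -> dict:
        d = {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_slope_per_year": self.log_slope_per_year,
        }
        if self.test is not None:
            d["test"] = self.test.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        test = WaldResult.from_dict(d["test"]) if "test" in d else None
        return cls(d["value"], d["ci_low"], d["ci_high"], d["log_slope_per_year"], test)


@dataclass(frozen=True)
class LocalDriftSeries:
    """Per-age-band annual percent change of rates over calendar time."""

    labels: tuple[str, ...]
    values: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.labels,
                "percent_per_year": self.values,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "values": list(self.values),
            "ci_low": list(self.ci_low),
            "ci_high": list(self.ci_high),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(tuple(d["labels"]), tuple(d["values"]), tuple(d["ci_low"]), tuple(d["ci_high"]))


@dataclass(frozen=True)
class AgeCurve:
    """Fitted age-specific rates per 100,000 person-years.

    ``kind`` is "longitudinal" (rates in the reference cohort adjusted for
    period effects) or "cross_sectional" (rates in the reference period
    adjusted for cohort effects); ``reference`` is the label of that
    category.
    """

    kind: str
    reference: str
    labels: tuple[str, ...]
    rates: tuple[float, ...]  # per 100,000 person-years
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.labels,
                "rate_per_100k": self.rates,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "reference": self.reference,
            "labels": list(self.labels),
            "rates": list(self.rates),
            "ci_low": list(self.ci_low),
            "ci_high": list(self.ci_high),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            d["kind"],
            d["reference"],
            tuple(d["labels"]),
            tuple(d["rates"]),
            tuple(d["ci_low"]),
            tuple(d["ci_high"]),
        )


@dataclass(frozen=True)
class RateRatioSeries:
    """Rate ratios relative to a reference category (period or cohort).

    The reference entry is exactly 1 with a degenerate CI [1, 1].
    """

    dimension: str  # "period" or "cohort"
    reference: str
    labels: tuple[str, ...]
    ratios: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def reference_index(self) -> int:
        return self.labels.index(self.reference)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.dimension: self.labels,
                "rate_ratio": self.ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "reference": self.reference,
            "labels": list(self.labels),
            "ratios": list(self.ratios),
            "ci_low": list(self.ci_low),
            "ci_high": list(self.ci_high),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            d["dimension"],
            d["reference"],
            tuple(d["labels"]),
            tuple(d["ratios"]),
            tuple(d["ci_low"]),
            tuple(d["ci_high"]),
        )


@dataclass
class EstimableReport:
    """The full set of reported APC outputs for one stratum."""

    stratum: dict
    references: dict  # {"period": label, "cohort": label}
    net_drift: DriftEstimate
    local_drifts: LocalDriftSeries
    longitudinal_age_curve: AgeCurve
    cross_sectional_age_curve: AgeCurve
    period_rate_ratios: RateRatioSeries
    cohort_rate_ratios: RateRatioSeries
    wald_tests: dict = field(default_factory=dict)  # name -> WaldResult
    dispersion: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "stratum": dict(self.stratum),
            "references": dict(self.references),
            "net_drift": self.net_drift.to_dict(),
            "local_drifts": self.local_drifts.to_dict(),
            "longitudinal_age_curve": self.longitudinal_age_curve.to_dict(),
            "cross_sectional_age_curve": self.cross_sectional_age_curve.to_dict(),
            "period_rate_ratios": self.period_rate_ratios.to_dict(),
            "cohort_rate_ratios": self.cohort_rate_ratios.to_dict(),
            "wald_tests": {k: v.to_dict() for k, v in self.wald_tests.items()},
            "dispersion": self.dispersion,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(_round12(self.to_dict()), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "EstimableReport":
        return cls(
            stratum=dict(d["stratum"]),
            references=dict(d["references"]),
            net_drift=DriftEstimate.from_dict(d["net_drift"]),
            local_drifts=LocalDriftSeries.from_dict(d["local_drifts"]),
            longitudinal_age_curve=AgeCurve.from_dict(d["longitudinal_age_curve"]),
            cross_sectional_age_curve=AgeCurve.from_dict(d["cross_sectional_age_curve"]),
            period_rate_ratios=RateRatioSeries.from_dict(d["period_rate_ratios"]),
            cohort_rate_ratios=RateRatioSeries.from_dict(d["cohort_rate_ratios"]),
            wald_tests={k: WaldResult.from_dict(v) for k, v in d.get("wald_tests", {}).items()},
            dispersion=d.get("dispersion", float("nan")),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "EstimableReport":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def to_tidy_frame(self) -> pd.DataFrame:
        """One row per category per quantity:
        columns quantity, category, estimate, ci_low, ci_high."""
        rows = [
            ("net_drift", "all", self.net_drift.value, self.net_drift.ci_low, self.net_drift.ci_high)
        ]
        for series, qname in (
            (self.local_drifts, "local_drift"),
            (self.longitudinal_age_curve, "longitudinal_age_curve"),
            (self.cross_sectional_age_curve, "cross_sectional_age_curve"),
        ):
            vals = series.values if isinstance(series, LocalDriftSeries) else series.rates
            for lab, v, lo, hi in zip(series.labels, vals, series.ci_low, series.ci_high):
                rows.append((qname, lab, v, lo, hi))
        for series, qname in (
            (self.period_rate_ratios, "period_rate_ratio"),
            (self.cohort_rate_ratios, "cohort_rate_ratio"),
        ):
            for lab, v, lo, hi in zip(series.labels, series.ratios, series.ci_low, series.ci_high):
                rows.append((qname, lab, v, lo, hi))
        return pd.DataFrame(rows, columns=["quantity", "category", "estimate", "ci_low", "ci_high"])

    @property
    def n_rows(self) -> int:
        """Tidy-frame row count: 1 + A + A + A + P + C."""
        return (
            1
            + len(self.local_drifts)
            + len(self.longitudinal_age_curve)
            + len(self.cross_sectional_age_curve)
            + len(self.period_rate_ratios)
            + len(self.cohort_rate_ratios)
        )
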