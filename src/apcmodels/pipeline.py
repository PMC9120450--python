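"""Study orchestration: many strata in, one consolidated report bundle out.

Applies the study preparation rules per stratum (ages 20-79 for total
mortality, 30-79 for risk-factor-attributable strata; median reference
categories unless overridden), fits each table, and collects estimable
reports plus a cross-stratum comparison table.  Failures are isolated per
stratum and recorded in a manifest so one malformed extract does not sink
a whole run.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .estimable import EstimableReport, _round12
from .model import APCModel
from .rate_tables import (
    RateTable,
    Stratum,
    aggregate_periods,
    load_gbd_csv,
    read_wide_pair,
    restrict_ages,
)

__all__ = ["StratumSpec", "StudyConfig", "StudyBundle", "run_study", "export_report"]


@dataclass
class StratumSpec:
    """Where one stratum's data lives and how to select it.

    ``kind`` is "gbd" (long CSV + selector filters), "wide" (deaths /
    population matrix pair) or "json" (serialized RateTable).
    """

    name: str
    kind: str
    path: str = ""
    deaths: str = ""
    population: str = ""
    location: str = "unspecified"
    sex: str = "both"
    cause: str = "unspecified"
    risk_factor: str = "all"

    def stratum(self) -> Stratum:
        return Stratum(
            location=self.location,
            sex=self.sex,
            cause=self.cause,
            risk_factor=self.risk_factor,
            source=self.path or self.deaths,
        )


@dataclass
class StudyConfig:
    """Configuration for a full study run.

    Age ranges: ``age_range`` applies to total-mortality strata and
    ``risk_factor_age_range`` to attributable strata (sparse counts at
    young ages).  Reference categories default to the median period and
    cohort of each fitted table; set start years to override.
    """

    strata: list = field(default_factory=list)
    age_range: tuple = (20, 79)
    risk_factor_age_range: tuple = (30, 79)
    period_width: int = 5
    ref_period: "int | None" = None
    ref_cohort: "int | None" = None
    risk_factor_ref_cohort: "int | None" = None
    overdispersion: bool = False
    zero_cell: str = "substitute"

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        d["strata"] = [
            s if isinstance(s, StratumSpec) else StratumSpec(**s) for s in d.get("strata", [])
        ]
        for key in ("age_range", "risk_factor_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {
            "strata": [vars(s).copy() for s in self.strata],
            "age_range": list(self.age_range),
            "risk_factor_age_range": list(self.risk_factor_age_range),
            "period_width": self.period_width,
            "ref_period": self.ref_period,
            "ref_cohort": self.ref_cohort,
            "risk_factor_ref_cohort": self.risk_factor_ref_cohort,
            "overdispersion": self.overdispersion,
            "zero_cell": self.zero_cell,
        }
        return d


@dataclass
class StudyBundle:
    """Everything a study run produced."""

    config: StudyConfig
    tables: dict = field(default_factory=dict)  # name -> RateTable
    reports: dict = field(default_factory=dict)  # name -> EstimableReport
    diagnostics: dict = field(default_factory=dict)  # name -> dict
    failures: dict = field(default_factory=dict)  # name -> error string

    @property
    def comparison(self) -> pd.DataFrame:
        """Net drifts and RR endpoints side by side across strata."""
        rows = []
        for name, rep in self.reports.items():
            nd = rep.net_drift
            prr = rep.period_rate_ratios
            crr = rep.cohort_rate_ratios
            rows.append(
                {
                    "stratum": name,
                    "net_drift_pct": nd.value,
                    "net_drift_ci_low": nd.ci_low,
                    "net_drift_ci_high": nd.ci_high,
                    "first_period_rr": prr.ratios[0],
                    "last_period_rr": prr.ratios[-1],
                    "first_cohort_rr": crr.ratios[0],
                    "last_cohort_rr": crr.ratios[-1],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "stratum",
                "net_drift_pct",
                "net_drift_ci_low",
                "net_drift_ci_high",
                "first_period_rr",
                "last_period_rr",
                "first_cohort_rr",
                "last_cohort_rr",
            ],
        )


def _load_stratum_table(spec: StratumSpec, cfg: StudyConfig) -> RateTable:
    if spec.kind == "gbd":
        records = load_gbd_csv(spec.path, spec.stratum())
        return aggregate_periods(records, cfg.period_width, spec.stratum())
    if spec.kind == "wide":
        return read_wide_pair(spec.deaths, spec.population, spec.stratum())
    if spec.kind == "json":
        return RateTable.from_json(spec.path)
    raise ValueError(f"unknown stratum kind {spec.kind!r}")


def _prepare(table: RateTable, spec: StratumSpec, cfg: StudyConfig) -> RateTable:
    lo, hi = cfg.age_range if spec.risk_factor == "all" else cfg.risk_factor_age_range
    if table.ages[0].start == lo and table.ages[-1].end == hi:
        return table
    # only narrow; never invent bands outside the table
    lo = max(lo, table.ages[0].start)
    hi = min(hi, table.ages[-1].end)
    return restrict_ages(table, lo, hi)


def run_study(cfg: StudyConfig) -> StudyBundle:
    """Fit every resolvable stratum; failures go into the manifest.

    Raises only if no stratum at all could be fitted.
    """
    if not cfg.strata:
        raise ValueError("study config lists no strata")
    bundle = StudyBundle(config=cfg)
    for spec in cfg.strata:
        try:
            table = _prepare(_load_stratum_table(spec, cfg), spec, cfg)
            ref_cohort = (
                cfg.ref_cohort if spec.risk_factor == "all" else cfg.risk_factor_ref_cohort
            )
            model = APCModel(
                table,
                ref_period=cfg.ref_period,
                ref_cohort=ref_cohort,
                zero_cell=cfg.zero_cell,
            )
            res = model.fit(overdispersion=cfg.overdispersion)
            bundle.tables[spec.name] = table
            bundle.reports[spec.name] = res.report()
            bundle.diagnostics[spec.name] = {
                "dispersion": res.dispersion,
                "residual_df": res.resid_df,
                "n_parameters": model.design.n_params,
                "n_zero_cells": res.n_zero_cells,
                "reference_period": model.design.periods[model.design.ref_period].label,
                "reference_cohort": model.design.cohorts[model.design.ref_cohort].label,
            }
        except Exception as exc:  # noqa: BLE001 - isolation is the point
            bundle.failures[spec.name] = f"{type(exc).__name__}: {exc}"
    return bundle


def export_report(bundle: StudyBundle, out_dir) -> dict:
    """Write the bundle as JSON + tidy CSV + comparison CSV + run log.

    JSON floats are pinned to 12 significant digits so identical inputs
    produce byte-identical files.  Returns the paths written.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "json": os.path.join(out_dir, "report.json"),
        "estimates": os.path.join(out_dir, "estimates.csv"),
        "comparison": os.path.join(out_dir, "comparison.csv"),
        "failures": os.path.join(out_dir, "failures.json"),
        "log": os.path.join(out_dir, "run.log"),
    }
    payload = {
        "package": {"name": "apcmodels", "version": __version__},
        "config": bundle.config.to_dict(),
        "diagnostics": bundle.diagnostics,
        "reports": {name: rep.to_dict() for name, rep in sorted(bundle.reports.items())},
    }
    with open(paths["json"], "w") as fh:
        json.dump(_round12(payload), fh, indent=1, sort_keys=True)

    frames = []
    for name, rep in sorted(bundle.reports.items()):
        f = rep.to_tidy_frame()
        f.insert(0, "stratum", name)
        frames.append(f)
    if frames:
        tidy = pd.concat(frames, ignore_index=True)
    else:
        warnings.warn("empty bundle: writing header-only files", stacklevel=2)
        tidy = pd.DataFrame(columns=["stratum", "quantity", "category", "estimate", "ci_low", "ci_high"])
    tidy.to_csv(paths["estimates"], index=False, float_format="%.12g")
    bundle.comparison.to_csv(paths["comparison"], index=False, float_format="%.12g")
    with open(paths["failures"], "w") as fh:
        json.dump(bundle.failures, fh, indent=1, sort_keys=True)

    lines = [
        f"apcmodels {__version__}",
        f"strata fitted: {sorted(bundle.reports)}",
        f"strata failed: {sorted(bundle.failures)}",
    ]
    for name, diag in sorted(bundle.diagnostics.items()):
        lines.append(
            f"{name}: ref period {diag['reference_period']}, ref cohort "
            f"{diag['reference_cohort']}, dispersion {diag['dispersion']:.4g}, "
            f"zero cells {diag['n_zero_cells']}"
        )
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths
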