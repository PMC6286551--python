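"""End-to-end study replica: four model classes, evaluated and transported.

Given (or generating) a derivation and a validation cohort, fits Cox
models of successively increasing covariate complexity — dichotomized
predictors, 3/4-level categorized predictors, closed-test-selected
fractional polynomials (MFP) and restricted cubic splines — on the
identical truncated derivation cohort, forms percentile risk groups on
each prognostic index, transports every model to the validation cohort
with frozen transforms and weights, and writes a JSON comparison
report.  Everything downstream of cohort generation and bootstrap is
deterministic, so a fixed seed reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coxladder import synthetic_data
from coxladder.evaluation import (
    RiskGrouping,
    harrell_c,
    make_risk_groups,
    transport_validate,
)
from coxladder.model import PrognosticModel
from coxladder.survival_core import cox_fit, truncate_followup
from coxladder.synthetic_data import (
    CohortConfig,
    derivation_config,
    generate_cohort,
    generate_validation_cohort,
    read_cohort_csv,
    validation_config,
)
from coxladder.transforms import (
    categorized_scheme,
    dichotomized_scheme,
    mfp_fit,
    place_knots,
)

logger = logging.getLogger(__name__)

MODEL_CLASSES = ("dichotomized", "categorized", "fp", "rcs")
DEFAULT_COVARIATES = ("age_years", "tumor_size_mm", "n_pos_nodes")


@dataclass
class StudyConfig:
    """Everything a full study run needs.

    Cohorts come either from the synthetic generator (configs) or from
    CSV paths; exactly one source per cohort must be set.  Sensitivity
    switches reproduce the classic robustness checks: dropping the
    single patient with the most positive nodes, and dropping tumors
    of at most 2 mm.
    """

    derivation: CohortConfig | str | None = None
    validation: CohortConfig | str | None = None
    model_classes: tuple[str, ...] = MODEL_CLASSES
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    followup_cutoff: float = 10.0
    risk_percentiles: tuple[float, float, float] = (16.0, 50.0, 84.0)
    stratified: bool = True
    ties: str = "breslow"
    exclude_max_nodes: bool = False
    exclude_small_tumors: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.model_classes:
            raise ValueError("at least one model class required")
        unknown = set(self.model_classes) - set(MODEL_CLASSES)
        if unknown:
            raise ValueError(f"unknown model classes: {sorted(unknown)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def sensitivity_filter(
    cohort: pd.DataFrame,
    exclude_max_nodes: bool = False,
    exclude_small_tumors: bool = False,
    small_tumor_mm: float = 2.0,
) -> pd.DataFrame:
    """Optional robustness exclusions, logged.

    ``exclude_max_nodes`` drops the single patient with the highest
    positive-node count (ties broken by first occurrence);
    ``exclude_small_tumors`` drops tumors of at most ``small_tumor_mm``.
    """
    out = cohort
    if exclude_max_nodes:
        drop = out["n_pos_nodes"].idxmax()
        logger.info("sensitivity: excluding patient %s with %d positive nodes",
                    out.loc[drop, "patient_id"], out.loc[drop, "n_pos_nodes"])
        out = out.drop(index=drop)
    if exclude_small_tumors:
        mask = out["tumor_size_mm"] <= small_tumor_mm
        logger.info("sensitivity: excluding %d tumors <= %g mm",
                    int(mask.sum()), small_tumor_mm)
        out = out[~mask]
    if len(out) == 0:
        raise ValueError("sensitivity filtering removed every patient")
    return out.reset_index(drop=True) if out is not cohort else cohort


def _fit_by_scheme(cohort, covariates, scheme_fn, strata, ties, method):
    design_blocks, transforms = [], {}
    for cov in covariates:
        scheme = scheme_fn(cov)
        transforms[cov] = scheme
        design_blocks.append(scheme.basis(cohort[cov].to_numpy()))
    design = np.column_stack(design_blocks)
    fit = cox_fit(design, cohort["time_years"].to_numpy(),
                  cohort["event"].to_numpy(), strata, ties=ties)
    return PrognosticModel(
        transforms=transforms, weights=fit.coefficients,
        covariance=fit.covariance,
        meta={"method": method,
              "log_partial_likelihood": fit.log_partial_likelihood,
              "n_events": fit.n_events})


def fit_model_class(
    model_class: str,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    stratified: bool = True,
    ties: str = "breslow",
) -> PrognosticModel:
    """Fit one of the four model classes on a (truncated) cohort."""
    strata = cohort["stratum"].to_numpy() if stratified else None
    if model_class == "dichotomized":
        return _fit_by_scheme(cohort, covariates, dichotomized_scheme, strata,
                              ties, "dichotomized")
    if model_class == "categorized":
        return _fit_by_scheme(cohort, covariates, categorized_scheme, strata,
                              ties, "categorized")
    if model_class == "fp":
        return mfp_fit(cohort, covariates, alpha=alpha, stratified=stratified,
                       ties=ties)
    if model_class == "rcs":
        design_blocks, transforms = [], {}
        for cov in covariates:
            spec = place_knots(cohort[cov].to_numpy(), cov)
            transforms[cov] = spec
            design_blocks.append(spec.basis(cohort[cov].to_numpy()))
        fit = cox_fit(np.column_stack(design_blocks),
                      cohort["time_years"].to_numpy(),
                      cohort["event"].to_numpy(), strata, ties=ties)
        return PrognosticModel(
            transforms=transforms, weights=fit.coefficients,
            covariance=fit.covariance,
            meta={"method": "rcs",
                  "log_partial_likelihood": fit.log_partial_likelihood,
                  "n_events": fit.n_events})
    raise ValueError(f"unknown model class {model_class!r}")


def _resolve_cohort(source, default_cfg, generator):
    if source is None:
        source = default_cfg
    if isinstance(source, CohortConfig):
        return generator(source)
    return read_cohort_csv(source)


def _covariate_domains(cohort, covariates):
    return {c: (float(cohort[c].min()), float(cohort[c].max()))
            for c in covariates if c in cohort.columns}


def run_study(config: StudyConfig) -> dict:
    """Run the full comparison and return the report as a plain dict.

    Per model class: derivation fit (selected transforms, coefficients
    with 95 % CIs), derivation C-index, risk grouping with requested
    and achieved percentiles, 10-year survival per group, and the
    weight-transport evaluation on the validation cohort.  A failure in
    one model class is recorded in its entry without aborting the
    others.
    """
    deriv_cfg = (config.derivation if isinstance(config.derivation, CohortConfig)
                 else None) or derivation_config(seed=config.seed)
    valid_cfg = (config.validation if isinstance(config.validation, CohortConfig)
                 else None) or validation_config(seed=config.seed + 1_000_000)
    derivation = _resolve_cohort(config.derivation, deriv_cfg, generate_cohort)
    validation = _resolve_cohort(config.validation, valid_cfg,
                                 generate_validation_cohort)

    derivation = truncate_followup(derivation, config.followup_cutoff)
    validation = truncate_followup(validation, config.followup_cutoff)
    derivation = sensitivity_filter(
        derivation, config.exclude_max_nodes, config.exclude_small_tumors)

    report = {
        "config": {
            "model_classes": list(config.model_classes),
            "covariates": list(config.covariates),
            "alpha": config.alpha,
            "followup_cutoff": config.followup_cutoff,
            "risk_percentiles": list(config.risk_percentiles),
            "stratified": config.stratified,
            "ties": config.ties,
            "exclude_max_nodes": config.exclude_max_nodes,
            "exclude_small_tumors": config.exclude_small_tumors,
            "seed": config.seed,
        },
        "derivation_n": len(derivation),
        "derivation_events": int(derivation["event"].sum()),
        "validation_n": len(validation),
        "validation_events": int(validation["event"].sum()),
        "models": {},
    }
    domains = _covariate_domains(derivation, config.covariates)

    for model_class in config.model_classes:
        try:
            report["models"][model_class] = _run_one_class(
                model_class, derivation, validation, config, domains)
        except Exception as exc:
            logger.exception("model class %s failed", model_class)
            report["models"][model_class] = {"error": f"{type(exc).__name__}: {exc}"}
    return report


def _run_one_class(model_class, derivation, validation, config, domains):
    model = fit_model_class(
        model_class, derivation, config.covariates, config.alpha,
        config.stratified, config.ties)
    pi = model.prognostic_index(derivation)
    grouping = make_risk_groups(pi, config.risk_percentiles)

    deriv_report = transport_validate(
        model, grouping, derivation, horizon=config.followup_cutoff)
    valid_report = transport_validate(
        model, grouping, validation, horizon=config.followup_cutoff,
        domains=domains)

    coef = pd.DataFrame()
    if model.weights.size:
        se = (np.sqrt(np.diag(model.covariance))
              if model.covariance is not None else np.full(model.weights.size,
                                                           np.nan))
        with np.errstate(over="ignore"):
            coef = pd.DataFrame({
                "coef": model.weights, "se": se,
                "hr": np.exp(model.weights),
                "hr_lower": np.exp(model.weights - 1.959963984540054 * se),
                "hr_upper": np.exp(model.weights + 1.959963984540054 * se),
            })
        names = []
        for cov, t in model.transforms.items():
            names += [f"{cov}[{i}]" for i in range(t.n_cols)]
        coef.index = names

    return {
        "model": model.to_dict(),
        "transforms": {c: t.to_dict() for c, t in model.transforms.items()},
        "coefficients": coef.round(6).to_dict(orient="index"),
        "risk_grouping": grouping.to_dict(),
        "derivation": {
            **deriv_report.to_dict(),
            "pi_mean": float(np.mean(pi)),
        },
        "validation": {
            **valid_report.to_dict(),
            "pi_mean": float(np.mean(model.prognostic_index(validation))),
        },
    }


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
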