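"""End-to-end analysis: cohort -> phenotypes -> model fit -> life-expectancy tables.

`run_full_analysis` is a pure function of (input data, configuration, seeds):
re-running it with the same configuration produces byte-identical outputs.
It reproduces the structure of a multistate disability analysis: a
hazard-ratio table per transition, life-expectancy tables by gender and by
BMI-category x gender, and figure-ready LE/DFLE/DLE curves against age.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, observe_cohort, write_cohort
from .model import ModelSpec, FittedModel, fit, hazard_ratios
from .phenotype import apply_exclusions, prepare_model_frame
from .life_expectancy import (
    DEFAULT_GRID_STEP,
    DEFAULT_MAX_AGE,
    fit_prevalence,
    marginal_life_expectancies,
    simulate_cis,
)

__all__ = ["AnalysisConfig", "run_descriptives", "run_full_analysis"]

log = logging.getLogger("mslt")

_CSV_FLOAT = "%.10g"


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    Either ``input_csv`` (a long-format panel CSV) or ``cohort`` (a synthetic
    cohort configuration) must be provided.  ``ages`` are the starting ages of
    the life-expectancy tables and must be sorted ascending.
    """

    input_csv: str | None = None
    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    ages: tuple = (60.0, 70.0, 80.0, 90.0)
    n_sim: int = 1000
    seed: int = 20100101
    grid_step: float = DEFAULT_GRID_STEP
    max_age: float = DEFAULT_MAX_AGE
    weighting: str = "prevalence"
    stratified: bool = False
    outdir: str = "mslt_run"

    def __post_init__(self):
        if self.input_csv is None and self.cohort is None:
            raise ValueError("either input_csv or cohort must be given")
        if list(self.ages) != sorted(self.ages):
            raise ValueError("ages must be sorted ascending")

    def content_hash(self) -> str:
        payload = asdict(self)
        if self.cohort is not None:
            payload["cohort"] = asdict(self.cohort)
            payload["cohort"]["true_params"] = asdict(self.cohort.true_params)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_descriptives(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline descriptive table, per sex.

    Reports n, mean (sd) age, age-band percentages, BMI-category percentages,
    the three limitation-criterion percentages and the composite
    functional-limitation percentage, computed on each subject's baseline
    record.
    """
    base = df.sort_values(["id", "age"], kind="mergesort").groupby("id").first()
    rows = {}
    for sex, grp in base.groupby("sex"):
        age = grp["age"]
        col = {
            "n": float(len(grp)),
            "age_mean": age.mean(),
            "age_sd": age.std(ddof=1),
            "pct_60_69": 100.0 * ((age >= 60) & (age < 70)).mean(),
            "pct_70_79": 100.0 * ((age >= 70) & (age < 80)).mean(),
            "pct_80_plus": 100.0 * (age >= 80).mean(),
        }
        for cat in ("underweight", "normal", "overweight", "obese"):
            col[f"pct_{cat}"] = 100.0 * (grp["bmi_cat"] == cat).mean()
        adl = grp["adl_count"] >= 1
        iadl = grp["iadl_count"] >= 2
        mf = grp["mf_count"] >= 3
        col["pct_adl_1plus"] = 100.0 * adl.mean()
        col["pct_iadl_2plus"] = 100.0 * iadl.mean()
        col["pct_mf_3plus"] = 100.0 * mf.mean()
        col["pct_functional_limitation"] = 100.0 * (adl | iadl | mf).mean()
        rows[sex] = col
    return pd.DataFrame(rows)


def _le_rows(sets, extra: dict) -> list[dict]:
    rows = []
    for est in sets:
        row = {**extra, "age": est.age, "total_le": est.total_le,
               "dfle": est.dfle, "dle": est.dle, "pct_disabled": est.pct_disabled}
        for q, (lo, hi) in est.ci.items():
            row[f"{q}_lo95"] = lo
            row[f"{q}_hi95"] = hi
        rows.append(row)
    return rows


def _gender_profile(base: pd.DataFrame, female: int) -> dict:
    """Population-average covariate profile for one sex.

    The BMI dummies are set to the observed baseline proportions within that
    sex, so the gender table describes an average man/woman of the cohort
    rather than a reference-BMI one.
    """
    sub = base[base["female"] == female]
    return {
        "female": float(female),
        "overweight": float(sub["overweight"].mean()),
        "obese": float(sub["obese"].mean()),
    }


def run_full_analysis(config: AnalysisConfig):
    """Run the whole pipeline and write the report bundle to ``config.outdir``.

    Returns a dict with the fitted model and every table as a DataFrame.
    Output CSVs keep full precision; display rounding (1 decimal for years and
    percentages, 2 for hazard ratios) is applied only in ``*_display`` tables.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        log.info("stage=load input=%s", config.input_csv)
        raw = pd.read_csv(config.input_csv)
    else:
        log.info("stage=simulate n=%d seed=%d", config.cohort.n_subjects, config.cohort.seed)
        raw, _ = observe_cohort(config.cohort)
        write_cohort(raw, config.cohort, outdir / "panel.csv")

    log.info("stage=phenotype")
    prepared = prepare_model_frame(raw)
    modelling, exclusion_log = apply_exclusions(prepared)
    with open(outdir / "exclusions.json", "w") as fh:
        json.dump(exclusion_log, fh, indent=1)

    descriptives = run_descriptives(prepared)
    descriptives.to_csv(outdir / "descriptives.csv", float_format=_CSV_FLOAT)

    log.info("stage=fit n_subjects=%d", modelling["id"].nunique())
    spec = ModelSpec()
    fitted = fit(modelling, spec)
    fitted.to_json(outdir / "model.json")
    hr = hazard_ratios(fitted)
    hr.to_csv(outdir / "hazard_ratios.csv", index=False, float_format=_CSV_FLOAT)
    hr_display = hr.copy()
    for c in ("hr", "lo95", "hi95"):
        hr_display[c] = hr_display[c].round(2)
    hr_display.to_csv(outdir / "hazard_ratios_display.csv", index=False)

    prev = fit_prevalence(modelling, spec)
    base = modelling.sort_values(["id", "age"], kind="mergesort").groupby("id").first()

    def le_for(profile, label_extra):
        if config.n_sim > 0:
            sets = simulate_cis(
                fitted, prev, profile, config.ages, n_sim=config.n_sim,
                seed=config.seed, grid_step=config.grid_step,
                max_age=config.max_age, weighting=config.weighting,
            )
        else:
            sets = [
                marginal_life_expectancies(
                    fitted, prev, profile, a, config.grid_step,
                    config.max_age, config.weighting,
                )
                for a in config.ages
            ]
        return _le_rows(sets, label_extra)

    log.info("stage=life_expectancy n_sim=%d", config.n_sim)
    gender_rows = []
    for female, sex in ((0, "male"), (1, "female")):
        profile = _gender_profile(base, female)
        gender_rows += le_for(profile, {"sex": sex})
    le_gender = pd.DataFrame(gender_rows)
    le_gender.to_csv(outdir / "le_by_gender.csv", index=False, float_format=_CSV_FLOAT)

    bmi_rows = []
    for female, sex in ((0, "male"), (1, "female")):
        for cat in ("normal", "overweight", "obese"):
            profile = {
                "female": float(female),
                "overweight": float(cat == "overweight"),
                "obese": float(cat == "obese"),
            }
            bmi_rows += le_for(profile, {"sex": sex, "bmi_cat": cat})
    le_bmi = pd.DataFrame(bmi_rows)
    le_bmi.to_csv(
        outdir / "le_by_bmi_gender.csv", index=False, float_format=_CSV_FLOAT
    )

    fig_ages = np.arange(config.ages[0], config.ages[-1] + 0.1, 5.0)
    fig_rows = []
    for female, sex in ((0, "male"), (1, "female")):
        profile = _gender_profile(base, female)
        for a in fig_ages:
            est = marginal_life_expectancies(
                fitted, prev, profile, float(a), config.grid_step,
                config.max_age, config.weighting,
            )
            fig_rows.append(
                {"sex": sex, "age": float(a), "total_le": est.total_le,
                 "dfle": est.dfle, "dle": est.dle}
            )
    figure = pd.DataFrame(fig_rows)
    figure.to_csv(outdir / "figure_le_by_age.csv", index=False, float_format=_CSV_FLOAT)

    stratified_tables = None
    if config.stratified:
        stratified_tables = _stratified_by_bmi(modelling, config)
        stratified_tables.to_csv(
            outdir / "le_by_bmi_gender_stratified.csv", index=False,
            float_format=_CSV_FLOAT,
        )

    provenance = {
        "package": "mslt",
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_sim": config.n_sim,
        "exclusions": exclusion_log,
        "log_likelihood": fitted.log_likelihood,
        "converged": fitted.converged,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    log.info("stage=done elapsed=%.1fs", time.time() - t0)
    return {
        "fitted": fitted,
        "prevalence": prev,
        "descriptives": descriptives,
        "hazard_ratios": hr,
        "le_by_gender": le_gender,
        "le_by_bmi_gender": le_bmi,
        "figure": figure,
        "stratified": stratified_tables,
        "exclusions": exclusion_log,
    }


def _stratified_by_bmi(modelling: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Separate fits per BMI category (age + sex covariates only)."""
    spec = ModelSpec(covariates=("age", "female"))
    rows = []
    for cat in ("normal", "overweight", "obese"):
        sub = modelling[modelling["bmi_cat"] == cat]
        if sub["id"].nunique() < 50:
            log.warning("stratified fit for %s skipped: too few subjects", cat)
            continue
        fitted = fit(sub, spec, compute_covariance=False)
        prev = fit_prevalence(sub, spec)
        for female, sex in ((0, "male"), (1, "female")):
            for a in config.ages:
                est = marginal_life_expectancies(
                    fitted, prev, {"female": float(female)}, float(a),
                    config.grid_step, config.max_age, config.weighting,
                )
                rows.append(
                    {"sex": sex, "bmi_cat": cat, "age": float(a),
                     "total_le": est.total_le, "dfle": est.dfle,
                     "dle": est.dle, "pct_disabled": est.pct_disabled}
                )
    return pd.DataFrame(rows)


def percent_disabled(dle: float, total_le: float, decimals: int = 1) -> float:
    """Reporting convention: share of remaining years lived with disability.

    Computed as 100 * DLE / LE and rounded to ``decimals`` for display.
    """
    return round(100.0 * dle / total_le, decimals)
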