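"""Shared fixtures: toy model specifications and small synthetic cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from mslt.cohort import CohortConfig, GroundTruthIntensities, observe_cohort
from mslt.model import ModelSpec
from mslt.phenotype import apply_exclusions, prepare_model_frame

#: effectively-off log intensity for toy models that disable a transition
OFF = math.log(1e-12)


def toy_params(q12=0.0, q21=0.0, q13=0.0, q23=0.0):
    """Parameter vector for a covariate-free spec with the given intensities.

    A rate of exactly 0 is encoded as an intensity small enough (1e-12/yr) to
    be numerically indistinguishable from an impossible transition.
    """
    return np.array(
        [math.log(q) if q > 0 else OFF for q in (q12, q21, q13, q23)]
    )


@pytest.fixture(scope="session")
def nocov_spec():
    """Three-state spec with no covariates (constant intensities)."""
    return ModelSpec(covariates=())


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design synthetic cohort of 400 subjects, raw panel frame."""
    cfg = CohortConfig(n_subjects=400, seed=20100101)
    df, trajs = observe_cohort(cfg)
    return cfg, df, trajs


@pytest.fixture(scope="session")
def small_modelling(small_cohort):
    """Phenotype-prepared, exclusion-applied modelling frame."""
    _, df, _ = small_cohort
    modelling, log = apply_exclusions(prepare_model_frame(df))
    return modelling, log


@pytest.fixture(scope="session")
def cohort_fit():
    """Full-size (study-scale) cohort fit with covariance, plus prevalence model.

    Uses n = 1216 subjects so every transition is informed and the observed
    information is well conditioned, as in the cohort the design emulates.
    """
    from mslt.model import fit
    from mslt.life_expectancy import fit_prevalence

    cfg = CohortConfig(n_subjects=1216, seed=20100101)
    df, _ = observe_cohort(cfg)
    modelling, _ = apply_exclusions(prepare_model_frame(df))
    fitted = fit(modelling, ModelSpec())
    prev = fit_prevalence(modelling, fitted.spec)
    return fitted, prev


def make_panel(records):
    """Build a long-format panel frame from (id, age, state, obstype) tuples.

    ``state`` may be None for censored records; covariate dummies default to
    the reference profile unless provided as a 5th dict element.
    """
    rows = []
    for rec in records:
        sid, age, state, obstype = rec[:4]
        covs = rec[4] if len(rec) > 4 else {}
        rows.append(
            {
                "id": sid,
                "age": float(age),
                "state": np.nan if state is None else float(state),
                "obstype": obstype,
                "female": covs.get("female", 0),
                "overweight": covs.get("overweight", 0),
                "obese": covs.get("obese", 0),
            }
        )
    return pd.DataFrame(rows)
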