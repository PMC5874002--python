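"""Analysis-variable derivation: BMI categories, functional limitation, exclusions.

Functional limitation follows the composite criterion proposed for the Chilean
older population: difficulty in at least one activity of daily living (ADL,
6 items), at least two instrumental ADL (IADL, 5 items), or at least three
mobility-function questions (MF, 11 items).  BMI uses the WHO cut-offs
(<18.5 underweight, 18.5-24.9 normal, 25-29.9 overweight, >=30 obese), with
half-open intervals: the lower bound of each category is inclusive, so a BMI
of exactly 25.0 is overweight and 30.0 is obese.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BmiCategory",
    "RawAssessment",
    "classify_bmi",
    "derive_functional_limitation",
    "apply_exclusions",
    "prepare_model_frame",
    "MissingAnthropometryError",
]

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

ADL_ITEMS = 6
IADL_ITEMS = 5
MF_ITEMS = 11


class MissingAnthropometryError(ValueError):
    """Raised when BMI is requested for a subject without weight or height."""


@dataclass(frozen=True)
class RawAssessment:
    """Item-count summary of one functional/anthropometric assessment."""

    adl_limit_count: int
    iadl_limit_count: int
    mf_limit_count: int
    weight_kg: float | None = None
    height_m: float | None = None

    def __post_init__(self):
        for value, n_items, name in (
            (self.adl_limit_count, ADL_ITEMS, "adl"),
            (self.iadl_limit_count, IADL_ITEMS, "iadl"),
            (self.mf_limit_count, MF_ITEMS, "mf"),
        ):
            if not 0 <= value <= n_items:
                raise ValueError(f"{name} count {value} outside 0..{n_items}")


class BmiCategory(str):
    """One of 'underweight', 'normal', 'overweight', 'obese'."""


def classify_bmi(weight_kg: float, height_m: float) -> str:
    """WHO BMI category from measured weight (kg) and height (m).

    Missing (None/NaN) anthropometry raises ``MissingAnthropometryError`` so
    the subject can be excluded downstream; non-positive values raise
    ``ValueError``.
    """
    if weight_kg is None or height_m is None:
        raise MissingAnthropometryError("missing weight or height")
    if isinstance(weight_kg, float) and math.isnan(weight_kg):
        raise MissingAnthropometryError("missing weight")
    if isinstance(height_m, float) and math.isnan(height_m):
        raise MissingAnthropometryError("missing height")
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / height_m**2
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def derive_functional_limitation(adl: int, iadl: int, mf: int) -> bool:
    """Composite functional-limitation state (True = limited, state 2).

    True iff adl >= 1, or iadl >= 2, or mf >= 3.
    """
    if adl < 0 or iadl < 0 or mf < 0:
        raise ValueError("limitation counts must be non-negative")
    if adl > ADL_ITEMS or iadl > IADL_ITEMS or mf > MF_ITEMS:
        raise ValueError("limitation count exceeds number of items")
    return adl >= 1 or iadl >= 2 or mf >= 3


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort's analysis exclusions to a long-format panel frame.

    Subjects with missing baseline weight or height are removed first (BMI
    cannot be determined), then underweight subjects (too rare to support
    estimation).  Underweight subjects are excluded from model *fitting*, not
    only from life-expectancy reporting, matching the analysis sample of the
    published hazard-ratio table.  Returns the modelling frame and a log of
    counts removed at each step; idempotent.
    """
    baseline = df.sort_values(["id", "age"], kind="mergesort").groupby("id").first()
    n_initial = len(baseline)

    missing = baseline.index[
        baseline["weight_kg"].isna() | baseline["height_m"].isna()
    ]
    kept = df[~df["id"].isin(missing)]
    base_kept = baseline.drop(index=missing)

    bmi_cat = pd.Series(
        [
            classify_bmi(w, h)
            for w, h in zip(base_kept["weight_kg"], base_kept["height_m"])
        ],
        index=base_kept.index,
    )
    underweight = bmi_cat.index[bmi_cat == "underweight"]
    out = kept[~kept["id"].isin(underweight)].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no subjects remain after exclusions")
    log = {
        "n_initial": int(n_initial),
        "n_missing_anthropometry": int(len(missing)),
        "n_complete_anthropometry": int(n_initial - len(missing)),
        "n_underweight": int(len(underweight)),
        "n_modelling": int(n_initial - len(missing) - len(underweight)),
    }
    return out, log


def prepare_model_frame(df: pd.DataFrame, use_stored_state: bool = True) -> pd.DataFrame:
    """Derive model covariates and the observed state from a raw panel frame.

    Adds ``bmi_cat`` (from baseline anthropometry), 0/1 dummies ``female``,
    ``overweight``, ``obese`` (reference: male, normal BMI), and — for panel
    records — the functional-limitation state from the item counts (unless
    ``use_stored_state`` and a ``state`` column already exists).  Exclusions
    are NOT applied here; see :func:`apply_exclusions`.
    """
    out = df.copy()
    baseline = out.sort_values(["id", "age"], kind="mergesort").groupby("id").first()

    def _cat(row):
        try:
            return classify_bmi(row["weight_kg"], row["height_m"])
        except MissingAnthropometryError:
            return np.nan

    bmi_cat = baseline.apply(_cat, axis=1)
    out["bmi_cat"] = out["id"].map(bmi_cat)
    out["female"] = (out["sex"] == "female").astype(int)
    out["overweight"] = (out["bmi_cat"] == "overweight").astype(int)
    out["obese"] = (out["bmi_cat"] == "obese").astype(int)
    if not (use_stored_state and "state" in out.columns):
        panel = out["obstype"] == "panel"
        out.loc[panel, "state"] = [
            2 if derive_functional_limitation(int(a), int(i), int(m)) else 1
            for a, i, m in zip(
                out.loc[panel, "adl_count"],
                out.loc[panel, "iadl_count"],
                out.loc[panel, "mf_count"],
            )
        ]
    return out


def write_exclusion_log(log: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=1)
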