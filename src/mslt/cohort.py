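"""Synthetic SABE-like longitudinal cohort generator.

Emulates the design of the Santiago SABE ageing cohort: community-dwelling
subjects aged 60+ recruited around year 2000, two follow-up interview waves
(about 4.5 and 9.5 years after baseline), deaths ascertained exactly from a
vital registry up to an administrative cut-off (~10.5 years), and a large
group of subjects known to be alive at the cut-off but with unknown health
state (right-censored).

Trajectories are simulated forward from a known three-state ground-truth model
(healthy <-> limited -> dead) with age-dependent intensities, approximated as
piecewise constant over a configurable micro-step.  Every subject owns an
independent random substream, so enlarging the cohort never perturbs existing
subjects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import TRANSITIONS, InvalidParameterError, ModelSpec

__all__ = [
    "GroundTruthIntensities",
    "CohortConfig",
    "Trajectory",
    "simulate_trajectory",
    "observe_cohort",
    "write_cohort",
    "read_cohort",
]

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


@dataclass(frozen=True)
class GroundTruthIntensities:
    """True log baseline intensities and covariate log-HRs, one per transition.

    Arrays are ordered as ``TRANSITIONS`` = (1->2, 2->1, 1->3, 2->3) and refer
    to a reference subject (male, normal BMI) at ``age_center`` years.  The
    default covariate effects are the published hazard-ratio point estimates
    for the Santiago cohort (age per +1 year; female vs male; overweight and
    obese vs normal BMI); the default baseline intensities were calibrated so
    that the model-implied life expectancies at 60 resemble the published ones.
    """

    theta: tuple = (
        math.log(0.160),  # 1->2 disability incidence /yr at reference
        math.log(0.180),  # 2->1 recovery /yr
        math.log(0.022),  # 1->3 mortality of non-disabled /yr
        math.log(0.110),  # 2->3 mortality of disabled /yr
    )
    beta_age: tuple = (
        math.log(1.06),
        math.log(0.97),
        math.log(1.06),
        math.log(1.06),
    )
    beta_female: tuple = (
        math.log(1.82),
        math.log(1.37),
        math.log(0.15),
        math.log(0.64),
    )
    beta_overweight: tuple = (
        math.log(1.03),
        math.log(0.74),
        math.log(0.93),
        math.log(0.81),
    )
    beta_obese: tuple = (
        math.log(1.56),
        math.log(1.42),
        math.log(0.10),
        math.log(0.91),
    )
    age_center: float = 70.0

    def __post_init__(self):
        for name in ("theta", "beta_age", "beta_female", "beta_overweight", "beta_obese"):
            v = getattr(self, name)
            if len(v) != len(TRANSITIONS) or not all(math.isfinite(x) for x in v):
                raise InvalidParameterError(f"{name} must be 4 finite reals")

    def to_params(self) -> np.ndarray:
        """Flat parameter vector matching the default ``ModelSpec`` layout."""
        return np.concatenate(
            [self.theta, self.beta_age, self.beta_female,
             self.beta_overweight, self.beta_obese]
        ).astype(float)

    def spec(self) -> ModelSpec:
        return ModelSpec(age_center=self.age_center)

    def linear_predictors(self, female: int, overweight: int, obese: int) -> np.ndarray:
        """Per-transition log-intensity at the reference age, given a profile."""
        lp = np.asarray(self.theta, dtype=float).copy()
        if female:
            lp += self.beta_female
        if overweight:
            lp += self.beta_overweight
        if obese:
            lp += self.beta_obese
        return lp


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the Santiago SABE design: n = 1216 subjects aged 60-99
    (decade weights from the published baseline table), two follow-up waves at
    4.5 and 9.5 years with +/- 0.5 y uniform jitter, registry cut-off at 10.5
    years, and a calibrated per-wave non-response probability producing a
    large alive-but-unknown censored group.
    """

    n_subjects: int = 1216
    baseline_age_min: float = 60.0
    baseline_age_max: float = 99.0
    #: probability weights per decade band starting at ``baseline_age_min``
    baseline_age_decade_weights: tuple = (0.52, 0.33, 0.12, 0.03)
    sex_fraction_female: float = 806 / 1216
    #: P(underweight, normal, overweight, obese) per sex
    bmi_category_probs: dict = field(
        default_factory=lambda: {
            "male": (0.015, 0.305, 0.451, 0.229),
            "female": (0.017, 0.254, 0.393, 0.336),
        }
    )
    wave_offsets_years: tuple = (4.5, 9.5)
    wave_jitter_years: float = 0.5
    admin_censor_years: float = 10.5
    wave_nonresponse_prob: float = 0.40
    missing_anthropometry_prob: float = 0.0
    burn_in_years: float = 5.0
    micro_step_years: float = 0.1
    true_params: GroundTruthIntensities = field(default_factory=GroundTruthIntensities)
    seed: int = 20100101

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        w = np.asarray(self.baseline_age_decade_weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("age decade weights must be non-negative, not all zero")
        for sex, p in self.bmi_category_probs.items():
            p = np.asarray(p, float)
            if len(p) != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"bmi_category_probs[{sex!r}] must sum to 1")
        if not 0 <= self.sex_fraction_female <= 1:
            raise ValueError("sex_fraction_female must be in [0, 1]")
        if not 0 <= self.wave_nonresponse_prob <= 1:
            raise ValueError("wave_nonresponse_prob must be in [0, 1]")
        offs = self.wave_offsets_years
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("wave offsets must be strictly increasing")
        if self.admin_censor_years < offs[-1]:
            raise ValueError("admin_censor_years must be >= last wave offset")
        if self.micro_step_years <= 0:
            raise ValueError("micro_step_years must be positive")


@dataclass
class Trajectory:
    """Complete latent state path of one subject.

    ``event_ages``/``event_states`` record the state after each change; states
    alternate between 1 and 2 until an optional terminal 3.
    """

    subject_id: int
    start_age: float
    start_state: int
    event_ages: list
    event_states: list
    death_age: float | None

    def state_at(self, age: float) -> int:
        """Latent state at a given age (3 if at/after death)."""
        if self.death_age is not None and age >= self.death_age:
            return 3
        state = self.start_state
        for a, s in zip(self.event_ages, self.event_states):
            if a <= age and s != 3:
                state = s
            elif a > age:
                break
        return state


def simulate_trajectory(
    covariates: dict,
    start_age: float,
    start_state: int,
    truth: GroundTruthIntensities,
    horizon: float,
    rng: np.random.Generator,
    micro_step: float | None = 0.1,
    subject_id: int = 0,
) -> Trajectory:
    """Forward-simulate one subject under the three-state ground truth.

    Intensities are held constant over micro-steps of ``micro_step`` years
    (bias O(step)); within a step with an exit, the event age is drawn
    uniformly.  Simulation stops at death or at ``start_age + horizon``.
    """
    if start_state not in (1, 2):
        raise ValueError("start_state must be 1 (healthy) or 2 (limited)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    lp = truth.linear_predictors(
        int(covariates.get("female", 0)),
        int(covariates.get("overweight", 0)),
        int(covariates.get("obese", 0)),
    )
    ba = truth.beta_age
    # per-transition (rate index into TRANSITIONS): exits from 1 are (0: 1->2,
    # 2: 1->3); exits from 2 are (1: 2->1, 3: 2->3)
    exits = {1: ((0, 2), (2, 3)), 2: ((1, 3), (1, 3))}
    h = micro_step
    n_steps = int(math.ceil(horizon / h))
    u_exit = rng.random(n_steps)
    u_dest = rng.random(n_steps)
    u_pos = rng.random(n_steps)

    state = start_state
    age = start_age
    end_age = start_age + horizon
    event_ages: list[float] = []
    event_states: list[int] = []
    death_age = None
    for i in range(n_steps):
        step = min(h, end_age - age)
        if step <= 0:
            break
        (idx_a, idx_b), (dest_a, dest_b) = exits[state]
        da = age - truth.age_center
        ra = math.exp(lp[idx_a] + ba[idx_a] * da)
        rb = math.exp(lp[idx_b] + ba[idx_b] * da)
        total = ra + rb
        if total > 0 and u_exit[i] < -math.expm1(-total * step):
            event_age = age + u_pos[i] * step
            dest = dest_a if u_dest[i] * total < ra else dest_b
            event_ages.append(event_age)
            event_states.append(dest)
            if dest == 3:
                death_age = event_age
                break
            state = dest
        age += step
    return Trajectory(
        subject_id=subject_id,
        start_age=start_age,
        start_state=start_state,
        event_ages=event_ages,
        event_states=event_states,
        death_age=death_age,
    )


# anthropometry (height in m) used to back out weight from a drawn BMI; rough
# Chilean older-adult values, truncated to plausible ranges
_HEIGHT = {"male": (1.68, 0.07), "female": (1.55, 0.065)}
_BMI_RANGES = {
    "underweight": (16.0, 18.5),
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, 40.0),
}


def _draw_limitation_counts(rng: np.random.Generator, limited: bool):
    """ADL/IADL/MF difficulty counts consistent with the latent state.

    The composite criterion is >=1 ADL, or >=2 IADL, or >=3 MF limitations;
    counts are drawn so that limited subjects satisfy at least one criterion
    (MF difficulties most common, as in the published baseline table) and
    healthy subjects satisfy none.
    """
    if not limited:
        adl = 0
        iadl = 1 if rng.random() < 0.15 else 0
        mf = int(rng.integers(0, 3))  # 0..2
        return adl, iadl, mf
    has_adl = rng.random() < 0.5
    has_iadl = rng.random() < 0.4
    has_mf = rng.random() < 0.85
    if not (has_adl or has_iadl or has_mf):
        has_mf = True
    adl = int(rng.integers(1, 7)) if has_adl else 0
    iadl = int(rng.integers(2, 6)) if has_iadl else (1 if rng.random() < 0.3 else 0)
    mf = int(rng.integers(3, 12)) if has_mf else int(rng.integers(0, 3))
    return adl, iadl, mf


def _draw_baseline(cfg: CohortConfig, rng: np.random.Generator):
    """Baseline age, sex and anthropometry for one subject."""
    w = np.asarray(cfg.baseline_age_decade_weights, float)
    w = w / w.sum()
    band = int(rng.choice(len(w), p=w))
    lo = cfg.baseline_age_min + 10.0 * band
    hi = min(lo + 10.0, cfg.baseline_age_max)
    age = float(rng.uniform(lo, hi))
    sex = "female" if rng.random() < cfg.sex_fraction_female else "male"
    bmi_cat = str(rng.choice(BMI_CATEGORIES, p=np.asarray(cfg.bmi_category_probs[sex])))
    mu, sd = _HEIGHT[sex]
    height = float(np.clip(rng.normal(mu, sd), 1.35, 2.0))
    bmi = float(rng.uniform(*_BMI_RANGES[bmi_cat]))
    weight = bmi * height**2
    if rng.random() < cfg.missing_anthropometry_prob:
        weight = np.nan
        height = np.nan
    return age, sex, bmi_cat, weight, height


def observe_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, list[Trajectory]]:
    """Simulate the cohort and apply the observation scheme.

    Returns the long-format panel data frame (one row per interview, exact
    death or censoring event) and the underlying ground-truth trajectories.

    Each subject gets a baseline interview; per follow-up wave, an interview
    record if alive and responding; an exact-death record if death occurs
    before the administrative cut-off; and, if alive at the cut-off without a
    final-wave interview, a right-censored alive-state-unknown record at the
    cut-off age.  Baseline state arises endogenously by burn-in: trajectories
    start healthy ``burn_in_years`` before baseline, conditioned on surviving
    to baseline.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects)
    rows = []
    trajectories = []
    for sid, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        age0, sex, bmi_cat, weight, height = _draw_baseline(cfg, rng)
        covs = {
            "female": int(sex == "female"),
            "overweight": int(bmi_cat == "overweight"),
            "obese": int(bmi_cat == "obese"),
        }
        # Baseline state by burn-in: simulate from healthy `burn_in_years`
        # before baseline, conditioned on surviving to baseline (community
        # recruitment).  Only the burn-in segment is conditioned; if survival
        # is too unlikely to sample (extreme mortality), fall back to a
        # healthy baseline, which is the dominant surviving path anyway.
        burn = None
        if cfg.burn_in_years > 0:
            for _ in range(200):
                cand = simulate_trajectory(
                    covs, age0 - cfg.burn_in_years, 1, cfg.true_params,
                    cfg.burn_in_years, rng,
                    micro_step=cfg.micro_step_years, subject_id=sid,
                )
                if cand.death_age is None:
                    burn = cand
                    break
        baseline_state = burn.state_at(age0) if burn is not None else 1
        main_horizon = cfg.admin_censor_years + cfg.wave_jitter_years + 0.1
        main = simulate_trajectory(
            covs, age0, baseline_state, cfg.true_params, main_horizon, rng,
            micro_step=cfg.micro_step_years, subject_id=sid,
        )
        traj = Trajectory(
            subject_id=sid,
            start_age=age0 - cfg.burn_in_years if burn is not None else age0,
            start_state=1 if burn is not None else baseline_state,
            event_ages=(burn.event_ages if burn is not None else []) + main.event_ages,
            event_states=(burn.event_states if burn is not None else [])
            + main.event_states,
            death_age=main.death_age,
        )
        trajectories.append(traj)

        def interview(age_at):
            st = traj.state_at(age_at)
            adl, iadl, mf = _draw_limitation_counts(rng, st == 2)
            rows.append(
                dict(
                    id=sid, age=age_at, state=st, obstype="panel", sex=sex,
                    bmi_cat=bmi_cat, weight_kg=weight, height_m=height,
                    adl_count=adl, iadl_count=iadl, mf_count=mf,
                )
            )

        interview(age0)
        censor_age = age0 + cfg.admin_censor_years
        death_age = traj.death_age if (
            traj.death_age is not None and traj.death_age <= censor_age
        ) else None
        saw_final_wave = False
        for w_i, offset in enumerate(cfg.wave_offsets_years):
            jitter = rng.uniform(-cfg.wave_jitter_years, cfg.wave_jitter_years)
            wave_age = age0 + offset + jitter
            responds = rng.random() >= cfg.wave_nonresponse_prob
            if death_age is not None and wave_age >= death_age:
                continue
            if responds:
                interview(wave_age)
                if w_i == len(cfg.wave_offsets_years) - 1:
                    saw_final_wave = True
        if death_age is not None:
            rows.append(
                dict(
                    id=sid, age=death_age, state=3, obstype="death", sex=sex,
                    bmi_cat=bmi_cat, weight_kg=weight, height_m=height,
                    adl_count=np.nan, iadl_count=np.nan, mf_count=np.nan,
                )
            )
        elif not saw_final_wave:
            rows.append(
                dict(
                    id=sid, age=censor_age, state=np.nan, obstype="censored",
                    sex=sex, bmi_cat=bmi_cat, weight_kg=weight, height_m=height,
                    adl_count=np.nan, iadl_count=np.nan, mf_count=np.nan,
                )
            )
    df = pd.DataFrame(rows)
    return df, trajectories


def write_cohort(df: pd.DataFrame, cfg: CohortConfig, csv_path, json_path=None) -> None:
    """Write the panel CSV plus a JSON sidecar with the generating config."""
    df.to_csv(csv_path, index=False, float_format="%.10g")
    if json_path is None:
        json_path = str(csv_path) + ".json"
    payload = asdict(cfg)
    payload["true_params"] = asdict(cfg.true_params)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_cohort(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
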