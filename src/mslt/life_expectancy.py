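"""State-specific and marginal life expectancies from a fitted multistate model.

Expected years lived in each living state are obtained by integrating state
occupancy probabilities over age::

    e_rs(x) = integral_x^{max_age} P_rs(x, a) da

where P is built as a product of interval matrix exponentials over a fine age
grid, with the intensity matrix refreshed at every grid point so that the
time-dependent age effect is followed.  Totals marginal over the starting
state weight the healthy-start and limited-start rows by the model-estimated
probability of being limited at the starting age (a logistic prevalence model
fitted to baseline interviews), the approach of the ELECT family of
multistate life-table estimators.  Percentile confidence intervals come from
re-computing all quantities under parameter vectors drawn from the asymptotic
normal distribution of the MLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import FittedModel, ModelSpec, InvalidParameterError

__all__ = [
    "PrevalenceModel",
    "LifeExpectancySet",
    "fit_prevalence",
    "occupancy",
    "state_expectancies",
    "marginal_life_expectancies",
    "simulate_cis",
]

DEFAULT_GRID_STEP = 0.25
DEFAULT_MAX_AGE = 115.0
DEFAULT_SEED = 20100101


# ---------------------------------------------------------------------------
# occupancy probabilities and state expectancies
# ---------------------------------------------------------------------------


def _profile_vector(spec: ModelSpec, profile: dict) -> np.ndarray:
    """Non-age covariate values in spec order (age column left at 0)."""
    z = np.zeros(len(spec.covariates))
    for k, name in enumerate(spec.covariates):
        if name != "age":
            z[k] = float(profile[name])
    return z


def _age_beta_split(spec: ModelSpec, params: np.ndarray):
    """theta + profile effects as (B, 4) plus the per-transition age slopes."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    nt = 4
    theta = params[:, :nt]
    beta = params[:, nt:].reshape(params.shape[0], len(spec.covariates), nt)
    return theta, beta


def _occupancy_living_batch(
    params: np.ndarray,
    spec: ModelSpec,
    profile: dict,
    grid: np.ndarray,
) -> np.ndarray:
    """Living-state occupancy P(grid[0], a) for each parameter row.

    Returns an array of shape (B, n_grid, 2, 2): entry [b, i, r-1, s-1] is the
    probability of occupying living state s at age grid[i] given living state
    r at grid[0], under parameter row b.  Because death is absorbing, the
    living 2x2 block of the interval exponential factorises across grid steps
    and the death column is the row complement.
    """
    theta, beta = _age_beta_split(spec, params)
    z = _profile_vector(spec, profile)
    base = theta + np.einsum("k,bkt->bt", z, beta)  # (B, 4)
    try:
        age_idx = spec.covariates.index("age")
        beta_age = beta[:, age_idx, :]  # (B, 4)
    except ValueError:
        beta_age = np.zeros_like(base)

    B = base.shape[0]
    n = len(grid)
    occ = np.empty((B, n, 2, 2))
    occ[:, 0] = np.eye(2)
    m11 = np.ones(B)
    m12 = np.zeros(B)
    m21 = np.zeros(B)
    m22 = np.ones(B)
    from .model import _expm_living, _LOGQ_MAX

    for i in range(1, n):
        a0, a1 = grid[i - 1], grid[i]
        logq = base + beta_age * (a0 - spec.age_center)
        if not np.all(np.isfinite(logq)) or np.any(logq > _LOGQ_MAX):
            raise InvalidParameterError("overflowing intensity on occupancy grid")
        q12, q21, q13, q23 = np.exp(logq).T
        p11, p12, p21, p22 = _expm_living(
            -(q12 + q13), q12, q21, -(q21 + q23), a1 - a0
        )
        n11 = m11 * p11 + m12 * p21
        n12 = m11 * p12 + m12 * p22
        n21 = m21 * p11 + m22 * p21
        n22 = m21 * p12 + m22 * p22
        m11, m12, m21, m22 = n11, n12, n21, n22
        occ[:, i, 0, 0] = m11
        occ[:, i, 0, 1] = m12
        occ[:, i, 1, 0] = m21
        occ[:, i, 1, 1] = m22
    return occ


def _make_grid(start_age: float, max_age: float, grid_step: float) -> np.ndarray:
    if start_age >= max_age:
        raise ValueError("start_age must be below max_age")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(np.ceil((max_age - start_age) / grid_step))
    return np.linspace(start_age, max_age, n + 1)


def occupancy(
    fitted: FittedModel,
    profile: dict,
    start_age: float,
    start_state: int,
    grid_step: float = DEFAULT_GRID_STEP,
    max_age: float = DEFAULT_MAX_AGE,
) -> pd.DataFrame:
    """Occupancy curves P_{start_state,s}(start_age, a) over an age grid.

    Returns a frame with columns ``age, p_healthy, p_limited, p_dead``.
    """
    if start_state not in (1, 2):
        raise ValueError("start_state must be 1 or 2")
    grid = _make_grid(start_age, max_age, grid_step)
    occ = _occupancy_living_batch(fitted.params, fitted.spec, profile, grid)[0]
    row = occ[:, start_state - 1, :]
    return pd.DataFrame(
        {
            "age": grid,
            "p_healthy": row[:, 0],
            "p_limited": row[:, 1],
            "p_dead": 1.0 - row.sum(axis=1),
        }
    )


def _expectancies_from_occupancy(occ: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of (B, n, 2, 2) occupancy -> (B, 2, 2) years."""
    return np.trapezoid(occ, grid, axis=1)


def state_expectancies(
    fitted: FittedModel,
    profile: dict,
    start_age: float,
    grid_step: float = DEFAULT_GRID_STEP,
    max_age: float = DEFAULT_MAX_AGE,
    truncation_warning: float = 1e-3,
) -> np.ndarray:
    """Expected years in each living state, as a 2x2 matrix e[r-1, s-1].

    e_rs integrates the probability of occupying state s at age a, given state
    r at ``start_age``, up to ``max_age`` (trapezoidal rule).  A warning is
    issued if non-negligible living occupancy remains at ``max_age``
    (truncation bias).
    """
    grid = _make_grid(start_age, max_age, grid_step)
    occ = _occupancy_living_batch(fitted.params, fitted.spec, profile, grid)
    living_at_end = occ[0, -1].sum(axis=1).max()
    if living_at_end > truncation_warning:
        import warnings

        warnings.warn(
            f"living occupancy {living_at_end:.2e} remains at max_age={max_age}; "
            "expectancies are truncated"
        )
    return _expectancies_from_occupancy(occ, grid)[0]


# ---------------------------------------------------------------------------
# baseline prevalence model (for marginal expectancies)
# ---------------------------------------------------------------------------


@dataclass
class PrevalenceModel:
    """Logistic model for P(limited | alive) at a given age and profile.

    Linear predictor: intercept + slope * (age - age_center) + profile terms,
    fitted by direct likelihood maximisation on baseline interview records.
    """

    coefficients: np.ndarray  # intercept, age slope, then non-age covariates
    covariates: tuple  # non-age covariate names, in order
    age_center: float = 70.0

    def linear_predictor(self, age: float, profile: dict) -> float:
        eta = self.coefficients[0] + self.coefficients[1] * (age - self.age_center)
        for k, name in enumerate(self.covariates):
            eta += self.coefficients[2 + k] * float(profile[name])
        return float(eta)

    def predict(self, age: float, profile: dict) -> float:
        eta = self.linear_predictor(age, profile)
        return float(1.0 / (1.0 + np.exp(-eta)))


def fit_prevalence(
    df: pd.DataFrame, spec: ModelSpec | None = None
) -> PrevalenceModel:
    """Fit the baseline-prevalence logistic model.

    Uses each subject's first record (the baseline interview); the response is
    1 for state 2.  Maximised with BFGS on the exact logistic log-likelihood.
    """
    spec = spec or ModelSpec()
    base = df.sort_values(["id", "age"], kind="mergesort").groupby("id").first()
    base = base[base["obstype"] == "panel"]
    covs = tuple(c for c in spec.covariates if c != "age")
    X = np.column_stack(
        [
            np.ones(len(base)),
            base["age"].to_numpy(float) - spec.age_center,
        ]
        + [base[c].to_numpy(float) for c in covs]
    )
    y = (base["state"].to_numpy(float) == 2).astype(float)

    def nll(b):
        eta = X @ b
        # log(1 + e^eta) - y*eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS")
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise RuntimeError(f"prevalence model did not converge: {res.message}")
    return PrevalenceModel(
        coefficients=res.x, covariates=covs, age_center=spec.age_center
    )


# ---------------------------------------------------------------------------
# marginal life expectancies and simulation CIs
# ---------------------------------------------------------------------------


@dataclass
class LifeExpectancySet:
    """Total, disability-free and disabled life expectancy at one age/profile.

    ``total_le = dfle + dle`` exactly (pre-rounding) and
    ``pct_disabled = 100 * dle / total_le``.  ``ci`` maps quantity name to the
    (2.5th, 97.5th) percentile pair when simulation intervals were computed.
    """

    age: float
    profile: dict
    e_rs: np.ndarray  # 2x2 expected years in state s starting from r
    dfle: float
    dle: float
    total_le: float
    pct_disabled: float
    start_prevalence: float
    ci: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "age": self.age,
            **{k: v for k, v in self.profile.items()},
            "total_le": self.total_le,
            "dfle": self.dfle,
            "dle": self.dle,
            "pct_disabled": self.pct_disabled,
        }
        for q, (lo, hi) in self.ci.items():
            row[f"{q}_lo95"] = lo
            row[f"{q}_hi95"] = hi
        return row


def _marginalise(e_rs: np.ndarray, pi: float | np.ndarray):
    """Weight starting states by limited-prevalence pi; returns dfle, dle."""
    w1 = 1.0 - pi
    dfle = w1 * e_rs[..., 0, 0] + pi * e_rs[..., 1, 0]
    dle = w1 * e_rs[..., 0, 1] + pi * e_rs[..., 1, 1]
    return dfle, dle


def marginal_life_expectancies(
    fitted: FittedModel,
    prev: PrevalenceModel | None,
    profile: dict,
    start_age: float,
    grid_step: float = DEFAULT_GRID_STEP,
    max_age: float = DEFAULT_MAX_AGE,
    weighting: str = "prevalence",
) -> LifeExpectancySet:
    """Point estimates of LE, DFLE, DLE and % disabled at one age/profile.

    ``weighting='prevalence'`` (default) marginalises over the starting state
    with the prevalence model; ``weighting='healthy'`` conditions on starting
    healthy (the e_1s row).
    """
    e_rs = state_expectancies(fitted, profile, start_age, grid_step, max_age)
    if weighting == "prevalence":
        if prev is None:
            raise ValueError("prevalence weighting requires a PrevalenceModel")
        pi = prev.predict(start_age, profile)
    elif weighting == "healthy":
        pi = 0.0
    else:
        raise ValueError("weighting must be 'prevalence' or 'healthy'")
    dfle, dle = _marginalise(e_rs, pi)
    total = dfle + dle
    return LifeExpectancySet(
        age=start_age,
        profile=dict(profile),
        e_rs=e_rs,
        dfle=float(dfle),
        dle=float(dle),
        total_le=float(total),
        pct_disabled=float(100.0 * dle / total) if total > 0 else float("nan"),
        start_prevalence=float(pi),
    )


#: per-direction cap on the proposal standard deviation (log-intensity units).
#: Directions with no likelihood curvature (an effect driven to the boundary
#: because the relevant events were never observed) yield a pseudo-inverse
#: covariance with arbitrarily large or even negative eigenvalues; the cap
#: replaces those with a wide-but-finite spread, an order of magnitude beyond
#: any data-supported standard error on this scale.
SD_CAP = 10.0


def draw_parameters(
    fitted: FittedModel, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Multivariate-normal parameter draws around the MLE.

    The covariance is stabilised by eigenvalue clipping to ``[0, SD_CAP**2]``:
    negative eigenvalues (numeric differencing noise, indefinite information at
    a boundary optimum) are set to zero, and curvature-free directions are
    given the finite spread ``SD_CAP`` instead of a meaningless huge one.  The
    fitted covariance itself is left untouched.
    """
    if fitted.covariance is None:
        raise ValueError("fit has no covariance matrix; cannot simulate")
    cov = np.asarray(fitted.covariance)
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, SD_CAP**2)
    L = V * np.sqrt(w)
    z = rng.standard_normal((n_sim, len(fitted.params)))
    return fitted.params[None, :] + z @ L.T


def simulate_cis(
    fitted: FittedModel,
    prev: PrevalenceModel | None,
    profile: dict,
    ages,
    n_sim: int = 1000,
    seed: int = DEFAULT_SEED,
    grid_step: float = DEFAULT_GRID_STEP,
    max_age: float = DEFAULT_MAX_AGE,
    weighting: str = "prevalence",
    return_draws: bool = False,
):
    """Life expectancies with simulation-based 95% percentile intervals.

    Parameter vectors are drawn from N(MLE, covariance); every quantity is
    recomputed per draw and the 2.5/97.5 empirical percentiles reported.  The
    point estimate remains the MLE plug-in.  Draws whose intensities overflow
    on the grid are rejected and redrawn (at most 10% of ``n_sim``).

    Returns a list of :class:`LifeExpectancySet`, one per age (plus the raw
    per-draw quantity arrays if ``return_draws``).
    """
    rng = np.random.default_rng(seed)
    point = [
        marginal_life_expectancies(
            fitted, prev, profile, a, grid_step, max_age, weighting
        )
        for a in ages
    ]
    if n_sim <= 0:
        return (point, {}) if return_draws else point

    draws = np.empty((n_sim, len(fitted.params)))
    n_ok = 0
    n_rejected = 0
    max_reject = max(1, int(0.1 * n_sim))
    while n_ok < n_sim:
        batch = draw_parameters(fitted, n_sim - n_ok, rng)
        z = _profile_vector(fitted.spec, profile)
        age_lo = min(ages) - fitted.spec.age_center
        age_hi = max_age - fitted.spec.age_center
        for row in batch:
            # reject draws whose intensities overflow anywhere on the age grid
            theta, beta = fitted.spec.split(row)
            worst = theta + z @ beta
            try:
                age_idx = fitted.spec.covariates.index("age")
                worst = worst + np.maximum(
                    beta[age_idx] * age_lo, beta[age_idx] * age_hi
                )
            except ValueError:
                pass
            if np.all(np.isfinite(row)) and np.all(worst < 50.0):
                draws[n_ok] = row
                n_ok += 1
            else:
                n_rejected += 1
                if n_rejected > max_reject:
                    raise RuntimeError(
                        "more than 10% of parameter draws rejected for overflow"
                    )

    draw_store = {}
    for est in point:
        grid = _make_grid(est.age, max_age, grid_step)
        occ = _occupancy_living_batch(draws, fitted.spec, profile, grid)
        e = _expectancies_from_occupancy(occ, grid)  # (n_sim, 2, 2)
        pi = est.start_prevalence if weighting == "prevalence" else 0.0
        dfle, dle = _marginalise(e, pi)
        total = dfle + dle
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * dle / total
        qs = {
            "total_le": total,
            "dfle": dfle,
            "dle": dle,
            "pct_disabled": pct,
        }
        est.ci = {
            name: tuple(np.percentile(vals, [2.5, 97.5])) for name, vals in qs.items()
        }
        draw_store[est.age] = qs
    return (point, draw_store) if return_draws else point
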