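"""Continuous-time three-state illness-death model for interval-censored panel data.

The model has states 1 = healthy (no functional limitation), 2 = functionally
limited, 3 = dead (absorbing), with four allowed transitions
(1->2 disability incidence, 2->1 recovery, 1->3 mortality of the non-disabled,
2->3 mortality of the disabled).  Each transition intensity is log-linear in
covariates::

    q_rs(z, age) = exp(theta_rs + beta_age_rs * (age - age_center)
                       + sum_k beta_k_rs * z_k)

Subjects are observed as panel data: the living state is known only at
interview ages, death ages are exact (vital registry), and subjects alive at
the administrative cut-off without a final interview are right-censored with
state known to be alive but otherwise unknown.  The likelihood follows the
standard panel-data factorisation over consecutive observation pairs, with the
intensity matrix held constant over each observation interval at its
start-of-interval value (time-dependent age is piecewise constant).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TRANSITIONS",
    "TRANSITION_LABELS",
    "ModelSpec",
    "ObservationRecord",
    "FittedModel",
    "InvalidParameterError",
    "intensity_matrix",
    "transition_probability",
    "log_likelihood",
    "fit",
    "hazard_ratios",
    "validate_panel",
]

#: allowed transitions, in parameter order
TRANSITIONS = ((1, 2), (2, 1), (1, 3), (2, 3))

TRANSITION_LABELS = {
    (1, 2): "Disability incidence",
    (2, 1): "Recovery",
    (1, 3): "Mortality of non-disabled",
    (2, 3): "Mortality of disabled",
}

#: observation-type codes used in the long-format panel data
OBSTYPE_PANEL = "panel"
OBSTYPE_DEATH = "death"
OBSTYPE_CENSORED = "censored"


class InvalidParameterError(ValueError):
    """Raised when parameters produce non-finite or overflowing intensities."""


@dataclass(frozen=True)
class ModelSpec:
    """State space, allowed transitions and covariate design.

    Parameters
    ----------
    covariates
        Ordered covariate names, each applied to every allowed transition.
        The name ``"age"`` is special: it is time-dependent and entered as
        ``age - age_center`` (years).  Other names refer to columns of the
        panel data frame (typically 0/1 dummies).
    age_center
        Centering constant for the age covariate, in years.
    """

    covariates: tuple[str, ...] = ("age", "female", "overweight", "obese")
    age_center: float = 70.0

    @property
    def n_params(self) -> int:
        return len(TRANSITIONS) * (1 + len(self.covariates))

    def parameter_labels(self) -> list[str]:
        labels = [f"theta[{r}->{s}]" for r, s in TRANSITIONS]
        for cov in self.covariates:
            labels += [f"beta_{cov}[{r}->{s}]" for r, s in TRANSITIONS]
        return labels

    def split(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a flat parameter vector into ``theta`` (4,) and ``beta`` (K, 4)."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"expected {self.n_params} parameters, got shape {params.shape}"
            )
        nt = len(TRANSITIONS)
        return params[:nt], params[nt:].reshape(len(self.covariates), nt)


@dataclass(frozen=True)
class ObservationRecord:
    """One observed time point of a subject.

    ``state`` is 1/2/3 or ``None`` for a right-censored alive-but-unknown
    record; ``obstype`` is ``"panel"``, ``"death"`` or ``"censored"``.
    """

    subject_id: int
    age: float
    state: int | None
    obstype: str
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class FittedModel:
    """Maximum-likelihood fit of the three-state model."""

    spec: ModelSpec
    params: np.ndarray
    covariance: np.ndarray | None
    log_likelihood: float
    convergence: dict

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))

    def standard_errors(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("covariance was not computed for this fit")
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def to_json(self, path) -> None:
        payload = {
            "covariates": list(self.spec.covariates),
            "age_center": self.spec.age_center,
            "labels": self.spec.parameter_labels(),
            "params": self.params.tolist(),
            "covariance": None
            if self.covariance is None
            else self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "convergence": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.convergence.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            payload = json.load(fh)
        spec = ModelSpec(
            covariates=tuple(payload["covariates"]),
            age_center=float(payload["age_center"]),
        )
        cov = payload["covariance"]
        return cls(
            spec=spec,
            params=np.asarray(payload["params"], dtype=float),
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            log_likelihood=float(payload["log_likelihood"]),
            convergence=payload["convergence"],
        )


# ---------------------------------------------------------------------------
# intensity matrix and transition probabilities
# ---------------------------------------------------------------------------

_LOGQ_MAX = 50.0  # exp(50) ~ 5e21: anything beyond is a parameter error


def _covariate_values(spec: ModelSpec, covariates: dict, age: float) -> np.ndarray:
    z = np.empty(len(spec.covariates))
    for k, name in enumerate(spec.covariates):
        if name == "age":
            z[k] = age - spec.age_center
        else:
            z[k] = float(covariates[name])
    return z


def intensity_matrix(
    params: np.ndarray, spec: ModelSpec, covariates: dict, age: float
) -> np.ndarray:
    """Transition intensity matrix Q (3x3) at a covariate profile and age.

    Off-diagonal allowed entries are ``exp(theta + beta'z)``; disallowed
    entries are 0; diagonals are the negated row sums; the dead row is zero.
    """
    theta, beta = spec.split(params)
    z = _covariate_values(spec, covariates, age)
    logq = theta + z @ beta
    if not np.all(np.isfinite(logq)) or np.any(logq > _LOGQ_MAX):
        raise InvalidParameterError(f"non-finite or overflowing log-intensity: {logq}")
    q = np.exp(logq)
    Q = np.zeros((3, 3))
    for (r, s), qi in zip(TRANSITIONS, q):
        Q[r - 1, s - 1] = qi
    Q[0, 0] = -(Q[0, 1] + Q[0, 2])
    Q[1, 1] = -(Q[1, 0] + Q[1, 2])
    return Q


def _expm_living(a, b, c, d, dt):
    """Matrix exponential of the 2x2 living-state generator block, batched.

    ``[[a, b], [c, d]]`` with ``b, c >= 0`` and non-positive row sums has real
    eigenvalues ``m +/- delta`` with ``m = (a+d)/2 <= 0`` and
    ``delta = sqrt(((a-d)/2)^2 + b c) <= -m``, so the exponential is computed
    stably from ``exp(m + delta)`` and ``exp(m - delta)``.

    Returns the four entries of ``expm(A * dt)``.
    """
    a = a * dt
    b = b * dt
    c = c * dt
    d = d * dt
    m = 0.5 * (a + d)
    half_diff = 0.5 * (a - d)
    delta = np.sqrt(half_diff * half_diff + b * c)
    ep = np.exp(m + delta)
    en = np.exp(m - delta)
    cosh_term = 0.5 * (ep + en)
    small = delta < 1e-7
    safe_delta = np.where(small, 1.0, delta)
    sinhc = np.where(
        small,
        np.exp(m) * (1.0 + delta * delta / 6.0),
        0.5 * (ep - en) / safe_delta,
    )
    p11 = cosh_term + sinhc * half_diff
    p12 = sinhc * b
    p21 = sinhc * c
    p22 = cosh_term - sinhc * half_diff
    return p11, p12, p21, p22


def transition_probability(
    params: np.ndarray,
    spec: ModelSpec,
    covariates: dict,
    age0: float,
    age1: float,
    grid_step: float | None = None,
) -> np.ndarray:
    """Transition probability matrix P(age0, age1) (3x3, row-stochastic).

    By default Q is held constant at its value at ``age0`` (the panel-data
    convention for time-dependent age).  If ``grid_step`` is given, the
    interval is chopped into sub-intervals of at most that length with Q
    refreshed at each sub-interval start, and P is the ordered product of
    sub-interval exponentials.
    """
    if age1 < age0:
        raise ValueError("age1 must be >= age0")
    if grid_step is None:
        breaks = np.array([age0, age1])
    else:
        n = max(1, int(np.ceil((age1 - age0) / grid_step)))
        breaks = np.linspace(age0, age1, n + 1)
    P = np.eye(3)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        Q = intensity_matrix(params, spec, covariates, lo)
        p11, p12, p21, p22 = _expm_living(Q[0, 0], Q[0, 1], Q[1, 0], Q[1, 1], hi - lo)
        step = np.eye(3)
        step[0, 0], step[0, 1] = p11, p12
        step[1, 0], step[1, 1] = p21, p22
        step[0, 2] = max(0.0, 1.0 - p11 - p12)
        step[1, 2] = max(0.0, 1.0 - p21 - p22)
        P = P @ step
    return P


# ---------------------------------------------------------------------------
# dataset compilation and likelihood
# ---------------------------------------------------------------------------

_KIND_PANEL = 0
_KIND_DEATH = 1
_KIND_CENSORED = 2


def validate_panel(df: pd.DataFrame, spec: ModelSpec | None = None) -> None:
    """Check the ObservationRecord invariants of a long-format panel frame.

    Required columns: ``id, age, state, obstype`` plus the non-age covariates
    of ``spec``.  Raises ``ValueError`` on the first violation.
    """
    required = {"id", "age", "state", "obstype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel data missing columns: {sorted(missing)}")
    if spec is not None:
        missing_cov = [
            c for c in spec.covariates if c != "age" and c not in df.columns
        ]
        if missing_cov:
            raise ValueError(f"panel data missing covariate columns: {missing_cov}")
    bad_type = set(df["obstype"]) - {OBSTYPE_PANEL, OBSTYPE_DEATH, OBSTYPE_CENSORED}
    if bad_type:
        raise ValueError(f"unknown obstype values: {sorted(bad_type)}")
    for sid, grp in df.groupby("id", sort=False):
        ages = grp["age"].to_numpy(dtype=float)
        if not np.all(np.diff(ages) > 0):
            raise ValueError(f"subject {sid}: ages not strictly increasing")
        types = grp["obstype"].to_numpy()
        states = grp["state"].to_numpy()
        terminal = np.isin(types, (OBSTYPE_DEATH, OBSTYPE_CENSORED))
        if terminal[:-1].any():
            raise ValueError(f"subject {sid}: records after a terminal record")
        for st, ty in zip(states, types):
            if ty == OBSTYPE_DEATH and not (st == 3):
                raise ValueError(f"subject {sid}: exact-death record without state 3")
            if ty == OBSTYPE_CENSORED and not pd.isna(st):
                raise ValueError(
                    f"subject {sid}: censored-alive record must have unknown state"
                )
            if ty == OBSTYPE_PANEL and st not in (1, 2):
                raise ValueError(f"subject {sid}: panel record with state {st}")


@dataclass
class _CompiledIntervals:
    """Arrays over consecutive observation pairs, for vectorised likelihood."""

    age0: np.ndarray
    dt: np.ndarray
    from_state: np.ndarray  # 1 or 2
    to_state: np.ndarray  # 1/2 for panel pairs, 0 otherwise
    kind: np.ndarray  # _KIND_*
    Z: np.ndarray  # (n_intervals, n_covariates); age column filled with age0-center
    subject_index: np.ndarray  # index into subject list, for per-subject totals
    n_subjects: int


def compile_intervals(df: pd.DataFrame, spec: ModelSpec) -> _CompiledIntervals:
    df = df.sort_values(["id", "age"], kind="mergesort")
    ids = df["id"].to_numpy()
    age = df["age"].to_numpy(dtype=float)
    state = df["state"].to_numpy(dtype=float)  # NaN for censored
    obstype = df["obstype"].to_numpy()

    new_subject = np.empty(len(df), dtype=bool)
    new_subject[0] = True
    new_subject[1:] = ids[1:] != ids[:-1]
    pair = ~new_subject  # rows that close an interval with their predecessor
    idx1 = np.nonzero(pair)[0]
    idx0 = idx1 - 1

    kind = np.full(idx1.shape, _KIND_PANEL, dtype=np.int8)
    kind[obstype[idx1] == OBSTYPE_DEATH] = _KIND_DEATH
    kind[obstype[idx1] == OBSTYPE_CENSORED] = _KIND_CENSORED

    from_state = state[idx0]
    if np.any(~np.isin(from_state, (1.0, 2.0))):
        raise ValueError("interval starting from a non-living or unknown state")
    to_state = np.where(kind == _KIND_PANEL, state[idx1], 0.0)

    age0 = age[idx0]
    Z = np.empty((len(idx1), len(spec.covariates)))
    for k, name in enumerate(spec.covariates):
        if name == "age":
            Z[:, k] = age0 - spec.age_center
        else:
            Z[:, k] = df[name].to_numpy(dtype=float)[idx0]

    subject_index = np.cumsum(new_subject)[idx0] - 1
    return _CompiledIntervals(
        age0=age0,
        dt=age[idx1] - age0,
        from_state=from_state.astype(np.int8),
        to_state=to_state.astype(np.int8),
        kind=kind,
        Z=Z,
        subject_index=subject_index,
        n_subjects=int(new_subject.sum()),
    )


def _interval_log_contributions(
    params: np.ndarray, spec: ModelSpec, iv: _CompiledIntervals
) -> np.ndarray:
    theta, beta = spec.split(params)
    logq = theta[None, :] + iv.Z @ beta  # (n, 4) in TRANSITIONS order
    if not np.all(np.isfinite(logq)) or np.any(logq > _LOGQ_MAX):
        raise InvalidParameterError("non-finite or overflowing log-intensity")
    q12, q21, q13, q23 = np.exp(logq).T
    p11, p12, p21, p22 = _expm_living(-(q12 + q13), q12, q21, -(q21 + q23), iv.dt)
    pd1 = np.clip(1.0 - p11 - p12, 0.0, None)
    pd2 = np.clip(1.0 - p21 - p22, 0.0, None)

    from1 = iv.from_state == 1
    pa = np.where(from1, p11, p21)  # P(alive in 1 at end)
    pb = np.where(from1, p12, p22)  # P(alive in 2 at end)

    lik = np.empty(len(iv.dt))
    panel = iv.kind == _KIND_PANEL
    lik[panel] = np.where(iv.to_state[panel] == 1, pa[panel], pb[panel])
    # interval-censored death at an interview would be pd1/pd2; deaths here are
    # exact, with the density q_{s,3} evaluated at the interval-start Q
    death = iv.kind == _KIND_DEATH
    lik[death] = pa[death] * q13[death] + pb[death] * q23[death]
    cens = iv.kind == _KIND_CENSORED
    lik[cens] = pa[cens] + pb[cens]

    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(lik)


def log_likelihood(
    params: np.ndarray,
    data: pd.DataFrame | _CompiledIntervals,
    spec: ModelSpec,
    by_subject: bool = False,
):
    """Panel-data log-likelihood.

    Sums, over consecutive record pairs, ``log P_{x0,x1}`` for panel pairs,
    ``log sum_s P_{x0,s} q_{s,3}`` for exact deaths, and
    ``log sum_{s in {1,2}} P_{x0,s}`` for right-censored alive records.
    A zero-probability path yields ``-inf``.

    With ``by_subject=True`` returns an array of per-subject totals.
    """
    iv = data if isinstance(data, _CompiledIntervals) else compile_intervals(data, spec)
    contrib = _interval_log_contributions(params, spec, iv)
    if by_subject:
        out = np.zeros(iv.n_subjects)
        np.add.at(out, iv.subject_index, contrib)
        return out
    return float(contrib.sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def crude_initial_values(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Crude-rate starting values: log(#observed r->s / person-years in r).

    Panel transitions are treated as direct; zero counts are floored at a rate
    of 1e-4/year.  Covariate coefficients start at 0.
    """
    iv = compile_intervals(df, spec)
    counts = dict.fromkeys(TRANSITIONS, 0.0)
    py = {1: 0.0, 2: 0.0}
    for r, dt, kind, s in zip(iv.from_state, iv.dt, iv.kind, iv.to_state):
        py[int(r)] += dt
        if kind == _KIND_PANEL and s != r and (int(r), int(s)) in counts:
            counts[(int(r), int(s))] += 1
        elif kind == _KIND_DEATH:
            counts[(int(r), 3)] += 1
    theta = np.array(
        [
            np.log(max(counts[t] / max(py[t[0]], 1e-12), 1e-4))
            for t in TRANSITIONS
        ]
    )
    unseen = [t for t in TRANSITIONS if counts[t] == 0]
    if unseen:
        warnings.warn(f"no crude observations for transitions {unseen}")
    return np.concatenate([theta, np.zeros(spec.n_params - len(TRANSITIONS))])


def _numeric_gradient(f, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def observed_information(f_loglik, x, h=1e-4) -> np.ndarray:
    """Negative Hessian of the log-likelihood by central differences."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f_loglik(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        fp[i] = f_loglik(x + e)
        fm[i] = f_loglik(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = f_loglik(x + ei + ej)
            fmm = f_loglik(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h**2)
    return -H


def fit(
    df: pd.DataFrame,
    spec: ModelSpec | None = None,
    init: np.ndarray | None = None,
    compute_covariance: bool = True,
    max_iter: int = 500,
) -> FittedModel:
    """Maximum-likelihood fit by quasi-Newton with numeric gradients.

    The covariance matrix is the inverse of the numerically differenced
    observed information at the MLE (pseudo-inverse with a warning if
    singular).  Non-convergence raises ``RuntimeError`` carrying the
    best-so-far parameters in ``err.args[1]``.
    """
    spec = spec or ModelSpec()
    validate_panel(df, spec)
    iv = compile_intervals(df, spec)
    x0 = crude_initial_values(df, spec) if init is None else np.asarray(init, float)

    def nll(x):
        try:
            ll = log_likelihood(x, iv, spec)
        except InvalidParameterError:
            return 1e12
        return 1e12 if not np.isfinite(ll) else -ll

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6, "maxcor": 25},
    )
    grad = _numeric_gradient(nll, res.x)
    # scaled criteria: relative log-lik stationarity and gradient max-norm
    converged = bool(
        res.success and np.max(np.abs(grad)) < 1e-4 * max(1.0, abs(res.fun))
    )
    report = {
        "converged": converged,
        "iterations": int(res.nit),
        "n_evaluations": int(res.nfev),
        "gradient_max_norm": float(np.max(np.abs(grad))),
        "message": str(res.message),
        "n_subjects": iv.n_subjects,
        "n_intervals": int(len(iv.dt)),
    }
    if not converged and not res.success:
        raise RuntimeError(f"optimizer did not converge: {res.message}", res.x)

    cov = None
    if compute_covariance:
        info = observed_information(lambda x: -nll(x), res.x)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; using pseudo-inverse")
            cov = np.linalg.pinv(info)
        if np.any(np.diag(cov) < 0):
            warnings.warn(
                "observed information not positive definite at the optimum"
            )
        cov = 0.5 * (cov + cov.T)
    return FittedModel(
        spec=spec,
        params=res.x,
        covariance=cov,
        log_likelihood=-res.fun,
        convergence=report,
    )


def hazard_ratios(fitted: FittedModel) -> pd.DataFrame:
    """Hazard ratios exp(beta) with 95% Wald intervals, per transition and covariate.

    Rows are labelled by transition (disability incidence, recovery, mortality
    of non-disabled, mortality of disabled) and covariate.
    """
    spec = fitted.spec
    se = fitted.standard_errors()
    nt = len(TRANSITIONS)
    rows = []
    for k, cov in enumerate(spec.covariates):
        for t, (r, s) in enumerate(TRANSITIONS):
            j = nt * (1 + k) + t
            beta = fitted.params[j]
            rows.append(
                {
                    "transition": TRANSITION_LABELS[(r, s)],
                    "from": r,
                    "to": s,
                    "covariate": cov,
                    "hr": np.exp(beta),
                    "lo95": np.exp(beta - 1.96 * se[j]),
                    "hi95": np.exp(beta + 1.96 * se[j]),
                }
            )
    return pd.DataFrame(rows)
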