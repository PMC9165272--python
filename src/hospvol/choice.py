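"""Conditional-logit model of individual hospital choice.

Each patient ``i`` facing the open hospitals ``j`` of the region perceives a
utility that trades off travel distance against hospital quality, where
quality is proxied by last year's procedure volume (patients learn about
hospitals with a one-year information lag):

    U_ij = (beta_d + sum_k alpha_kd g_ki) d_ij + (beta_q + sum_k alpha_kq g_ki) x_{j,t-1}

with K = 5 personal characteristics g (age, sex, rurality, admission type,
comorbidity) shifting the distance and quality sensitivities.  Choice
probabilities follow McFadden's conditional logit,
``p_ij = exp(U_ij) / sum_j' exp(U_ij')``; a guarded ``literal-ratio`` mode
computes the raw ratio ``U_ij / sum U_ij'`` instead and refuses non-positive
utilities.  Predicted hospital volumes are the per-hospital sums of choice
probabilities, so they conserve the number of patients exactly.

Coefficients are estimated by maximum likelihood on long-format choice
records (one row per decision x alternative); the log-likelihood is concave
in the coefficient vector and is maximized by quasi-Newton from a zero
start, with standard errors from the observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax as _softmax

from .curves import InputError

__all__ = [
    "CHARACTERISTICS",
    "Coefficients",
    "utility",
    "utility_matrix",
    "choice_probabilities",
    "predict_volumes",
    "simulate_choices",
    "modal_choices",
    "ChoiceFit",
    "fit_coefficients",
    "adherence_rate",
]

#: The K = 5 personal characteristics interacting with distance and quality.
CHARACTERISTICS = ("age", "sex", "rurality", "admission_type", "comorbidity")


@dataclass(frozen=True)
class Coefficients:
    """Conditional-logit parameters.

    ``beta_d`` is utility per km (typically negative), ``beta_q`` utility per
    lagged intervention (typically positive); ``alpha_d``/``alpha_q`` are the
    K-vectors of characteristic interactions with distance and quality.
    """

    beta_d: float
    beta_q: float
    alpha_d: tuple[float, ...] = (0.0,) * 5
    alpha_q: tuple[float, ...] = (0.0,) * 5
    labels: tuple[str, ...] = CHARACTERISTICS

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha_d", tuple(float(a) for a in self.alpha_d))
        object.__setattr__(self, "alpha_q", tuple(float(a) for a in self.alpha_q))
        if not (len(self.alpha_d) == len(self.alpha_q) == len(self.labels)):
            raise InputError(
                "alpha_d, alpha_q and labels must share the same length K "
                f"(got {len(self.alpha_d)}, {len(self.alpha_q)}, {len(self.labels)})"
            )

    @property
    def K(self) -> int:
        return len(self.labels)

    def as_vector(self) -> np.ndarray:
        """Stack as [beta_d, beta_q, alpha_d (K), alpha_q (K)]."""
        return np.concatenate([[self.beta_d, self.beta_q], self.alpha_d, self.alpha_q])

    @classmethod
    def from_vector(cls, theta: np.ndarray, labels: tuple[str, ...] = CHARACTERISTICS) -> "Coefficients":
        K = len(labels)
        return cls(
            beta_d=float(theta[0]),
            beta_q=float(theta[1]),
            alpha_d=tuple(theta[2 : 2 + K]),
            alpha_q=tuple(theta[2 + K : 2 + 2 * K]),
            labels=labels,
        )


def _as_G(coeffs: Coefficients, patients: pd.DataFrame) -> np.ndarray:
    missing = [c for c in coeffs.labels if c not in patients.columns]
    if missing:
        raise InputError(f"patient table is missing characteristic column(s): {missing}")
    return patients[list(coeffs.labels)].to_numpy(dtype=float)


def utility(coeffs: Coefficients, g, d: float, lagged_volume: float) -> float:
    """Perceived utility of one hospital for one patient."""
    g = np.asarray(g, dtype=float)
    if g.shape != (coeffs.K,):
        raise InputError(f"characteristic vector must have length K={coeffs.K}, got shape {g.shape}")
    bd = coeffs.beta_d + float(np.dot(coeffs.alpha_d, g))
    bq = coeffs.beta_q + float(np.dot(coeffs.alpha_q, g))
    return bd * d + bq * lagged_volume


def utility_matrix(
    coeffs: Coefficients,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    lagged_volumes: pd.Series,
    open_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Patients x open-hospitals utility matrix."""
    open_ids = sorted(lagged_volumes.index) if open_ids is None else sorted(open_ids)
    if not open_ids:
        raise InputError("choice set is empty")
    missing = [h for h in open_ids if h not in distances.columns]
    if missing:
        raise InputError(f"distance matrix is missing hospital column(s): {missing}")
    missing = [h for h in open_ids if h not in lagged_volumes.index]
    if missing:
        raise InputError(f"lagged volumes missing for hospital(s): {missing}")
    G = _as_G(coeffs, patients)
    D = distances.loc[patients.index, open_ids].to_numpy(dtype=float)
    if np.any(D < 0):
        raise InputError("distances must be non-negative")
    x = lagged_volumes[open_ids].to_numpy(dtype=float)
    bd = coeffs.beta_d + G @ np.asarray(coeffs.alpha_d)
    bq = coeffs.beta_q + G @ np.asarray(coeffs.alpha_q)
    U = bd[:, None] * D + bq[:, None] * x[None, :]
    return pd.DataFrame(U, index=patients.index, columns=open_ids)


def choice_probabilities(
    coeffs: Coefficients,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    lagged_volumes: pd.Series,
    open_ids: Iterable[str] | None = None,
    mode: str = "softmax",
) -> pd.DataFrame:
    """Per-patient probabilities over the open hospitals; rows sum to 1.

    ``mode="softmax"`` (default) is the conditional-logit form with
    log-sum-exp stabilization.  ``mode="literal-ratio"`` computes the plain
    ratio ``U / sum U`` and refuses whenever any utility is non-positive.
    """
    U = utility_matrix(coeffs, patients, distances, lagged_volumes, open_ids)
    if mode == "softmax":
        P = _softmax(U.to_numpy(), axis=1)
    elif mode == "literal-ratio":
        A = U.to_numpy()
        if np.any(A <= 0):
            raise InputError(
                "literal-ratio mode requires strictly positive utilities; "
                "use mode='softmax' (the conditional-logit convention) instead"
            )
        P = A / A.sum(axis=1, keepdims=True)
    else:
        raise InputError(f"unknown probability mode {mode!r}")
    return pd.DataFrame(P, index=U.index, columns=U.columns)


def predict_volumes(
    coeffs: Coefficients,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    lagged_volumes: pd.Series,
    open_ids: Iterable[str] | None = None,
    mode: str = "softmax",
) -> pd.Series:
    """Predicted hospital volumes: per-hospital sums of choice probabilities."""
    P = choice_probabilities(coeffs, patients, distances, lagged_volumes, open_ids, mode)
    return P.sum(axis=0)


def simulate_choices(
    coeffs: Coefficients,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    lagged_volumes: pd.Series,
    open_ids: Iterable[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Draw one hospital per patient from their choice probabilities."""
    P = choice_probabilities(coeffs, patients, distances, lagged_volumes, open_ids)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(P.to_numpy(), axis=1)
    u = rng.random(len(P))
    idx = (u[:, None] > cum).sum(axis=1)
    idx = np.minimum(idx, P.shape[1] - 1)  # guard against cum[-1] = 1 - eps
    return pd.Series(np.asarray(P.columns)[idx], index=P.index, name="hospital_id")


def modal_choices(probabilities: pd.DataFrame) -> pd.Series:
    """Each patient's highest-probability hospital (deterministic)."""
    return probabilities.idxmax(axis=1)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class ChoiceFit:
    """Maximum-likelihood estimate of the choice coefficients."""

    coefficients: Coefficients
    std_errors: Coefficients
    loglik: float
    converged: bool
    n_decisions: int
    message: str = ""

    def summary(self) -> pd.DataFrame:
        names = ["beta_d", "beta_q"]
        names += [f"alpha_d[{c}]" for c in self.coefficients.labels]
        names += [f"alpha_q[{c}]" for c in self.coefficients.labels]
        est = self.coefficients.as_vector()
        se = self.std_errors.as_vector()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        return pd.DataFrame({"parameter": names, "estimate": est, "std_error": se, "z": z})


def _design(records: pd.DataFrame, labels: tuple[str, ...]):
    required = ["decision_id", "hospital_id", "chosen", "distance", "lagged_volume", *labels]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise InputError(f"choice records missing column(s): {missing}")
    df = records.sort_values(["decision_id", "hospital_id"], kind="stable").reset_index(drop=True)
    codes, _ = pd.factorize(df["decision_id"], sort=False)
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    counts = np.diff(np.r_[starts, len(df)])
    chosen = df["chosen"].to_numpy(dtype=float)
    per_group = np.add.reduceat(chosen, starts)
    if not np.allclose(per_group, 1.0):
        raise InputError("every decision must have exactly one chosen alternative")
    d = df["distance"].to_numpy(dtype=float)
    x = df["lagged_volume"].to_numpy(dtype=float)
    G = df[list(labels)].to_numpy(dtype=float)
    Z = np.column_stack([d, x, G * d[:, None], G * x[:, None]])
    return Z, chosen.astype(bool), starts, counts


def fit_coefficients(
    records: pd.DataFrame,
    labels: tuple[str, ...] = CHARACTERISTICS,
    gtol: float = 1e-8,
) -> ChoiceFit:
    """Fit the conditional logit by maximum likelihood.

    ``records`` is long format: one row per (decision, alternative) with
    columns decision_id, hospital_id, chosen (0/1), distance, lagged_volume
    and the K characteristic columns (constant within a decision).  The
    negative log-likelihood is convex; optimization starts from zero.
    Non-identified problems (no within-choice-set contrast, perfect
    separation) are flagged as non-converged rather than raising.
    """
    Z, chosen, starts, counts = _design(records, labels)
    n_par = Z.shape[1]
    n_dec = len(starts)

    if np.all(counts == 1):
        nan = tuple([np.nan] * len(labels))
        return ChoiceFit(
            coefficients=Coefficients(np.nan, np.nan, nan, nan, labels),
            std_errors=Coefficients(np.nan, np.nan, nan, nan, labels),
            loglik=0.0,
            converged=False,
            n_decisions=n_dec,
            message="non-identified: every choice set has a single alternative",
        )

    def parts(theta):
        u = Z @ theta
        gmax = np.maximum.reduceat(u, starts)
        e = np.exp(u - np.repeat(gmax, counts))
        S = np.add.reduceat(e, starts)
        p = e / np.repeat(S, counts)
        ll = float(u[chosen].sum() - (gmax + np.log(S)).sum())
        return ll, p

    def nll(theta):
        ll, _ = parts(theta)
        return -ll

    def grad(theta):
        _, p = parts(theta)
        return Z.T @ p - Z.T @ chosen

    def hess(theta):
        _, p = parts(theta)
        M = np.add.reduceat(p[:, None] * Z, starts, axis=0)
        return (Z * p[:, None]).T @ Z - M.T @ M

    # Newton trust-region on the convex NLL (analytic gradient and Hessian),
    # zero start; convergence judged on the gradient norm directly
    res = minimize(
        nll, np.zeros(n_par), jac=grad, hess=hess, method="trust-exact",
        options={"gtol": gtol, "maxiter": 200},
    )
    theta = res.x
    ll, p = parts(theta)
    grad_ok = bool(np.max(np.abs(grad(theta))) <= 1e3 * gtol * max(1.0, abs(ll)))

    # observed information at the optimum
    M = np.add.reduceat(p[:, None] * Z, starts, axis=0)
    H = (Z * p[:, None]).T @ Z - M.T @ M
    se = np.full(n_par, np.nan)
    identified = True
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            identified = False
        else:
            se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        identified = False

    converged = (bool(res.success) or grad_ok) and identified and float(np.max(np.abs(theta))) < 1e3
    if converged:
        message = ""
    elif not identified:
        message = "non-identified or separated data"
    else:
        message = str(res.message)
    return ChoiceFit(
        coefficients=Coefficients.from_vector(theta, labels),
        std_errors=Coefficients.from_vector(se, labels),
        loglik=ll,
        converged=converged,
        n_decisions=n_dec,
        message=message,
    )


def adherence_rate(
    chosen: pd.Series,
    patient_provinces: pd.Series,
    planned_sets: Mapping[str, Iterable[str]],
) -> float:
    """Fraction of patients choosing outside their province's planned set.

    ``chosen`` maps patient -> hospital id (a simulated draw or the modal
    predicted choice); ``planned_sets`` maps province -> hospitals the policy
    maker intends that province's patients to use.  Patients from provinces
    with no planned hospital necessarily diverge.
    """
    planned = {n: set(h) for n, h in planned_sets.items()}
    diverged = 0
    for pid, hosp in chosen.items():
        prov = patient_provinces.loc[pid]
        if hosp not in planned.get(prov, set()):
            diverged += 1
    return diverged / len(chosen) if len(chosen) else 0.0
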