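"""GAMLSS reference models and the informatics-consult engine.

Fits a distributional regression over time since cohort index: each
distribution parameter of a SHASH or Logistic family gets its own
predictor, with location and (log-)scale smoothed by penalized cubic
B-splines (P-splines: order-d difference penalty on adjacent coefficients)
and the SHASH shape parameters held constant.  The fit maximizes the
penalized log-likelihood

    sum_i log f(y_i; theta(t_i))  -  1/2 * sum_theta lambda_theta ||D_d beta_theta||^2

jointly over all coefficients by L-BFGS-B with analytic gradients — a
deterministic fit with no randomized initialization.  Smoothing parameters
are either fixed or chosen by a GAIC grid search (penalty 2, i.e. AIC)
with effective dimensions from the penalized/unpenalized Hessian pair.

An individual patient is scored against a fitted reference model through
the family CDF: centile = F(value; theta(t)) and z = Phi^-1(centile) —
for the SHASH family this is exactly the sinh-arcsinh r-transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

from .cohort import Cohort
from .data_model import Dataset
from .shash import ShashParams, shash_cdf, shash_quantile

_DEGREE = 3  # cubic B-splines
MIN_SHASH_OBS = 50

FAMILIES = ("SHASH", "Logistic")


@dataclass(frozen=True)
class SmoothSpec:
    """P-spline configuration for the location and log-scale smooths.

    ``lambda_mu`` / ``lambda_sigma`` are either nonnegative reals or
    ``"select"`` (GAIC grid search over ``lambda_grid``).
    """

    n_basis: int = 20
    penalty_order: int = 2
    lambda_mu: float | Literal["select"] = "select"
    lambda_sigma: float | Literal["select"] = "select"
    lambda_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)

    def __post_init__(self) -> None:
        if self.n_basis < self.penalty_order + 1:
            raise ValueError("n_basis must be at least penalty_order + 1")
        for lam in (self.lambda_mu, self.lambda_sigma):
            if lam != "select" and (not np.isfinite(lam) or lam < 0):
                raise ValueError("lambda must be nonnegative or 'select'")


def _knots(t_min: float, t_max: float, n_basis: int) -> np.ndarray:
    """Clamped knot vector giving exactly ``n_basis`` cubic basis functions."""
    n_break = n_basis - _DEGREE + 1
    breaks = np.linspace(t_min, t_max, n_break)
    return np.concatenate(
        [np.repeat(t_min, _DEGREE), breaks, np.repeat(t_max, _DEGREE)]
    )


def _design(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    t = np.clip(np.asarray(t, dtype=float), knots[0], knots[-1])
    return BSpline.design_matrix(t, knots, _DEGREE, extrapolate=False).toarray()


def _diff_penalty(n_basis: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# family log-likelihoods with analytic parameter gradients

def _shash_ll_grads(y, mu, sigma, nu, tau):
    z = (y - mu) / sigma
    sa = np.arcsinh(z)
    u = np.clip(tau * sa - nu, -300.0, 300.0)
    r, ch = np.sinh(u), np.cosh(u)
    ll = (
        -0.5 * r**2
        - 0.5 * np.log(2 * np.pi)
        + (np.abs(u) + np.log1p(np.exp(-2 * np.abs(u))) - np.log(2.0))
        + np.log(tau) - np.log(sigma) - 0.5 * np.log1p(z**2)
    )
    dl_du = -r * ch + np.tanh(u)
    dl_dz = dl_du * tau / np.sqrt(1 + z**2) - z / (1 + z**2)
    return {
        "ll": ll,
        "d_mu": -dl_dz / sigma,
        "d_logsigma": -z * dl_dz - 1.0,
        "d_nu": -dl_du,
        "d_logtau": tau * (dl_du * sa) + 1.0,
    }


def _logistic_ll_grads(y, mu, s):
    z = np.clip((y - mu) / s, -300.0, 300.0)
    ll = -z - np.log(s) - 2.0 * np.logaddexp(0.0, -z)
    dl_dz = -1.0 + 2.0 / (1.0 + np.exp(z))
    return {
        "ll": ll,
        "d_mu": -dl_dz / s,
        "d_logsigma": -z * dl_dz - 1.0,
        "d_nu": None,
        "d_logtau": None,
    }


# ---------------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """Fitted distributional reference model over time since index."""

    family: str
    knots: np.ndarray
    penalty_order: int
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    nu: float = 0.0
    log_tau: float = 0.0
    lambda_mu: float = 0.0
    lambda_sigma: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def t_domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def in_domain(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        lo, hi = self.t_domain
        return (t >= lo) & (t <= hi)

    def params_at(self, times) -> pd.DataFrame:
        """mu(t), sigma(t) (and shape) with times clamped to the fit domain."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        B = _design(t, self.knots)
        out = pd.DataFrame({
            "time": t,
            "mu": B @ self.beta_mu,
            "sigma": np.exp(B @ self.beta_sigma),
            "extrapolated": ~self.in_domain(t),
        })
        if self.family == "SHASH":
            out["nu"] = self.nu
            out["tau"] = float(np.exp(self.log_tau))
        return out

    def cdf(self, value, time) -> np.ndarray:
        p = self.params_at(time)
        if self.family == "SHASH":
            return np.array([
                shash_cdf(v, ShashParams(m, s, self.nu, float(np.exp(self.log_tau))))
                for v, m, s in zip(np.atleast_1d(value), p["mu"], p["sigma"])
            ])
        return stats.logistic.cdf(np.atleast_1d(value), loc=p["mu"], scale=p["sigma"])

    def quantile(self, prob: float, time) -> np.ndarray:
        p = self.params_at(time)
        if self.family == "SHASH":
            return np.array([
                shash_quantile(prob, ShashParams(m, s, self.nu, float(np.exp(self.log_tau))))
                for m, s in zip(p["mu"], p["sigma"])
            ])
        return stats.logistic.ppf(prob, loc=p["mu"], scale=p["sigma"])

    # -- persistence ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "knots": list(self.knots),
            "penalty_order": self.penalty_order,
            "beta_mu": list(self.beta_mu),
            "beta_sigma": list(self.beta_sigma),
            "nu": self.nu,
            "log_tau": self.log_tau,
            "lambda_mu": self.lambda_mu,
            "lambda_sigma": self.lambda_sigma,
            "diagnostics": self.diagnostics,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceModel":
        d = json.loads(text)
        return cls(
            family=d["family"], knots=np.array(d["knots"]),
            penalty_order=d["penalty_order"],
            beta_mu=np.array(d["beta_mu"]), beta_sigma=np.array(d["beta_sigma"]),
            nu=d["nu"], log_tau=d["log_tau"],
            lambda_mu=d["lambda_mu"], lambda_sigma=d["lambda_sigma"],
            diagnostics=d["diagnostics"],
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        return cls.from_json(Path(path).read_text())


def _fit_once(y, B, P, lam_mu, lam_sigma, family, theta0):
    nb = B.shape[1]
    has_shape = family == "SHASH"

    def unpack(theta):
        bm, bs = theta[:nb], theta[nb:2 * nb]
        nu = theta[2 * nb] if has_shape else 0.0
        lt = theta[2 * nb + 1] if has_shape else 0.0
        return bm, bs, nu, lt

    def objective(theta):
        bm, bs, nu, lt = unpack(theta)
        mu = B @ bm
        sigma = np.exp(np.clip(B @ bs, -30.0, 30.0))
        if has_shape:
            g = _shash_ll_grads(y, mu, sigma, nu, np.exp(np.clip(lt, -5.0, 5.0)))
        else:
            g = _logistic_ll_grads(y, mu, sigma)
        nll = -np.sum(g["ll"]) + 0.5 * lam_mu * bm @ P @ bm + 0.5 * lam_sigma * bs @ P @ bs
        grad = np.empty_like(theta)
        grad[:nb] = -B.T @ g["d_mu"] + lam_mu * (P @ bm)
        grad[nb:2 * nb] = -B.T @ g["d_logsigma"] + lam_sigma * (P @ bs)
        if has_shape:
            grad[2 * nb] = -np.sum(g["d_nu"])
            grad[2 * nb + 1] = -np.sum(g["d_logtau"])
        if not np.isfinite(nll):
            return 1e300, np.zeros_like(theta)
        return nll, grad

    bounds = [(None, None)] * nb + [(-30.0, 30.0)] * nb
    if has_shape:
        bounds += [(-10.0, 10.0), (-5.0, 5.0)]
    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res, objective


def _edf_and_gaic(res, objective, P, lam_mu, lam_sigma, nb, has_shape, y_n):
    """Effective dimension tr(H_pen^-1 H_unpen) and GAIC = -2 ll + 2 edf."""
    theta = res.x
    p = len(theta)
    g0 = objective(theta)[1]
    H = np.empty((p, p))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(p):
        tj = theta.copy()
        tj[j] += h[j]
        H[:, j] = (objective(tj)[1] - g0) / h[j]
    H = 0.5 * (H + H.T)
    Pfull = np.zeros((p, p))
    Pfull[:nb, :nb] = lam_mu * P
    Pfull[nb:2 * nb, nb:2 * nb] = lam_sigma * P
    try:
        Hi = np.linalg.solve(H + 1e-8 * np.eye(p), H - Pfull)
        edf = float(np.trace(Hi))
    except np.linalg.LinAlgError:
        edf = float(p)
    edf = float(np.clip(edf, 1.0, p))
    # unpenalized log-likelihood at the optimum
    pen = 0.5 * lam_mu * theta[:nb] @ P @ theta[:nb] + 0.5 * lam_sigma * theta[nb:2 * nb] @ P @ theta[nb:2 * nb]
    ll = -(res.fun - pen)
    return edf, float(-2.0 * ll + 2.0 * edf), float(ll)


def fit_reference_model(
    times,
    values,
    family: str = "SHASH",
    smooth: SmoothSpec | None = None,
) -> ReferenceModel:
    """Fit the penalized-likelihood reference model.

    Deterministic given identical inputs and settings; observation order
    does not matter.  The SHASH family needs at least ``MIN_SHASH_OBS``
    observations to identify its shape parameters — with fewer, request the
    Logistic family.  Non-convergence is reported in the diagnostics, not
    raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; valid: {FAMILIES}")
    smooth = smooth or SmoothSpec()
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-d sequences")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("times and values must be finite")
    order = np.argsort(t, kind="mergesort")  # order-invariant fit
    t, y = t[order], y[order]
    n = len(y)
    if family == "SHASH" and n < MIN_SHASH_OBS:
        raise ValueError(
            f"SHASH needs >= {MIN_SHASH_OBS} observations to identify skewness and "
            f"tail weight (got {n}); use family='Logistic' for sparse series"
        )
    if n < smooth.n_basis:
        raise ValueError(
            f"fewer observations ({n}) than basis functions ({smooth.n_basis})"
        )

    t_min, t_max = float(t.min()), float(t.max())
    if t_max <= t_min:
        t_max = t_min + 1.0
    knots = _knots(t_min, t_max, smooth.n_basis)
    B = _design(t, knots)
    P = _diff_penalty(smooth.n_basis, smooth.penalty_order)
    nb = smooth.n_basis
    has_shape = family == "SHASH"

    grid_mu = smooth.lambda_grid if smooth.lambda_mu == "select" else (float(smooth.lambda_mu),)
    grid_sigma = smooth.lambda_grid if smooth.lambda_sigma == "select" else (float(smooth.lambda_sigma),)

    # deterministic initialization: penalized LS for mu, constant log-scale
    ridge = B.T @ B + 10.0 * P + 1e-8 * np.eye(nb)
    bm0 = np.linalg.solve(ridge, B.T @ y)
    resid_sd = max(float(np.std(y - B @ bm0)), 1e-6)
    bs0 = np.full(nb, np.log(resid_sd))
    theta0 = np.concatenate([bm0, bs0, [0.0, 0.0]]) if has_shape else np.concatenate([bm0, bs0])

    best = None
    for lam_mu in grid_mu:
        for lam_sigma in grid_sigma:
            res, obj = _fit_once(y, B, P, lam_mu, lam_sigma, family, theta0)
            edf, gaic, ll = _edf_and_gaic(res, obj, P, lam_mu, lam_sigma, nb, has_shape, n)
            if best is None or gaic < best["gaic"] - 1e-9:
                best = {"res": res, "lam_mu": lam_mu, "lam_sigma": lam_sigma,
                        "edf": edf, "gaic": gaic, "ll": ll}

    res = best["res"]
    theta = res.x
    return ReferenceModel(
        family=family,
        knots=knots,
        penalty_order=smooth.penalty_order,
        beta_mu=theta[:nb],
        beta_sigma=theta[nb:2 * nb],
        nu=float(theta[2 * nb]) if has_shape else 0.0,
        log_tau=float(np.clip(theta[2 * nb + 1], -5.0, 5.0)) if has_shape else 0.0,
        lambda_mu=best["lam_mu"],
        lambda_sigma=best["lam_sigma"],
        diagnostics={
            "converged": bool(res.success),
            "n_obs": n,
            "log_likelihood": best["ll"],
            "penalized_objective": float(res.fun),
            "edf": best["edf"],
            "gaic": best["gaic"],
            "optimizer_message": str(res.message),
        },
    )


def predict_centiles(model: ReferenceModel, times, centiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Centile curves on a time grid; strictly increasing in the centile at
    every t.  Times outside the fitted domain are evaluated at the boundary
    and flagged ``extrapolated``."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    out = pd.DataFrame({"time": t, "extrapolated": ~model.in_domain(t)})
    for c in centiles:
        if not (0 < c < 1):
            raise ValueError(f"centile {c} outside (0, 1)")
        out[f"c{c:g}"] = model.quantile(c, t)
    return out


@dataclass(frozen=True)
class ZScore:
    z: float
    centile: float
    extrapolated: bool = False


def zscore(model: ReferenceModel, time: float, value: float) -> ZScore:
    """Place one observation against the model: centile = F(value; theta(t)),
    z = probit(centile).  For SHASH, z is the sinh-arcsinh r-transform."""
    centile = float(np.clip(model.cdf([value], [time])[0], 1e-12, 1 - 1e-12))
    return ZScore(
        z=float(stats.norm.ppf(centile)),
        centile=centile,
        extrapolated=not bool(model.in_domain(time)),
    )


# ---------------------------------------------------------------------------
# the informatics consult

@dataclass
class ConsultReport:
    """Everything needed to render a single-patient consult.

    ``patient_scores`` has one row per in-window patient observation with
    its z-score/centile against the comparator model; ``overlay`` carries
    both cohorts' raw observations for the raw-values panel.
    """

    observation_code: str
    window_days: tuple[float, float]
    reference: ReferenceModel
    patient_model: ReferenceModel | None
    patient_scores: pd.DataFrame
    overlay: pd.DataFrame  # columns: cohort, patient_id, time, value
    reference_n_obs: int

    def to_json(self) -> str:
        return json.dumps({
            "observation_code": self.observation_code,
            "window_days": list(self.window_days),
            "reference_model": json.loads(self.reference.to_json()),
            "patient_model": (
                json.loads(self.patient_model.to_json()) if self.patient_model else None
            ),
            "patient_scores": self.patient_scores.to_dict(orient="records"),
            "reference_n_obs": self.reference_n_obs,
        }, indent=2)


def _observations_since_index(dataset: Dataset, cohort: Cohort, code: str,
                              window: tuple[float, float]) -> pd.DataFrame:
    obs = dataset.events_for("observation")
    obs = obs[obs["code"] == code]
    idx = cohort.members.set_index("patient_id")["index_date"]
    obs = obs[obs["patient_id"].isin(idx.index)].copy()
    obs["time"] = (obs["event_date"] - obs["patient_id"].map(idx)).dt.days.astype(float)
    obs = obs[(obs["time"] >= window[0]) & (obs["time"] <= window[1])]
    return obs[["patient_id", "time", "value"]].reset_index(drop=True)


def consult(
    dataset: Dataset,
    patient: Cohort,
    comparator: Cohort,
    observation_code: str,
    families: tuple[str, str] = ("SHASH", "Logistic"),
    smooth: SmoothSpec | None = None,
    window: tuple[float, float] = (7.0, 730.0),
) -> ConsultReport:
    """Compare one patient's longitudinal observation values against a
    comparator cohort.

    The comparator's in-window observations are fitted with the first
    family (SHASH by default); the patient's own trajectory with the second
    (Logistic, suited to a short noisy single-patient series).  Each patient
    observation is then scored via the comparator model's CDF.
    """
    if len(patient) != 1:
        raise ValueError(f"patient cohort must contain exactly 1 member, got {len(patient)}")
    code = observation_code.upper().replace(".", "")
    ref_obs = _observations_since_index(dataset, comparator, code, window)
    pat_obs = _observations_since_index(dataset, patient, code, window)
    if not len(pat_obs):
        raise ValueError(
            f"patient has no {code} observations in the window "
            f"{window[0]:g}-{window[1]:g} days post-index"
        )
    if not len(ref_obs):
        raise ValueError(f"comparator cohort has no {code} observations in the window")

    smooth = smooth or SmoothSpec()
    reference = fit_reference_model(ref_obs["time"], ref_obs["value"], families[0], smooth)

    patient_model = None
    n_pat = len(pat_obs)
    nb_pat = min(smooth.n_basis, max(smooth.penalty_order + 2, n_pat - 1))
    if n_pat > smooth.penalty_order + 2:
        pat_smooth = SmoothSpec(
            n_basis=nb_pat, penalty_order=smooth.penalty_order,
            lambda_mu=smooth.lambda_mu, lambda_sigma=smooth.lambda_sigma,
            lambda_grid=smooth.lambda_grid,
        )
        patient_model = fit_reference_model(
            pat_obs["time"], pat_obs["value"], families[1], pat_smooth
        )

    scores = []
    for _, row in pat_obs.iterrows():
        zs = zscore(reference, row["time"], row["value"])
        scores.append({"time": row["time"], "value": row["value"],
                       "z": zs.z, "centile": zs.centile, "extrapolated": zs.extrapolated})
    overlay = pd.concat([
        ref_obs.assign(cohort=comparator.name),
        pat_obs.assign(cohort=patient.name),
    ], ignore_index=True)[["cohort", "patient_id", "time", "value"]]

    return ConsultReport(
        observation_code=code,
        window_days=window,
        reference=reference,
        patient_model=patient_model,
        patient_scores=pd.DataFrame(scores),
        overlay=overlay,
        reference_n_obs=len(ref_obs),
    )


__all__ = [
    "SmoothSpec",
    "ReferenceModel",
    "fit_reference_model",
    "predict_centiles",
    "ZScore",
    "zscore",
    "ConsultReport",
    "consult",
    "FAMILIES",
    "MIN_SHASH_OBS",
]
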