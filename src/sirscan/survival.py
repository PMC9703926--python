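"""Discrete-time survival model (cloglog link) and standardized incidence ratios.

The person-period records y_jt are Bernoulli with

    log(-log(1 - lambda_jt)) = log d_jt + alpha + sum_k beta_k x_jtk ,

i.e. a binomial GLM with complementary log-log link and offset log d_jt; the
offset makes the model a constant-hazard (exponential) survival model with
person-years d_jt, and exp(beta_k) is the hazard ratio for a one-unit
increase in covariate k. Per-region expected counts e_i are sums of fitted
probabilities, and SIR_i = o_i / e_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    InvalidArgumentError,
    NoEventsError,
    SchemaError,
    SingularDesignError,
)
from .regions import RegionSet

__all__ = [
    "DEFAULT_COVARIATES",
    "SurvivalFit",
    "RegionTable",
    "fit_cloglog",
    "predict_hazard",
    "compute_sir",
]

DEFAULT_COVARIATES = ("sex", "log_age", "log_bmi", "round3")


@dataclass
class SurvivalFit:
    """Maximum-likelihood fit of the cloglog discrete survival model."""

    labels: list[str]  # "alpha" then covariate names
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    converged: bool
    grad_norm: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def hazard_ratios(self) -> pd.DataFrame:
        """exp(coef) with 95% Wald CIs and two-sided normal p-values."""
        from scipy.stats import norm

        se = self.se
        z = self.coef / se
        with np.errstate(over="ignore"):
            return pd.DataFrame(
                {
                    "term": self.labels,
                    "coef": self.coef,
                    "se": se,
                    "hr": np.exp(self.coef),
                    "hr_lo": np.exp(self.coef - 1.96 * se),
                    "hr_hi": np.exp(self.coef + 1.96 * se),
                    "p": 2 * norm.sf(np.abs(z)),
                }
            )

    def to_dict(self) -> dict:
        hr = self.hazard_ratios()
        return {
            "terms": hr.to_dict(orient="records"),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _design(pseudo_obs: pd.DataFrame, covariates) -> np.ndarray:
    missing = [c for c in covariates if c not in pseudo_obs.columns]
    if missing:
        raise SchemaError(f"missing covariate column(s): {missing}")
    X = np.column_stack(
        [np.ones(len(pseudo_obs))]
        + [pseudo_obs[c].to_numpy(dtype=float) for c in covariates]
    )
    return X


def _cloglog_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                    logd: np.ndarray) -> float:
    """Direct Bernoulli log-likelihood at the given coefficients."""
    eta = logd + X @ beta
    lam = -np.expm1(-np.exp(eta))
    lam = np.clip(lam, 1e-300, 1 - 1e-16)
    return float(y @ np.log(lam) + (1 - y) @ np.log1p(-lam))


def fit_cloglog(
    pseudo_obs: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> SurvivalFit:
    """Fit the binomial GLM with cloglog link and offset log d.

    Raises :class:`NoEventsError` with zero cases, and
    :class:`SingularDesignError` when the design matrix is rank deficient.
    Non-convergence or quasi-separation is flagged on the returned fit.
    """
    y = pseudo_obs["y"].to_numpy(dtype=float)
    d = pseudo_obs["d"].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise InvalidArgumentError("intervals d must be positive")
    if y.sum() == 0:
        raise NoEventsError("no diagnosed cases in the person-period table")
    X = _design(pseudo_obs, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")

    logd = np.log(d)
    # closed-form starting intercept: lambda-bar = event rate at unit interval
    start = np.zeros(X.shape[1])
    start[0] = np.log(-np.log1p(-y.mean())) - logd.mean()

    model = sm.GLM(
        y, X, family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=logd,
    )
    res = model.fit(start_params=start, maxiter=200, tol=1e-10)

    # Newton polishing with step-halving so the score equations hold tightly
    params = np.asarray(res.params, dtype=float)
    ll = _cloglog_loglik(params, X, y, logd)
    for _ in range(25):
        grad = model.score(params)
        if np.linalg.norm(grad) < 1e-9:
            break
        H = model.hessian(params)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = params - scale * step
            ll_cand = _cloglog_loglik(cand, X, y, logd)
            if ll_cand >= ll - 1e-12:
                params, ll = cand, ll_cand
                break
            scale /= 2.0
        else:
            break

    loglik = _cloglog_loglik(params, X, y, logd)
    grad = model.score(params)
    grad_norm = float(np.linalg.norm(grad))
    k = X.shape[1]
    labels = ["alpha"] + list(covariates)
    cov = np.linalg.inv(-model.hessian(params))
    return SurvivalFit(
        labels=labels,
        coef=params,
        cov=cov,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        converged=bool(res.converged) and grad_norm < 1e-4 * max(1.0, abs(loglik)),
        grad_norm=grad_norm,
    )


def predict_hazard(fit: SurvivalFit, pseudo_obs: pd.DataFrame) -> np.ndarray:
    """Fitted per-record diagnosis probabilities lambda-hat in (0, 1)."""
    covariates = fit.labels[1:]
    X = _design(pseudo_obs, covariates)
    eta = np.log(pseudo_obs["d"].to_numpy(dtype=float)) + X @ fit.coef
    lam = -np.expm1(-np.exp(eta))
    return np.clip(lam, np.finfo(float).tiny, 1 - 1e-16)


@dataclass
class RegionTable:
    """Per-region observed/expected cases, SIRs, and geometry for spatial tests."""

    table: pd.DataFrame  # region_id, observed, expected, sir
    centroids: np.ndarray  # (n, 2) km, aligned with table rows
    adjacency: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def observed(self) -> np.ndarray:
        return self.table["observed"].to_numpy(dtype=float)

    @property
    def expected(self) -> np.ndarray:
        return self.table["expected"].to_numpy(dtype=float)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy(dtype=int)

    def distance_matrix(self) -> np.ndarray:
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((d**2).sum(axis=2))

    def analysed(self) -> "RegionTable":
        """Drop regions with zero expected count (no analysable records)."""
        keep = self.expected > 0
        if keep.all():
            return self
        kept_ids = set(self.table.loc[keep, "region_id"].astype(int))
        adj = {
            r: tuple(n for n in nbrs if n in kept_ids)
            for r, nbrs in self.adjacency.items()
            if r in kept_ids
        }
        return RegionTable(
            table=self.table.loc[keep].reset_index(drop=True),
            centroids=self.centroids[keep],
            adjacency=adj,
        )

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out["x_km"] = self.centroids[:, 0]
        out["y_km"] = self.centroids[:, 1]
        out.to_csv(path, index=False)


def compute_sir(
    pseudo_obs: pd.DataFrame,
    lam_hat: np.ndarray,
    regions: RegionSet,
) -> RegionTable:
    """Aggregate fitted hazards into per-region o_i, e_i and SIR_i = o_i/e_i.

    e_i is the sum of lambda-hat over the region's person-period records and
    o_i the sum of observed cases; regions without records are reported with
    e = 0 (and are excluded from spatial tests downstream).
    """
    df = pd.DataFrame(
        {
            "region_id": pseudo_obs["region_id"].to_numpy(),
            "y": pseudo_obs["y"].to_numpy(dtype=float),
            "lam": np.asarray(lam_hat, dtype=float),
        }
    )
    agg = df.groupby("region_id").agg(observed=("y", "sum"), expected=("lam", "sum"))
    table = pd.DataFrame({"region_id": regions.region_ids})
    table = table.merge(agg, on="region_id", how="left").fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sir = np.where(
            table["expected"] > 0, table["observed"] / table["expected"], np.nan
        )
    table["sir"] = sir
    return RegionTable(
        table=table,
        centroids=regions.centroids.copy(),
        adjacency=dict(regions.adjacency),
    )
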