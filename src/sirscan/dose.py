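"""Dose-group models: scenario aggregation, grouping, Poisson regression.

Municipal thyroid absorbed doses (mGy, first year) come as several
evacuation-scenario estimates per municipality; the representative dose is an
order statistic (median by default) over equally weighted scenarios. Regions
are then classed into four dose groups — lowest [0, 2.0), middle-low
[2.0, 5.0), middle-high [5.0, 10.0) and highest [10.0, inf) mGy — and the
ecological model

    o_i ~ Poisson(r_i e_i),   ln(r_i) = sum_k beta_k z_ki

(no intercept, exhaustive group dummies, offset log e_i) estimates each
group's relative risk exp(beta_k) = group SIR. A separate intercept-plus-
ordinal-score model provides a Wald trend test, and the same group dummies
can enter the individual-level discrete survival model as a sensitivity
analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from scipy.special import gammaln

from .errors import InvalidArgumentError, MissingDataError
from .survival import DEFAULT_COVARIATES, SurvivalFit, fit_cloglog

__all__ = [
    "DOSE_GROUP_LABELS",
    "DOSE_CUTPOINTS_MGY",
    "GroupRRResult",
    "aggregate_scenario_dose",
    "assign_groups",
    "fit_group_poisson",
    "fit_individual_dose_model",
]

DOSE_GROUP_LABELS = ("lowest", "middle-low", "middle-high", "highest")
DOSE_CUTPOINTS_MGY = (2.0, 5.0, 10.0)


def aggregate_scenario_dose(
    scenarios: pd.DataFrame, method: str = "median"
) -> pd.DataFrame:
    """Collapse per-region scenario doses to one representative dose.

    ``scenarios`` has columns ``region_id, dose_mGy`` (one row per scenario,
    scenarios equally weighted); ``method`` is the order statistic to take —
    median (midpoint of the central pair for even counts), min or max.
    """
    if method not in ("median", "min", "max"):
        raise InvalidArgumentError(f"unknown aggregation method {method!r}")
    if scenarios.empty:
        raise MissingDataError("no scenario doses supplied")
    if scenarios["dose_mGy"].isna().any():
        raise MissingDataError("scenario doses contain missing values")
    agg = scenarios.groupby("region_id")["dose_mGy"].agg(method)
    return agg.rename("dose_mGy").reset_index()


def assign_groups(representative: pd.DataFrame) -> pd.DataFrame:
    """Assign each region to a dose group by the half-open mGy cutpoints.

    Input has columns ``region_id, dose_mGy``; output adds ``group`` (label),
    ``group_index`` (0-3) and the four 0/1 dummies ``z_lowest`` ...
    ``z_highest`` (exactly one per region).
    """
    dose = representative["dose_mGy"].to_numpy(dtype=float)
    if np.any(dose < 0):
        raise InvalidArgumentError("doses must be nonnegative")
    idx = np.digitize(dose, DOSE_CUTPOINTS_MGY, right=False)
    out = representative.copy()
    out["group_index"] = idx
    out["group"] = [DOSE_GROUP_LABELS[i] for i in idx]
    for k, label in enumerate(DOSE_GROUP_LABELS):
        out[f"z_{label.replace('-', '_')}"] = (idx == k).astype(int)
    return out


@dataclass
class GroupRRResult:
    """Relative risks per dose group with AIC comparison and trend test."""

    table: pd.DataFrame  # group, observed, expected, rr, rr_lo, rr_hi, p
    loglik: float
    aic: float
    null_aic: float
    trend_coef: float
    trend_p: float

    def to_dict(self) -> dict:
        return {
            "groups": self.table.to_dict(orient="records"),
            "loglik": self.loglik,
            "aic": self.aic,
            "null_aic": self.null_aic,
            "delta_aic_vs_null": self.aic - self.null_aic,
            "trend_coef": self.trend_coef,
            "trend_p": self.trend_p,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _poisson_loglik(o: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(o * np.log(mu) - mu - gammaln(o + 1)))


def fit_group_poisson(region_groups: pd.DataFrame) -> GroupRRResult:
    """Fit the no-intercept dose-group Poisson model with offset log e.

    ``region_groups`` carries ``observed, expected, group_index`` per region
    (expected > 0). With exhaustive dummies the MLE is closed-form — each
    group's relative risk is its pooled observed/expected ratio — but the
    model is fitted as a GLM to get Wald intervals and p-values. Groups with
    no regions (or zero cases) are reported as undefined. The trend test is
    a Wald test on an ordinal score (1-4) in a separate intercept model; the
    null model fixes every r_i = 1 (zero parameters).
    """
    df = region_groups
    e = df["expected"].to_numpy(dtype=float)
    o = df["observed"].to_numpy(dtype=float)
    if np.any(e <= 0):
        raise InvalidArgumentError("all regions must have expected > 0")
    gidx = df["group_index"].to_numpy(dtype=int)

    rows = []
    present = []
    for k, label in enumerate(DOSE_GROUP_LABELS):
        mask = gidx == k
        ok_sum, ek_sum = float(o[mask].sum()), float(e[mask].sum())
        defined = mask.any() and ok_sum > 0
        rows.append(
            {"group": label, "n_regions": int(mask.sum()),
             "observed": ok_sum, "expected": ek_sum, "defined": defined}
        )
        if defined:
            present.append(k)
    if not present:
        raise InvalidArgumentError("no dose group has observed cases")

    Z = np.column_stack([(gidx == k).astype(float) for k in present])
    keep = Z.sum(axis=1) > 0  # regions in degenerate (case-free) groups drop out
    model = sm.GLM(
        o[keep], Z[keep], family=sm.families.Poisson(), offset=np.log(e[keep])
    )
    res = model.fit()
    se = np.sqrt(np.diag(res.cov_params()))
    zstat = res.params / se
    for pos, k in enumerate(present):
        rows[k].update(
            rr=float(np.exp(res.params[pos])),
            rr_lo=float(np.exp(res.params[pos] - 1.96 * se[pos])),
            rr_hi=float(np.exp(res.params[pos] + 1.96 * se[pos])),
            p=float(2 * norm.sf(abs(zstat[pos]))),
        )
    for k in range(4):
        rows[k].setdefault("rr", np.nan)
        rows[k].setdefault("rr_lo", np.nan)
        rows[k].setdefault("rr_hi", np.nan)
        rows[k].setdefault("p", np.nan)

    # regions dropped from the fit (case-free groups) contribute rr = o/e = 0
    # degenerately; score them at r = 1 in the fitted loglik for comparability
    loglik = _poisson_loglik(o[keep], e[keep] * np.exp(Z[keep] @ res.params))
    loglik += _poisson_loglik(o[~keep], e[~keep]) if (~keep).any() else 0.0
    k_params = len(present)
    aic = 2 * k_params - 2 * loglik
    null_aic = -2 * _poisson_loglik(o, e)

    # trend: intercept + ordinal score 1..4, Wald test on the score
    score = (gidx + 1).astype(float)
    Xt = np.column_stack([np.ones_like(score), score])
    trend_res = sm.GLM(
        o, Xt, family=sm.families.Poisson(), offset=np.log(e)
    ).fit()
    t_se = np.sqrt(trend_res.cov_params()[1, 1])
    trend_coef = float(trend_res.params[1])
    trend_p = float(2 * norm.sf(abs(trend_coef / t_se)))

    return GroupRRResult(
        table=pd.DataFrame(rows),
        loglik=loglik,
        aic=aic,
        null_aic=null_aic,
        trend_coef=trend_coef,
        trend_p=trend_p,
    )


def fit_individual_dose_model(
    pseudo_obs: pd.DataFrame,
    groups: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> SurvivalFit:
    """Individual-level sensitivity model: cloglog survival + group dummies.

    Merges the region dose groups onto the person-period table and adds three
    dummies (lowest group as reference) to the survival covariates; contract
    identical to :func:`sirscan.survival.fit_cloglog`.
    """
    merged = pseudo_obs.merge(
        groups[["region_id", "group_index"]], on="region_id", how="left"
    )
    if merged["group_index"].isna().any():
        missing = sorted(
            set(merged.loc[merged["group_index"].isna(), "region_id"].astype(int))
        )
        raise MissingDataError(f"regions without dose group: {missing[:10]}")
    dose_cols = []
    for k, label in enumerate(DOSE_GROUP_LABELS[1:], start=1):
        col = f"dose_{label.replace('-', '_')}"
        merged[col] = (merged["group_index"] == k).astype(float)
        dose_cols.append(col)
    return fit_cloglog(merged, tuple(covariates) + tuple(dose_cols))
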