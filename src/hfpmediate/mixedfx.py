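"""Random-intercept linear models for total intervention effects.

One model per indicator (outcome or mediator): the indicator regressed on
treatment (plus the indicator's own baseline measure where available), with
a settlement-level random intercept absorbing within-cluster correlation.
Estimation uses statsmodels' MixedLM; maximum likelihood is the default so
log-likelihoods are comparable across fixed-effect specifications (REML by
flag).  Wald 95% confidence intervals, beta +/- 1.96 se.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RandomInterceptFit", "fit_random_intercept", "total_effects_table"]

Z975 = 1.959963984540054

#: per-indicator baseline adjustment used in the total-effect models
DEFAULT_ADJUSTMENTS = {
    "dds_mean": ["dds_baseline"],
    "mdd_prop": ["dds_baseline"],
    "crop_richness": ["crop_richness_baseline"],
    "market_score": ["market_score_baseline"],
}


@dataclass
class RandomInterceptFit:
    """Fixed effects and variance components of a random-intercept model."""

    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame          # columns lo, hi (Wald)
    sigma_u2: float                 # cluster-intercept variance
    sigma_e2: float                 # residual variance
    loglik: float
    n: int
    n_clusters: int
    boundary: bool                  # sigma_u2 at (or within tolerance of) zero
    method: str

    @property
    def icc(self):
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


def fit_random_intercept(y, design: pd.DataFrame, cluster_ids,
                         method: str = "ml") -> RandomInterceptFit:
    """Fit y = X beta + u_cluster + e with a settlement random intercept.

    ``design`` must not contain a constant column (one is added).  Rank
    deficiency raises with the offending column named; a boundary estimate
    sigma_u2 = 0 is reported with a flag, not an error.
    """
    y = np.asarray(y, float)
    X = design.copy()
    X.insert(0, "intercept", 1.0)
    r = np.linalg.matrix_rank(X.to_numpy(float))
    if r < X.shape[1]:
        for j, col in enumerate(X.columns):
            sub = X.drop(columns=[col]).to_numpy(float)
            if np.linalg.matrix_rank(sub) == r:
                raise ValueError(f"design is rank deficient: column {col!r}")
        raise ValueError("design is rank deficient")
    groups = np.asarray(cluster_ids)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 clusters")
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X.to_numpy(float), groups=groups)
        res = model.fit(reml=(method.lower() == "reml"))
        beta = pd.Series(res.fe_params, index=X.columns)
        se = pd.Series(np.asarray(res.bse_fe), index=X.columns)
    z = beta / se
    from scipy.stats import norm

    pvals = pd.Series(2 * norm.sf(np.abs(z)), index=X.columns)
    ci = pd.DataFrame({"lo": beta - Z975 * se, "hi": beta + Z975 * se})
    sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
    sigma_e2 = float(res.scale)
    return RandomInterceptFit(
        beta=beta, se=se, pvalues=pvals, conf_int=ci,
        sigma_u2=max(sigma_u2, 0.0), sigma_e2=sigma_e2,
        loglik=float(res.llf), n=len(y), n_clusters=len(np.unique(groups)),
        boundary=bool(sigma_u2 < 1e-8), method=method.lower(),
    )


def total_effects_table(table: pd.DataFrame, indicators=None, treatment="arm",
                        cluster="cluster_id", adjustments=None,
                        method: str = "ml") -> pd.DataFrame:
    """Total intervention effects, one random-intercept model per indicator.

    Returns one row per indicator: n, descriptive arm means, effect estimate
    (treatment coefficient), Wald 95% CI and two-sided p.
    """
    if indicators is None:
        indicators = [
            "dds_mean", "mdd_prop", "crop_richness", "garden_practices",
            "n_poultry", "n_eggs", "fg_knowledge", "dd_knowledge", "market_score",
        ]
    adjustments = DEFAULT_ADJUSTMENTS if adjustments is None else adjustments
    rows = []
    for ind in indicators:
        adj = [c for c in adjustments.get(ind, []) if c in table.columns]
        cols = [ind, treatment, cluster] + adj
        sub = table[cols].dropna()
        design = sub[[treatment] + adj]
        fit = fit_random_intercept(sub[ind], design, sub[cluster], method=method)
        rows.append({
            "indicator": ind,
            "n": len(sub),
            "mean_control": float(sub.loc[sub[treatment] == 0, ind].mean()),
            "mean_intervention": float(sub.loc[sub[treatment] == 1, ind].mean()),
            "beta": float(fit.beta[treatment]),
            "ci_low": float(fit.conf_int.loc[treatment, "lo"]),
            "ci_high": float(fit.conf_int.loc[treatment, "hi"]),
            "p": float(fit.pvalues[treatment]),
            "sigma_u2": fit.sigma_u2,
            "sigma_e2": fit.sigma_e2,
        })
    return pd.DataFrame(rows)
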