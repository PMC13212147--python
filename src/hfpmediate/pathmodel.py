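"""Recursive linear path model fitted by FIML, statsmodels-style.

:class:`PathModel` is built from a one-row-per-woman DataFrame and a
:class:`~hfpmediate.pathspec.PathModelSpec`; ``fit()`` returns a
:class:`PathModelResults` carrying estimates, naive and cluster-robust
standard errors, Wald tests, fit indices (chi-square, CFI, TLI, RMSEA) and
standardized coefficients.

Inference accounts for settlement-level clustering through a sandwich
covariance A^-1 B A^-1 where A is the observed information (Hessian of the
negative log-likelihood at the optimum) and B sums outer products of
within-cluster summed score vectors.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import fiml
from .pathspec import PathModelSpec, parse_model_syntax

__all__ = ["PathModel", "PathModelResults", "wald_tests"]


def wald_tests(estimates, variances):
    """Two-sided Wald z and p per coefficient: z = est/se, p = 2(1-Phi(|z|)).

    Zero standard errors yield NaN p-values with a warning.
    """
    est = np.asarray(estimates, float)
    se = np.sqrt(np.asarray(variances, float))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    if np.any(se == 0):
        warnings.warn("zero standard error; Wald p undefined for some coefficients")
        z = np.where(se == 0, np.nan, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


class PathModel:
    """Recursive path model over observed variables.

    Parameters
    ----------
    data : DataFrame
        One row per woman; must contain every variable in the spec.  NaN
        marks a missing observation, handled by FIML.
    spec : PathModelSpec
        The equation system (see :func:`hfpmediate.pathspec.build_model_spec`).
    cluster : str, optional
        Column with the settlement (cluster) identifier, enabling
        cluster-robust standard errors.
    mode : {"auto", "fixed", "saturated"}
        Exogenous-variable handling: ``fixed`` conditions on complete
        exogenous data; ``saturated`` gives the exogenous block free
        jointly-normal moments (required when covariates have holes).
        ``auto`` picks ``fixed`` when the exogenous columns are complete.
    """

    def __init__(self, data: pd.DataFrame, spec: PathModelSpec,
                 cluster: str | None = None, mode: str = "auto"):
        self.spec = spec
        self.endo = spec.endogenous
        self.exog = spec.exogenous
        missing_cols = [c for c in self.endo + self.exog if c not in data.columns]
        if missing_cols:
            raise KeyError(f"data lacks model variables: {missing_cols}")
        self.data = data.reset_index(drop=True)
        Y = self.data[self.endo].to_numpy(float)
        X = self.data[self.exog].to_numpy(float)
        if mode == "auto":
            mode = "fixed" if not np.isnan(X).any() else "saturated"
        self.mode = mode
        self.param = fiml.Parameterization(spec, mode)
        if mode == "fixed":
            self.like = fiml.FixedLikelihood(Y, X)
        else:
            self.like = fiml.SaturatedLikelihood(np.hstack([X, Y]))
        self.Y, self.X = Y, X
        self.nobs = len(self.data)
        self.cluster_ids = (
            self.data[cluster].to_numpy() if cluster is not None else None
        )
        logging.getLogger(__name__).info(
            "path model: %d endogenous, %d exogenous, mode=%s, n=%d; equations: %s",
            len(self.endo), len(self.exog), self.mode, self.nobs,
            {d: " + ".join(r) for d, r in spec.equations.items()},
        )

    @classmethod
    def from_formulas(cls, data, formulas: str, **kw):
        """Build from the ``y ~ x`` / ``m1 ~~ m2`` mini-language."""
        return cls(data, parse_model_syntax(formulas), **kw)

    # -- starting values ---------------------------------------------------
    def start_values(self):
        """Equation-wise complete-case least squares (+ residual-block cov)."""
        m, p = self.param.m, self.param.p
        alpha = np.zeros(m)
        B = np.zeros((m, m))
        G = np.zeros((m, p))
        resid = np.full((self.nobs, m), np.nan)
        for i, dep in enumerate(self.endo):
            regs = self.spec.equations[dep]
            cols = [self.endo.index(r) if r in self.param.e_idx else None for r in regs]
            Rmat = np.column_stack([
                self.Y[:, self.endo.index(r)] if r in self.param.e_idx
                else self.X[:, self.exog.index(r)]
                for r in regs
            ]) if regs else np.empty((self.nobs, 0))
            y = self.Y[:, i]
            ok = ~np.isnan(y)
            if Rmat.shape[1]:
                ok &= ~np.isnan(Rmat).any(axis=1)
            if ok.sum() >= Rmat.shape[1] + 2:
                D = np.column_stack([np.ones(ok.sum()), Rmat[ok]])
                coef, *_ = np.linalg.lstsq(D, y[ok], rcond=None)
                alpha[i] = coef[0]
                for val, r in zip(coef[1:], regs):
                    if r in self.param.e_idx:
                        B[i, self.endo.index(r)] = val
                    else:
                        G[i, self.exog.index(r)] = val
                resid[ok, i] = y[ok] - D @ coef
            else:  # too few complete cases: intercept-only start
                alpha[i] = np.nanmean(y)
                resid[ok, i] = y[ok] - alpha[i]
        Psi = pd.DataFrame(resid).cov(ddof=0).to_numpy()
        bad = ~np.isfinite(np.diag(Psi))
        if bad.any():
            Psi[bad, :] = 0.0
            Psi[:, bad] = 0.0
            Psi[np.diag_indices_from(Psi)] = np.where(
                bad, np.nanvar(self.Y, axis=0), np.diag(Psi)
            )
        Psi = np.where(np.isfinite(Psi), Psi, 0.0)
        kw = {}
        if self.mode == "saturated":
            kw["mu_x"] = np.nanmean(self.X, axis=0)
            kw["Sigma_xx"] = pd.DataFrame(self.X).cov(ddof=0).to_numpy()
        return self.param.pack(alpha, B, G, Psi, **kw)

    # -- estimation --------------------------------------------------------
    def loglik(self, theta):
        mom, _ = self.param.moments(np.asarray(theta, float))
        return self.like.loglik(*mom)

    def fit(self, start=None, gtol=1e-5, maxiter=1000,
            small_sample_correction: bool = False) -> "PathModelResults":
        obj = fiml.ObjectiveWrapper(self.param, self.like)
        theta0 = self.start_values() if start is None else np.asarray(start, float)
        theta, ll, converged, gnorm, nit, H = fiml.maximize_loglik(
            obj, theta0, gtol=gtol, maxiter=maxiter
        )
        res = PathModelResults(
            self, theta, ll, converged, gnorm, nit,
            small_sample_correction=small_sample_correction, hessian=H,
        )
        if not converged:
            warnings.warn(
                f"FIML optimization did not meet tolerances (max|grad|={gnorm:.2e}); "
                "returning best-found parameters"
            )
        return res


class PathModelResults:
    """Estimates, covariances, tests and fit diagnostics of a path model."""

    def __init__(self, model: PathModel, theta, loglik, converged, gnorm, nit,
                 small_sample_correction=False, hessian=None):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.loglik = float(loglik)
        self.converged = bool(converged)
        self.grad_norm = float(gnorm)
        self.n_iter = nit
        self.nobs = model.nobs
        self.small_sample_correction = small_sample_correction
        self.params = pd.Series(self.theta, index=model.param.labels)
        self._hessian = hessian
        self._vcov = {}

    # -- covariances -------------------------------------------------------
    def _neg_loglik_grad(self, theta):
        obj = fiml.ObjectiveWrapper(self.model.param, self.model.like)
        return obj.value_and_grad(theta)[1]

    def hessian(self):
        """Observed information: Hessian of the negative log-likelihood."""
        if self._hessian is None:
            self._hessian = fiml.fd_hessian(self._neg_loglik_grad, self.theta)
        return self._hessian

    def scores(self):
        """Per-row score vectors d loglik_i / d theta at the estimate."""
        mom, _ = self.model.param.moments(self.theta)
        _, G = self.model.like.loglik(*mom, rowwise=True)
        J = self.model.param.jacobian(self.theta)
        return G @ J

    def vcov(self, kind: str = "cluster"):
        """Coefficient covariance: 'naive' (inverse information) or 'cluster'
        (sandwich over settlement-summed scores).  With no cluster column,
        'cluster' degenerates to the per-row heteroskedasticity-robust
        sandwich."""
        if kind in self._vcov:
            return self._vcov[kind]
        A = self.hessian()
        if np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError(
                f"singular information matrix (cond={np.linalg.cond(A):.2e})"
            )
        Ainv = linalg.inv(A)
        if kind == "naive":
            V = 0.5 * (Ainv + Ainv.T)
        elif kind == "cluster":
            S = self.scores()
            ids = self.model.cluster_ids
            if ids is None:
                Sc = S
            else:
                df = pd.DataFrame(S)
                df["__c"] = ids
                Sc = df.groupby("__c").sum().to_numpy()
            Bmat = Sc.T @ Sc
            G = len(Sc)
            V = Ainv @ Bmat @ Ainv
            if self.small_sample_correction and G > 1:
                V = V * (G / (G - 1.0))
            V = 0.5 * (V + V.T)
        else:
            raise ValueError(f"unknown vcov kind {kind!r}")
        self._vcov[kind] = V
        return V

    def bse(self, kind="cluster"):
        return pd.Series(np.sqrt(np.diag(self.vcov(kind))), index=self.params.index)

    def wald(self, kind="cluster"):
        z, p = wald_tests(self.theta, np.diag(self.vcov(kind)))
        return pd.DataFrame({"z": z, "p": p}, index=self.params.index)

    # -- implied structure -------------------------------------------------
    def structural(self):
        """Structural matrices (alpha, B, Gamma, Psi) at the estimate."""
        return self.model.param.unpack(self.theta)

    def psi(self):
        st = self.structural()
        return pd.DataFrame(st["Psi"], index=self.model.endo, columns=self.model.endo)

    def implied_moments(self):
        """Implied mean and covariance over (exogenous, endogenous).

        In fixed mode the exogenous moments are the sample ML moments."""
        param = self.model.param
        mom, cache = param.moments(self.theta)
        names = self.model.exog + self.model.endo
        if param.mode == "saturated":
            mu, Sigma = mom
        else:
            a0, Pi, S = mom
            mu_x = self.model.X.mean(axis=0)
            Sxx = np.cov(self.model.X.T, bias=True).reshape(param.p, param.p)
            p, m = param.p, param.m
            mu = np.concatenate([mu_x, a0 + Pi @ mu_x])
            Sigma = np.empty((p + m, p + m))
            Sigma[:p, :p] = Sxx
            Sigma[:p, p:] = Sxx @ Pi.T
            Sigma[p:, :p] = Pi @ Sxx
            Sigma[p:, p:] = Pi @ Sxx @ Pi.T + S
        return (pd.Series(mu, index=names),
                pd.DataFrame(Sigma, index=names, columns=names))

    def standardized_params(self):
        """Coefficients scaled by implied sd(regressor)/sd(dependent)."""
        _, Sigma = self.implied_moments()
        sd = pd.Series(np.sqrt(np.diag(Sigma)), index=Sigma.index)
        if (sd == 0).any():
            warnings.warn("zero implied variance; standardized paths undefined there")
        out = {}
        for lab in self.params.index:
            if "~" in lab and "~~" not in lab and not lab.startswith(("chol:", "mean:", "cholx:")):
                dep, reg = lab.split("~", 1)
                if reg == "1":
                    continue
                out[lab] = self.params[lab] * sd[reg] / sd[dep]
        return pd.Series(out)

    # -- fit indices -------------------------------------------------------
    def fit_indices(self):
        """Chi-square against the saturated model, with CFI/TLI/RMSEA.

        The baseline (independence) model frees every modeled variable's mean
        and variance with all covariances zero, on the same missing-data
        patterns.  The saturated log-likelihood comes from an EM fit of the
        unrestricted multivariate normal."""
        model = self.model
        param = model.param
        m, p = param.m, param.p
        if param.mode == "fixed":
            n_mom = m + m * p + m * (m + 1) // 2
            Z = np.hstack([model.X, model.Y])
            _, _, ll_joint = fiml.mvn_mle(Z)
            if p > 0:
                xlike = fiml.SaturatedLikelihood(model.X)
                mu_x = model.X.mean(axis=0)
                Sxx = np.cov(model.X.T, bias=True).reshape(p, p)
                ll_x = xlike.loglik(mu_x, Sxx)
            else:
                ll_x = 0.0
            ll_sat = ll_joint - ll_x
            base_cols = [model.Y[:, j] for j in range(m)]
            n_base_par = 2 * m
        else:
            d = p + m
            n_mom = d + d * (d + 1) // 2
            Z = model.like.Z
            _, _, ll_sat = fiml.mvn_mle(Z)
            base_cols = [Z[:, j] for j in range(d)]
            n_base_par = 2 * d
        ll_base = sum(fiml.univariate_mle_loglik(c)[0] for c in base_cols)
        df_m = n_mom - param.n_params
        df_b = n_mom - n_base_par
        chi2_m = max(2.0 * (ll_sat - self.loglik), 0.0)
        chi2_b = max(2.0 * (ll_sat - ll_base), 0.0)
        out = {"chi2": chi2_m, "df": df_m, "chi2_baseline": chi2_b,
               "df_baseline": df_b, "n": self.nobs,
               "loglik": self.loglik, "loglik_saturated": ll_sat}
        out["p"] = float(stats.chi2.sf(chi2_m, df_m)) if df_m > 0 else np.nan
        num = max(chi2_m - df_m, 0.0)
        den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
        out["cfi"] = 1.0 if den == 0 else 1.0 - num / den
        if df_m > 0 and df_b > 0 and chi2_b / df_b != 1.0:
            out["tli"] = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
        else:
            out["tli"] = np.nan
        if chi2_m <= df_m:
            out["rmsea"] = 0.0
        else:
            out["rmsea"] = float(np.sqrt((chi2_m - df_m) / (df_m * self.nobs)))
        return out

    # -- reporting ---------------------------------------------------------
    def param_table(self, kind="cluster"):
        """Tidy coefficient table: estimate, naive and cluster SEs, z, p."""
        se_n = self.bse("naive")
        se_c = self.bse(kind) if kind != "naive" else se_n
        z, pvals = wald_tests(self.theta, np.diag(self.vcov(kind)))
        return pd.DataFrame({
            "label": self.params.index,
            "estimate": self.theta,
            "se_naive": se_n.to_numpy(),
            "se_cluster": se_c.to_numpy(),
            "z": z,
            "p": pvals,
        }).reset_index(drop=True)

    def summary(self, kind="cluster"):
        ids = self.model.cluster_ids
        ncl = len(np.unique(ids)) if ids is not None else self.nobs
        lines = [
            "Recursive path model (FIML)",
            "=" * 70,
            f"n = {self.nobs}   clusters = {ncl}   mode = {self.model.mode}",
            f"log-likelihood = {self.loglik:.3f}   converged = {self.converged}"
            f"   max|grad| = {self.grad_norm:.2e}",
            "-" * 70,
            f"{'parameter':<38}{'est':>9}{'se':>9}{'z':>7}{'p':>7}",
        ]
        tab = self.param_table(kind)
        for _, r in tab.iterrows():
            lab = r["label"]
            if lab.startswith(("chol:", "cholx:", "mean:")):
                continue
            pstr = "<0.001" if r["p"] < 1e-3 else f"{r['p']:.3f}"
            lines.append(
                f"{lab:<38}{r['estimate']:>9.3f}{r['se_cluster']:>9.3f}"
                f"{r['z']:>7.2f}{pstr:>7}"
            )
        lines.append("-" * 70)
        psi = self.psi()
        for i, a in enumerate(psi.index):
            lines.append(f"resid var  {a:<27}{psi.iloc[i, i]:>9.3f}")
        return "\n".join(lines)
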