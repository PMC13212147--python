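"""Full-information maximum likelihood engine for recursive path models.

The model is linear-Gaussian.  Writing eta for the endogenous vector and x
for the exogenous vector (treatment + covariates),

    eta = alpha + B eta + Gamma x + zeta,   zeta ~ N(0, Psi),

with B strictly lower triangular under the topological ordering, so
A = (I - B)^-1 exists and the reduced form is

    eta | x ~ N(A alpha + A Gamma x, A Psi A').

Two exogenous-handling modes are supported:

* ``fixed`` — x is conditioned on (requires complete exogenous data); the
  modelled variables are the endogenous ones and each row contributes the
  Gaussian log-density of its *observed* endogenous sub-vector given x.
* ``saturated`` — x is given free jointly-normal moments (mu_x, Sigma_xx) and
  the modelled vector is z = (x, eta); rows may then have holes anywhere.

Casewise likelihoods are grouped by missing-data pattern.  Gradients are
analytic: the data side gives the gradient with respect to the implied
moments, which is chained through the moment structure to the free
parameters.  Residual blocks (and Sigma_xx) are parameterized by Cholesky
factors with log-transformed diagonals, so every proposal is positive
definite by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize

LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# pattern-grouped casewise Gaussian likelihood
# ---------------------------------------------------------------------------

def pattern_groups(observed: np.ndarray):
    """Group row indices by their observedness pattern.

    ``observed`` is an (n, k) boolean array.  Returns a list of
    ``(obs_indices, row_indices)``.  Raises if any row observes nothing.
    """
    if (~observed).all(axis=1).any():
        bad = int(np.where((~observed).all(axis=1))[0][0])
        raise ValueError(f"row {bad} has no observed modeled variable")
    keys = {}
    for i, row in enumerate(map(tuple, observed)):
        keys.setdefault(row, []).append(i)
    return [
        (np.flatnonzero(np.array(key)), np.array(rows))
        for key, rows in keys.items()
    ]


class FixedLikelihood:
    """Casewise likelihood of eta | x for complete x, pattern-grouped."""

    def __init__(self, Y: np.ndarray, X: np.ndarray):
        Y = np.asarray(Y, float)
        X = np.asarray(X, float)
        if np.isnan(X).any():
            raise ValueError(
                "exogenous data contain missing values; use mode='saturated'"
            )
        self.Y, self.X = Y, X
        self.n, self.m = Y.shape
        self.p = X.shape[1]
        self.groups = pattern_groups(~np.isnan(Y))

    @property
    def n_flat(self):
        return self.m + self.m * self.p + self.m * self.m

    def loglik(self, a0, Pi, S, grad=False, rowwise=False):
        """Log-likelihood; optionally the moment-space gradient.

        With ``grad`` returns ``(ll, g_a0, g_Pi, g_S)``; with ``rowwise``
        returns ``(ll, G)`` where G is (n, n_flat) of per-row gradients in
        the flat layout [a0, Pi.ravel(), S.ravel()].
        """
        m, p = self.m, self.p
        ll = 0.0
        if grad:
            g_a0 = np.zeros(m)
            g_Pi = np.zeros((m, p))
            g_S = np.zeros((m, m))
        if rowwise:
            G = np.zeros((self.n, self.n_flat))
        for obs, rows in self.groups:
            k = len(obs)
            So = S[np.ix_(obs, obs)]
            try:
                L = linalg.cholesky(So, lower=True)
            except linalg.LinAlgError as e:
                raise FloatingPointError("implied residual covariance not PD") from e
            Xg = self.X[rows]
            R = self.Y[np.ix_(rows, obs)] - a0[obs] - Xg @ Pi[obs].T
            Z = linalg.solve_triangular(L, R.T, lower=True)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            ll += -0.5 * (len(rows) * (k * LOG2PI + logdet) + (Z * Z).sum())
            if grad or rowwise:
                K = linalg.cho_solve((L, True), np.eye(k))
                U = R @ K
            if grad:
                g_a0[obs] += U.sum(axis=0)
                g_Pi[obs] += U.T @ Xg
                g_S[np.ix_(obs, obs)] += 0.5 * (U.T @ U - len(rows) * K)
            if rowwise:
                ga = np.zeros((len(rows), m))
                ga[:, obs] = U
                gp = np.zeros((len(rows), m, p))
                gp[:, obs, :] = U[:, :, None] * Xg[:, None, :]
                gs = np.zeros((len(rows), m, m))
                outer = U[:, :, None] * U[:, None, :]
                gs[:, obs[:, None], obs[None, :]] = 0.5 * (outer - K)
                G[rows] = np.concatenate(
                    [ga, gp.reshape(len(rows), -1), gs.reshape(len(rows), -1)], axis=1
                )
        if rowwise:
            return ll, G
        if grad:
            return ll, g_a0, g_Pi, g_S
        return ll


class SaturatedLikelihood:
    """Casewise likelihood of the joint modeled vector z, pattern-grouped."""

    def __init__(self, Z: np.ndarray):
        Z = np.asarray(Z, float)
        self.Z = Z
        self.n, self.d = Z.shape
        self.groups = pattern_groups(~np.isnan(Z))

    @property
    def n_flat(self):
        return self.d + self.d * self.d

    def loglik(self, mu, Sigma, grad=False, rowwise=False):
        d = self.d
        ll = 0.0
        if grad:
            g_mu = np.zeros(d)
            g_Sig = np.zeros((d, d))
        if rowwise:
            G = np.zeros((self.n, self.n_flat))
        for obs, rows in self.groups:
            k = len(obs)
            So = Sigma[np.ix_(obs, obs)]
            try:
                L = linalg.cholesky(So, lower=True)
            except linalg.LinAlgError as e:
                raise FloatingPointError("implied covariance not PD") from e
            R = self.Z[np.ix_(rows, obs)] - mu[obs]
            Zt = linalg.solve_triangular(L, R.T, lower=True)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            ll += -0.5 * (len(rows) * (k * LOG2PI + logdet) + (Zt * Zt).sum())
            if grad or rowwise:
                K = linalg.cho_solve((L, True), np.eye(k))
                U = R @ K
            if grad:
                g_mu[obs] += U.sum(axis=0)
                g_Sig[np.ix_(obs, obs)] += 0.5 * (U.T @ U - len(rows) * K)
            if rowwise:
                gm = np.zeros((len(rows), d))
                gm[:, obs] = U
                gs = np.zeros((len(rows), d, d))
                gs[:, obs[:, None], obs[None, :]] = 0.5 * (U[:, :, None] * U[:, None, :] - K)
                G[rows] = np.concatenate([gm, gs.reshape(len(rows), -1)], axis=1)
        if rowwise:
            return ll, G
        if grad:
            return ll, g_mu, g_Sig
        return ll


# ---------------------------------------------------------------------------
# parameterization: theta <-> structural matrices <-> implied moments
# ---------------------------------------------------------------------------

def _chol_from_params(vals, k):
    """Lower-triangular Cholesky from packed params (log diagonal)."""
    L = np.zeros((k, k))
    idx = 0
    for r in range(k):
        for c in range(r + 1):
            if r == c:
                L[r, c] = np.exp(vals[idx])
            else:
                L[r, c] = vals[idx]
            idx += 1
    return L


def _chol_to_params(L):
    k = L.shape[0]
    out = []
    for r in range(k):
        for c in range(r + 1):
            out.append(np.log(L[r, c]) if r == c else L[r, c])
    return np.array(out)


class Parameterization:
    """Maps the free-parameter vector theta to structural matrices and
    implied moments, with analytic gradients.

    theta layout: [alpha (m)] [coefficients, per equation in topological
    order] [Psi Cholesky blocks] and, in saturated mode, [mu_x (p)]
    [Sigma_xx Cholesky].
    """

    def __init__(self, spec, mode: str):
        if mode not in ("fixed", "saturated"):
            raise ValueError(f"unknown mode {mode!r}")
        self.spec = spec
        self.mode = mode
        self.endo = spec.endogenous
        self.exog = spec.exogenous
        self.m, self.p = len(self.endo), len(self.exog)
        self.e_idx = {v: i for i, v in enumerate(self.endo)}
        self.x_idx = {v: i for i, v in enumerate(self.exog)}

        self.coef_entries = []  # (dep_i, reg_idx, is_endo, label)
        self.labels = [f"{v}~1" for v in self.endo]
        for dep in self.endo:
            for reg in spec.equations[dep]:
                if reg in self.e_idx:
                    self.coef_entries.append((self.e_idx[dep], self.e_idx[reg], True))
                else:
                    self.coef_entries.append((self.e_idx[dep], self.x_idx[reg], False))
                self.labels.append(f"{dep}~{reg}")
        self.i_coef = self.m
        self.i_psi = self.i_coef + len(self.coef_entries)
        # index arrays for vectorized packing/gradients
        ce = self.coef_entries
        self._exog_pos = np.array([k for k, e in enumerate(ce) if not e[2]], dtype=int)
        self._exog_ij = np.array([(e[0], e[1]) for e in ce if not e[2]], dtype=int).reshape(-1, 2)
        self._endo_pos = np.array([k for k, e in enumerate(ce) if e[2]], dtype=int)
        self._endo_ij = np.array([(e[0], e[1]) for e in ce if e[2]], dtype=int).reshape(-1, 2)

        self.block_idx = []  # endogenous indices per residual block
        self.psi_labels = []
        for b in spec.blocks():
            bi = [self.e_idx[v] for v in b]
            self.block_idx.append(np.array(bi))
            for r in range(len(b)):
                for c in range(r + 1):
                    self.psi_labels.append(f"{b[r]}~~{b[c]}" if r != c else f"{b[r]}~~{b[r]}")
        self.n_psi = sum(len(b) * (len(b) + 1) // 2 for b in self.block_idx)
        self.labels += [f"chol:{lab}" for lab in self.psi_labels]
        self.i_sat = self.i_psi + self.n_psi
        if mode == "saturated":
            self.labels += [f"mean:{v}" for v in self.exog]
            for r in range(self.p):
                for c in range(r + 1):
                    self.labels.append(f"cholx:{self.exog[r]},{self.exog[c]}")
        self.n_params = len(self.labels)

    # -- structural matrices ----------------------------------------------
    def unpack(self, theta):
        m, p = self.m, self.p
        alpha = theta[: m].copy()
        B = np.zeros((m, m))
        Gm = np.zeros((m, p))
        coef = theta[self.i_coef:self.i_psi]
        if len(self._endo_pos):
            B[self._endo_ij[:, 0], self._endo_ij[:, 1]] = coef[self._endo_pos]
        if len(self._exog_pos):
            Gm[self._exog_ij[:, 0], self._exog_ij[:, 1]] = coef[self._exog_pos]
        Ls = []
        Psi = np.zeros((m, m))
        pos = self.i_psi
        for bi in self.block_idx:
            k = len(bi)
            nb = k * (k + 1) // 2
            L = _chol_from_params(theta[pos:pos + nb], k)
            Ls.append(L)
            Psi[np.ix_(bi, bi)] = L @ L.T
            pos += nb
        out = {"alpha": alpha, "B": B, "Gamma": Gm, "Psi": Psi, "Ls": Ls}
        if self.mode == "saturated":
            out["mu_x"] = theta[self.i_sat:self.i_sat + p].copy()
            Lx = _chol_from_params(theta[self.i_sat + p:], p)
            out["Lx"] = Lx
            out["Sigma_xx"] = Lx @ Lx.T
        return out

    def pack(self, alpha, B, Gamma, Psi, mu_x=None, Sigma_xx=None, jitter=1e-8):
        """Build theta from structural matrices (used for start values)."""
        theta = np.empty(self.n_params)
        theta[: self.m] = alpha
        for k, (i, j, is_endo) in enumerate(self.coef_entries):
            theta[self.i_coef + k] = B[i, j] if is_endo else Gamma[i, j]
        pos = self.i_psi
        for bi in self.block_idx:
            blk = Psi[np.ix_(bi, bi)]
            blk = _nearest_pd(blk, jitter)
            L = linalg.cholesky(blk, lower=True)
            nb = len(bi) * (len(bi) + 1) // 2
            theta[pos:pos + nb] = _chol_to_params(L)
            pos += nb
        if self.mode == "saturated":
            theta[self.i_sat:self.i_sat + self.p] = mu_x
            Lx = linalg.cholesky(_nearest_pd(Sigma_xx, jitter), lower=True)
            theta[self.i_sat + self.p:] = _chol_to_params(Lx)
        return theta

    # -- implied moments ---------------------------------------------------
    def moments(self, theta):
        """Implied moments plus a cache for the gradient chain."""
        st = self.unpack(theta)
        A = linalg.solve_triangular(np.eye(self.m) - st["B"], np.eye(self.m), lower=True)
        a0 = A @ st["alpha"]
        Pi = A @ st["Gamma"]
        S = A @ st["Psi"] @ A.T
        cache = {**st, "A": A, "a0": a0, "Pi": Pi, "S": S}
        if self.mode == "fixed":
            return (a0, Pi, S), cache
        mu_x, Sxx = st["mu_x"], st["Sigma_xx"]
        d = self.p + self.m
        mu = np.concatenate([mu_x, a0 + Pi @ mu_x])
        Sigma = np.empty((d, d))
        Sigma[: self.p, : self.p] = Sxx
        Sigma[: self.p, self.p:] = Sxx @ Pi.T
        Sigma[self.p:, : self.p] = Pi @ Sxx
        Sigma[self.p:, self.p:] = Pi @ Sxx @ Pi.T + S
        return (mu, Sigma), cache

    # -- gradient chain ----------------------------------------------------
    def chain_fixed(self, g_a0, g_Pi, g_S, cache):
        """theta-gradient from the moment-space gradient (fixed mode)."""
        A, alpha, Gm, S = cache["A"], cache["alpha"], cache["Gamma"], cache["S"]
        g = np.empty(self.n_params)
        g[: self.m] = A.T @ g_a0
        AtgPi = A.T @ g_Pi
        if len(self._exog_pos):
            g[self.i_coef + self._exog_pos] = AtgPi[self._exog_ij[:, 0], self._exog_ij[:, 1]]
        for k, i, j in zip(self._endo_pos, self._endo_ij[:, 0], self._endo_ij[:, 1]):
            Aj = A[:, i]
            val = (A[j] @ alpha) * (Aj @ g_a0)
            val += Aj @ g_Pi @ (Gm.T @ A[j])
            val += 2.0 * (Aj @ g_S @ S[j])
            g[self.i_coef + k] = val
        M = A.T @ g_S @ A
        pos = self.i_psi
        for bi, L in zip(self.block_idx, cache["Ls"]):
            Mb = M[np.ix_(bi, bi)]
            GL = 2.0 * (Mb @ L)
            k = len(bi)
            for r in range(k):
                for c in range(r + 1):
                    v = GL[r, c]
                    if r == c:
                        v *= L[r, r]
                    g[pos] = v
                    pos += 1
        return g

    def chain_saturated(self, g_mu, g_Sig, cache):
        p, m = self.p, self.m
        A, Pi, S = cache["A"], cache["Pi"], cache["S"]
        mu_x, Sxx, Lx = cache["mu_x"], cache["Sigma_xx"], cache["Lx"]
        g_mu_x = g_mu[:p].copy()
        g_mu_e = g_mu[p:]
        Gxx = g_Sig[:p, :p]
        Gex = g_Sig[p:, :p]
        Gee = g_Sig[p:, p:]
        g_a0 = g_mu_e.copy()
        g_Pi = np.outer(g_mu_e, mu_x) + 2.0 * Gex @ Sxx + 2.0 * Gee @ Pi @ Sxx
        g_S = Gee
        g_theta = self.chain_fixed(g_a0, g_Pi, g_S, cache)
        g_mu_x += Pi.T @ g_mu_e
        GxeP = Gex.T @ Pi  # = Gxe @ Pi since g_Sig symmetric
        g_Sxx = Gxx + GxeP + GxeP.T + Pi.T @ Gee @ Pi
        g_theta[self.i_sat:self.i_sat + p] = g_mu_x
        GLx = 2.0 * (g_Sxx @ Lx)
        pos = self.i_sat + p
        for r in range(p):
            for c in range(r + 1):
                v = GLx[r, c]
                if r == c:
                    v *= Lx[r, r]
                g_theta[pos] = v
                pos += 1
        return g_theta

    # -- Jacobian of flat moments wrt theta (for per-row scores) -----------
    def jacobian(self, theta):
        """d(flat moments)/d(theta), flat layout matching the likelihood
        classes: fixed [a0, Pi, S]; saturated [mu, Sigma]."""
        _, cache = self.moments(theta)
        m, p = self.m, self.p
        A, alpha, Gm, S = cache["A"], cache["alpha"], cache["Gamma"], cache["S"]
        nf = (m + m * p + m * m) if self.mode == "fixed" else \
             ((p + m) + (p + m) ** 2)
        J = np.zeros((nf, self.n_params))

        def put(col, da0, dPi, dS):
            if self.mode == "fixed":
                J[:m, col] = da0
                J[m:m + m * p, col] = dPi.ravel()
                J[m + m * p:, col] = dS.ravel()
            else:
                d = p + m
                mu_x, Sxx = cache["mu_x"], cache["Sigma_xx"]
                Pi = cache["Pi"]
                dmu = np.zeros(d)
                dmu[p:] = da0 + dPi @ mu_x
                dSig = np.zeros((d, d))
                dSig[:p, p:] = Sxx @ dPi.T
                dSig[p:, :p] = dPi @ Sxx
                dSig[p:, p:] = dPi @ Sxx @ Pi.T + Pi @ Sxx @ dPi.T + dS
                J[:d, col] = dmu
                J[d:, col] = dSig.ravel()

        zmp = np.zeros((m, p))
        zmm = np.zeros((m, m))
        for j in range(m):
            put(j, A[:, j], zmp, zmm)
        for k, (i, j, is_endo) in enumerate(self.coef_entries):
            col = self.i_coef + k
            if is_endo:
                Aj = A[:, i]
                da0 = (A[j] @ alpha) * Aj
                dPi = np.outer(Aj, Gm.T @ A[j])
                dS = np.outer(Aj, S[j]) + np.outer(S[j], Aj)
                put(col, da0, dPi, dS)
            else:
                dPi = np.zeros((m, p))
                dPi[:, j] = A[:, i]
                put(col, np.zeros(m), dPi, zmm)
        pos = self.i_psi
        for bi, L in zip(self.block_idx, cache["Ls"]):
            k = len(bi)
            Ab = A[:, bi]
            for r in range(k):
                for c in range(r + 1):
                    dL = np.zeros((k, k))
                    dL[r, c] = L[r, r] if r == c else 1.0
                    dPsi = dL @ L.T
                    dPsi = dPsi + dPsi.T
                    put(pos, np.zeros(m), zmp, Ab @ dPsi @ Ab.T)
                    pos += 1
        if self.mode == "saturated":
            d = p + m
            Pi = cache["Pi"]
            Lx = cache["Lx"]
            for j in range(p):
                col = self.i_sat + j
                dmu = np.zeros(d)
                dmu[j] = 1.0
                dmu[p:] = Pi[:, j]
                J[:d, col] = dmu
            pos = self.i_sat + p
            for r in range(p):
                for c in range(r + 1):
                    dLx = np.zeros((p, p))
                    dLx[r, c] = Lx[r, r] if r == c else 1.0
                    dSxx = dLx @ Lx.T
                    dSxx = dSxx + dSxx.T
                    dSig = np.zeros((d, d))
                    dSig[:p, :p] = dSxx
                    dSig[:p, p:] = dSxx @ Pi.T
                    dSig[p:, :p] = Pi @ dSxx
                    dSig[p:, p:] = Pi @ dSxx @ Pi.T
                    J[d:, pos] = dSig.ravel()
                    pos += 1
        return J


def _nearest_pd(M, jitter=1e-8):
    """Symmetrize and, if needed, shrink off-diagonals / add jitter until PD."""
    M = 0.5 * (M + M.T)
    for shrink in (1.0, 0.9, 0.7, 0.5, 0.2, 0.0):
        C = np.diag(np.diag(M)) + shrink * (M - np.diag(np.diag(M)))
        C = C + jitter * np.eye(len(M)) * max(1.0, np.trace(M) / max(len(M), 1))
        try:
            linalg.cholesky(C, lower=True)
            return C
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError("could not repair covariance to PD")


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class ObjectiveWrapper:
    """Negative log-likelihood with analytic gradient; guards non-PD proposals."""

    def __init__(self, param: Parameterization, like):
        self.param = param
        self.like = like
        self.n_eval = 0

    def value_and_grad(self, theta):
        self.n_eval += 1
        try:
            mom, cache = self.param.moments(theta)
            out = self.like.loglik(*mom, grad=True)
        except FloatingPointError:
            return np.inf, np.zeros_like(theta)
        ll, *gm = out
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(theta)
        if self.param.mode == "fixed":
            g = self.param.chain_fixed(*gm, cache)
        else:
            g = self.param.chain_saturated(*gm, cache)
        return -ll, -g

    def loglik(self, theta):
        mom, _ = self.param.moments(theta)
        return self.like.loglik(*mom)

    def grad(self, theta):
        return -self.value_and_grad(theta)[1]


def fd_hessian(grad_fn, theta, rel_step=1e-5):
    """Central-difference Hessian of a function whose gradient is analytic."""
    n = len(theta)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def maximize_loglik(obj: ObjectiveWrapper, theta0, gtol=1e-5, maxiter=1000):
    """L-BFGS then Newton polishing; convergence = max|grad| < gtol and the
    polish's relative log-likelihood change < 1e-9.

    Returns (theta, loglik, converged, grad_inf_norm, n_iter, hessian) where
    ``hessian`` is the last finite-difference Hessian of the negative
    log-likelihood (None if polishing was unnecessary).
    """
    res = optimize.minimize(
        obj.value_and_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": min(maxiter, 200), "maxcor": 40,
                 "ftol": 1e-11, "gtol": 1e-7},
    )
    theta = res.x
    f, g = obj.value_and_grad(theta)
    gnorm = np.abs(g).max()
    H = None
    if gnorm > gtol:
        # Newton polish; the FD Hessian changes slowly near the optimum, so
        # it is reused across steps and refreshed only when the iterate has
        # moved appreciably from where it was computed (or progress stalls)
        grad_fn = lambda t: obj.value_and_grad(t)[1]
        for refresh in range(3):
            theta_H = theta.copy()
            H = fd_hessian(grad_fn, theta)
            stalled = False
            for _ in range(10):
                try:
                    step = linalg.solve(H, -g, assume_a="sym")
                except linalg.LinAlgError:
                    stalled = True
                    break
                for scale in (1.0, 0.5, 0.25, 0.1):
                    f_new, g_new = obj.value_and_grad(theta + scale * step)
                    if f_new <= f + 1e-10 * (abs(f) + 1.0):
                        theta = theta + scale * step
                        f, g = f_new, g_new
                        break
                else:
                    stalled = True
                    break
                gnorm = np.abs(g).max()
                if gnorm < gtol:
                    break
            if stalled and gnorm >= gtol:
                continue
            break
        if H is not None and np.abs(theta - theta_H).max() > 0.05:
            H = fd_hessian(grad_fn, theta)  # re-center for downstream reuse
    return theta, -f, bool(gnorm < gtol), float(gnorm), int(res.nit), H


# ---------------------------------------------------------------------------
# saturated multivariate-normal MLE with missing data (EM)
# ---------------------------------------------------------------------------

def mvn_mle(Z: np.ndarray, max_iter=2000, rtol=1e-11):
    """ML estimate of an unrestricted MVN mean/covariance with missing data.

    EM over missing-data patterns; returns (mu, Sigma, loglik).  Used for the
    saturated model in the fit-index computation.
    """
    Z = np.asarray(Z, float)
    n, d = Z.shape
    groups = pattern_groups(~np.isnan(Z))
    col_mean = np.nanmean(Z, axis=0)
    Zc = np.where(np.isnan(Z), col_mean, Z)
    mu = Zc.mean(axis=0)
    Sigma = _nearest_pd(np.cov(Zc.T, bias=True) + 1e-6 * np.eye(d))
    if all(len(obs) == d for obs, _ in groups):
        mu = Z.mean(axis=0)
        Sigma = np.cov(Z.T, bias=True).reshape(d, d)
        like = SaturatedLikelihood(Z)
        return mu, Sigma, like.loglik(mu, Sigma)

    like = SaturatedLikelihood(Z)
    ll_old = -np.inf
    for _ in range(max_iter):
        sum_z = np.zeros(d)
        sum_zz = np.zeros((d, d))
        for obs, rows in groups:
            mis = np.setdiff1d(np.arange(d), obs)
            Zo = Z[np.ix_(rows, obs)]
            ng = len(rows)
            if len(mis) == 0:
                sum_z += Zo.sum(axis=0)
                sum_zz += Zo.T @ Zo
                continue
            K = linalg.inv(Sigma[np.ix_(obs, obs)])
            W = Sigma[np.ix_(mis, obs)] @ K
            Em = mu[mis] + (Zo - mu[obs]) @ W.T
            C = Sigma[np.ix_(mis, mis)] - W @ Sigma[np.ix_(obs, mis)]
            full = np.zeros((ng, d))
            full[:, obs] = Zo
            full[:, mis] = Em
            sum_z += full.sum(axis=0)
            sum_zz += full.T @ full
            sum_zz[np.ix_(mis, mis)] += ng * C
        mu = sum_z / n
        Sigma = sum_zz / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = like.loglik(mu, Sigma)
        if ll - ll_old < rtol * (abs(ll) + 1.0):
            break
        ll_old = ll
    return mu, Sigma, like.loglik(mu, Sigma)


def univariate_mle_loglik(col: np.ndarray):
    """Gaussian ML loglik of one variable's observed values (mean, ML var)."""
    v = col[~np.isnan(col)]
    n = len(v)
    if n == 0:
        return 0.0, 0
    var = v.var()  # ML (biased) variance
    if var <= 0:
        raise ValueError("degenerate variable (zero variance)")
    return -0.5 * n * (LOG2PI + np.log(var) + 1.0), n
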