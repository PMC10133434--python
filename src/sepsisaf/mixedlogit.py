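"""Weighted logistic regression with a Gaussian random intercept.

This is the outcome model of the attributable-fraction pipeline: a pooled
(person-period) logistic regression, weighted by inverse-probability-of-
exposure weights, with one Gaussian random intercept per hospital.  The
marginal likelihood integrates the random intercept by adaptive
Gauss-Hermite quadrature: for each cluster the integrand is re-centred at
its mode (found by a damped scalar Newton iteration, vectorised across
clusters) and re-scaled by the local curvature, so the rule stays accurate
for the large, sharply-peaked clusters a multicentre hospital study
produces.  One quadrature node recovers the Laplace approximation.

Weights enter as frequency-type weights on the conditional log-likelihood
terms (the estimating-equation convention of marginal structural models);
the reported covariance is the inverse of the numerically differentiated
Hessian of the weighted marginal log-likelihood.

The model class follows the ``Model.fit() -> Results`` convention: design
matrices in, a results object with ``params``, ``cov_params()``, ``bse``
and ``summary()`` out.  With ``group_var`` fixed at 0 the fit reduces
exactly to an ordinary weighted logistic regression (delegated to a GLM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
import statsmodels.api as sm

_SIGMA_FLOOR = 1e-6


def _grad_hessian(grad_fn, x, rel_step=1e-5):
    """Symmetrised central-difference Hessian from a gradient function."""
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        h = rel_step * max(1.0, abs(x[i]))
        e = np.zeros(k)
        e[i] = h
        H[i] = (grad_fn(x + e) - grad_fn(x - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the optimizer trace message."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(X / scale, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(1.0, diag.max())
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"singular design matrix; collinear column(s): {cols}")


class WeightedMixedLogit:
    """Weighted logistic regression with one Gaussian random intercept.

    Parameters
    ----------
    endog : (n,) binary outcome.
    exog : (n, p) design matrix including an explicit constant column.
    groups : (n,) cluster labels (the random-intercept grouping).
    weights : (n,) positive observation weights, default all one.
    exog_names : column names for reporting.
    """

    def __init__(self, endog, exog, groups, weights=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (nobs, k) aligned with endog")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary")
        codes, self._group_labels = pd.factorize(np.asarray(groups).ravel())
        if codes.shape[0] != self.endog.shape[0]:
            raise ValueError("groups must align with endog")
        self.group_codes = codes
        self.n_groups = len(self._group_labels)
        if weights is None:
            self.weights = np.ones_like(self.endog)
        else:
            self.weights = np.asarray(weights, dtype=float).ravel()
            if (self.weights <= 0).any():
                raise ValueError("weights must be strictly positive")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        _check_full_rank(self.exog, self.exog_names)
        # internal standardisation for optimiser conditioning; the constant
        # column (zero variance) is left untouched and absorbs the shifts
        self._mean = self.exog.mean(axis=0)
        self._sd = self.exog.std(axis=0)
        self._const_cols = self._sd < 1e-12
        if not self._const_cols.any():
            raise ValueError("exog must contain a constant column")
        self._mean[self._const_cols] = 0.0
        self._sd[self._const_cols] = 1.0
        self._Z = (self.exog - self._mean) / self._sd

    # -- transformations ------------------------------------------------
    def _to_raw(self) -> np.ndarray:
        """Linear map L with beta_raw = L @ beta_std."""
        p = self.exog.shape[1]
        L = np.diag(1.0 / self._sd)
        const_idx = int(np.flatnonzero(self._const_cols)[0])
        L[const_idx, :] = -self._mean / self._sd
        L[const_idx, const_idx] = 1.0
        return L

    # -- likelihood -----------------------------------------------------
    def _inner_modes(self, eta: np.ndarray, sigma: float):
        """Per-cluster posterior mode and curvature scale of the intercept."""
        g = self.group_codes
        w = self.weights
        y = self.endog
        b = np.zeros(self.n_groups)
        inv_s2 = 1.0 / sigma**2
        for _ in range(100):
            p = expit(eta + b[g])
            grad = np.bincount(g, w * (y - p), self.n_groups) - b * inv_s2
            hess = np.bincount(g, w * p * (1.0 - p), self.n_groups) + inv_s2
            step = np.clip(grad / hess, -5.0, 5.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-11:
                break
        p = expit(eta + b[g])
        hess = np.bincount(g, w * p * (1.0 - p), self.n_groups) + inv_s2
        return b, 1.0 / np.sqrt(hess)

    def loglike(self, beta: np.ndarray, sigma: float, n_quad: int = 7) -> float:
        """Weighted marginal log-likelihood at raw-scale ``beta``, ``sigma``."""
        return self._loglike_eta(self.exog @ np.asarray(beta, float), sigma, n_quad)[0]

    def _loglike_eta(self, eta, sigma, n_quad, Z=None):
        """Marginal log-likelihood and, when ``Z`` is given, its gradient.

        The gradient is the quadrature-posterior expectation of the
        complete-data score (the node positions are treated as fixed at the
        current adaptive re-centring, whose own sensitivity is negligible
        at the quadrature's accuracy).  The variance-component derivative
        is taken with respect to log(sigma).
        """
        w, y, g = self.weights, self.endog, self.group_codes
        if sigma < _SIGMA_FLOOR:
            ll = float((w * (y * eta - np.logaddexp(0.0, eta))).sum())
            if Z is None:
                return ll, None
            p = expit(eta)
            return ll, np.append(Z.T @ (w * (y - p)), 0.0)
        b_hat, tau = self._inner_modes(eta, sigma)
        nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
        sqrt2 = np.sqrt(2.0)
        log_terms = np.empty((n_quad, self.n_groups))
        resid = np.empty((n_quad, eta.shape[0])) if Z is not None else None
        bks = np.empty((n_quad, self.n_groups))
        for k in range(n_quad):
            bk = b_hat + sqrt2 * tau * nodes[k]
            bks[k] = bk
            etak = eta + bk[g]
            s = np.bincount(g, w * (y * etak - np.logaddexp(0.0, etak)), self.n_groups)
            s += -0.5 * np.log(2.0 * np.pi * sigma**2) - bk**2 / (2.0 * sigma**2)
            log_terms[k] = np.log(wts[k]) + nodes[k] ** 2 + s
            if Z is not None:
                resid[k] = w * (y - expit(etak))
        lse = logsumexp(log_terms, axis=0)
        ll = float((np.log(sqrt2 * tau) + lse).sum())
        if Z is None:
            return ll, None
        post = np.exp(log_terms - lse)  # (K, J) posterior node weights
        grad_beta = Z.T @ (post[:, g] * resid).sum(axis=0)
        grad_logsig = float(
            (post * (bks**2 / sigma**2 - 1.0)).sum()
        )
        return ll, np.append(grad_beta, grad_logsig)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        n_quad: int = 7,
        group_var: float | None = None,
        start_params: np.ndarray | None = None,
        start_group_sd: float = 0.3,
        maxiter: int = 300,
        gtol: float = 5e-4,
    ) -> "WeightedMixedLogitResults":
        """Maximise the weighted marginal likelihood.

        Parameters
        ----------
        n_quad : number of adaptive Gauss-Hermite nodes (1 = Laplace).
        group_var : fix the random-intercept variance at this value
            (0 collapses to an ordinary weighted logistic regression)
            instead of estimating it.
        """
        glm = sm.GLM(
            self.endog,
            self.exog,
            family=sm.families.Binomial(),
            freq_weights=self.weights,
        ).fit(maxiter=200)

        if group_var is not None and group_var <= _SIGMA_FLOOR**2:
            cov = np.asarray(glm.cov_params())
            return WeightedMixedLogitResults(
                model=self,
                params=np.asarray(glm.params, dtype=float),
                cov=cov,
                group_var=0.0,
                llf=self.loglike(np.asarray(glm.params), 0.0),
                converged=bool(glm.converged),
                n_quad=n_quad,
            )

        L = self._to_raw()
        Linv = np.linalg.inv(L)
        beta0_std = (
            Linv @ np.asarray(glm.params, float)
            if start_params is None
            else Linv @ np.asarray(start_params, float)
        )
        fixed_sigma = None if group_var is None else float(np.sqrt(group_var))

        if fixed_sigma is None:
            x0 = np.append(beta0_std, np.log(start_group_sd))

            def negll(th):
                ll, grad = self._loglike_eta(
                    self._Z @ th[:-1], float(np.exp(th[-1])), n_quad, Z=self._Z
                )
                return -ll, -grad

        else:
            x0 = beta0_std

            def negll(th):
                ll, grad = self._loglike_eta(
                    self._Z @ th, fixed_sigma, n_quad, Z=self._Z
                )
                return -ll, -grad[:-1]

        bounds = None
        if fixed_sigma is None:
            bounds = [(None, None)] * len(beta0_std) + [(np.log(1e-4), np.log(20.0))]
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        if not res.success and "ABNORMAL" not in str(res.message):
            raise ConvergenceError(
                f"mixed logistic fit did not converge: {res.message} "
                f"(iterations={res.nit}, |grad|={np.max(np.abs(res.jac)):.3g})"
            )

        # observed information by central differences of the analytic gradient
        H = _grad_hessian(lambda th: negll(th)[1], res.x)
        # guard: Hessian should be positive definite at the optimum
        try:
            cov_all = np.linalg.inv(H)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular Hessian at the optimum: {err}")
        p = self.exog.shape[1]
        cov_std = cov_all[:p, :p]
        beta_std = res.x[:p]
        params = L @ beta_std
        cov = L @ cov_std @ L.T
        sigma = fixed_sigma if fixed_sigma is not None else float(np.exp(res.x[-1]))
        return WeightedMixedLogitResults(
            model=self,
            params=params,
            cov=cov,
            group_var=sigma**2,
            llf=-float(res.fun),
            converged=True,
            n_quad=n_quad,
        )


class WeightedMixedLogitResults:
    """Estimates, covariance and diagnostics for a fitted mixed logit."""

    def __init__(self, model, params, cov, group_var, llf, converged, n_quad):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self._cov = np.asarray(cov, dtype=float)
        self.group_var = float(group_var)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_quad = int(n_quad)

    @property
    def group_sd(self) -> float:
        return float(np.sqrt(self.group_var))

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self._cov))

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    def cov_params(self) -> np.ndarray:
        return self._cov.copy()

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        """Point estimate and variance of the linear contrast c'beta."""
        c = np.asarray(c, dtype=float)
        return float(c @ self.params), float(c @ self._cov @ c)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def summary(self) -> str:
        z = self.params / self.bse
        pvals = 2.0 * norm.sf(np.abs(z))
        ci = self.conf_int()
        lines = [
            "Weighted mixed logistic regression (Gaussian random intercept)",
            f"nobs: {self.nobs}   groups: {self.model.n_groups}   "
            f"quad nodes: {self.n_quad}   loglik: {self.llf:.3f}",
            f"random-intercept SD: {self.group_sd:.4f}",
            "",
            f"{'term':<24}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>9}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for i, name in enumerate(self.model.exog_names):
            lines.append(
                f"{name:<24}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{z[i]:>8.2f}{pvals[i]:>9.3g}{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}"
            )
        return "\n".join(lines)
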