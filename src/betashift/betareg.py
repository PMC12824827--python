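"""Beta-likelihood regression models with a logit link.

Beta-diversity values live in (0, 1), so temporal trends are modelled with
a beta-distributed response: y ~ Beta(mu * phi, (1 - mu) * phi) with
logit(mu) = X b (+ a Gaussian basin random intercept), phi the precision.
:class:`BetaRegression` is the fixed-effects model (analytic gradient ML);
:class:`BetaMixedModel` adds a Gaussian random intercept per group,
integrated out by adaptive Gauss-Hermite quadrature.  Both follow the
model/results convention: ``Model(endog, exog, ...).fit()`` returns a
results object carrying estimates, standard errors, Wald tests and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.special as sp
import scipy.stats as st

__all__ = ["BetaRegression", "BetaMixedModel", "BetaResults", "compress_unit_interval"]

_LOG_SIGMA_MIN = np.log(1e-5)
_LOG_SIGMA_MAX = np.log(50.0)
_LOG_PHI_MIN = np.log(1e-3)
_LOG_PHI_MAX = np.log(1e7)


def compress_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Shrink boundary responses into (0, 1): (y (n-1) + 1/2) / n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = len(y)
    return (y * (n - 1) + 0.5) / n


def _obs_loglik(eta, log_y, log_1my, phi):
    mu = sp.expit(np.clip(eta, -30.0, 30.0))
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        sp.gammaln(phi)
        - sp.gammaln(a)
        - sp.gammaln(b)
        + (a - 1.0) * log_y
        + (b - 1.0) * log_1my
    )


def _obs_score_eta(eta, ystar, phi):
    """d loglik / d eta per observation; ystar = logit(y)."""
    mu = sp.expit(np.clip(eta, -30.0, 30.0))
    mustar = sp.digamma(mu * phi) - sp.digamma((1.0 - mu) * phi)
    return phi * (ystar - mustar) * mu * (1.0 - mu)


def _obs_curv_eta(eta, ystar, phi):
    """d^2 loglik / d eta^2 per observation."""
    mu = sp.expit(np.clip(eta, -30.0, 30.0))
    dmu = mu * (1.0 - mu)
    mustar = sp.digamma(mu * phi) - sp.digamma((1.0 - mu) * phi)
    h = phi * (ystar - mustar)
    hprime = -(phi**2) * (sp.polygamma(1, mu * phi) + sp.polygamma(1, (1.0 - mu) * phi))
    return hprime * dmu**2 + h * dmu * (1.0 - 2.0 * mu)


@dataclass
class BetaResults:
    """Estimates, uncertainties and diagnostics of a beta-likelihood fit."""

    model: object
    params: np.ndarray  # fixed-effect coefficients on the logit scale
    bse: np.ndarray
    phi: float
    sigma2: float  # random-intercept variance (0 for fixed-effects model)
    llf: float
    converged: bool
    exog_names: list
    cov_params: np.ndarray  # covariance of the fixed effects
    n_obs: int
    message: str = ""
    _llnull: float | None = None

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * st.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = st.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    @property
    def fittedvalues(self) -> np.ndarray:
        return sp.expit(self.model.exog @ self.params)

    def pseudo_r2(self) -> float:
        """Likelihood-ratio pseudo R^2 (Cox-Snell form,
        1 - exp(-2 (llf - llf_null) / n)); valid for densities whose
        log-likelihood can be positive.  Not comparable across R^2
        flavours."""
        if self._llnull is None:
            null = self.model.null_model()
            self._llnull = null.fit().llf
        return float(1.0 - np.exp(-2.0 * (self.llf - self._llnull) / self.n_obs))

    def coef_table(self):
        import pandas as pd

        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
                "[0.025": ci[:, 0],
                "0.975]": ci[:, 1],
            },
            index=self.exog_names,
        )

    def summary(self) -> str:
        kind = type(self.model).__name__
        lines = [
            f"{kind} results (logit link, ML)",
            f"  n obs: {self.n_obs}   log-likelihood: {self.llf:.4f}   "
            f"converged: {self.converged}",
            f"  precision phi: {self.phi:.4f}   random-intercept var: {self.sigma2:.6f}",
            "",
            self.coef_table().to_string(float_format=lambda v: f"{v: .5f}"),
        ]
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)


class BetaRegression:
    """Fixed-effects beta regression, logit link, ML with analytic score."""

    def __init__(self, endog, exog, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("endog/exog length mismatch")
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError(
                "responses must lie strictly in (0, 1); "
                "use compress_unit_interval for boundary values"
            )
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self._log_y = np.log(self.endog)
        self._log_1my = np.log1p(-self.endog)
        self._ystar = self._log_y - self._log_1my

    def null_model(self) -> "BetaRegression":
        return BetaRegression(self.endog, np.ones((len(self.endog), 1)), ["const"])

    def _start(self) -> np.ndarray:
        X, y = self.exog, self.endog
        ystar = self._ystar
        beta, *_ = np.linalg.lstsq(X, ystar, rcond=None)
        mu = sp.expit(X @ beta)
        resid_var = max(np.var(y - mu), 1e-6)
        phi = max(np.mean(mu * (1 - mu)) / resid_var - 1.0, 1.0)
        return np.append(beta, np.log(phi))

    def _nll_grad(self, params):
        beta, log_phi = params[:-1], params[-1]
        phi = np.exp(np.clip(log_phi, _LOG_PHI_MIN, _LOG_PHI_MAX))
        eta = self.exog @ beta
        ll = _obs_loglik(eta, self._log_y, self._log_1my, phi).sum()
        score_eta = _obs_score_eta(eta, self._ystar, phi)
        g_beta = self.exog.T @ score_eta
        mu = sp.expit(np.clip(eta, -30.0, 30.0))
        dphi = (
            sp.digamma(phi)
            - mu * sp.digamma(mu * phi)
            - (1 - mu) * sp.digamma((1 - mu) * phi)
            + mu * self._log_y
            + (1 - mu) * self._log_1my
        ).sum()
        grad = np.append(g_beta, dphi * phi)  # chain rule for log-phi
        return -ll, -grad

    def fit(self, maxiter: int = 500) -> BetaResults:
        x0 = self._start()
        opt = scipy.optimize.minimize(
            self._nll_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        if not opt.success:  # rare stall: polish from the current point
            polish = scipy.optimize.minimize(
                self._nll_grad, opt.x, jac=True, method="BFGS",
                options={"maxiter": maxiter, "gtol": 1e-7},
            )
            if polish.fun <= opt.fun:
                opt = polish
        params = opt.x
        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(params, lambda p: self._nll_grad(p)[0])
        p = len(params) - 1
        try:
            cov_all = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(H)
        cov = cov_all[:p, :p]
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return BetaResults(
            model=self,
            params=params[:p],
            bse=bse,
            phi=float(np.exp(params[-1])),
            sigma2=0.0,
            llf=float(-opt.fun),
            converged=bool(opt.success),
            exog_names=self.exog_names,
            cov_params=cov,
            n_obs=len(self.endog),
            message="" if opt.success else str(opt.message),
        )


class BetaMixedModel:
    """Beta regression with a Gaussian random intercept per group.

    The group-level integral of the beta likelihood against the N(0,
    sigma^2) intercept density is evaluated by adaptive Gauss-Hermite
    quadrature: per group a one-dimensional Newton search locates the mode
    of the integrand and the quadrature grid is centred and scaled there,
    which keeps 15 nodes accurate even for long series.  ``fix_sigma=0``
    drops the random effect, reducing exactly to :class:`BetaRegression`'s
    likelihood.
    """

    def __init__(self, endog, exog, groups, exog_names=None, n_nodes: int = 15,
                 fix_sigma: float | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError(
                "responses must lie strictly in (0, 1); "
                "use compress_unit_interval for boundary values"
            )
        self.group_labels, self.groups = np.unique(np.asarray(groups), return_inverse=True)
        self.n_groups = len(self.group_labels)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.n_nodes = int(n_nodes)
        self.fix_sigma = fix_sigma
        self._log_y = np.log(self.endog)
        self._log_1my = np.log1p(-self.endog)
        self._ystar = self._log_y - self._log_1my
        self._nodes, self._weights = np.polynomial.hermite.hermgauss(self.n_nodes)

    def null_model(self) -> "BetaMixedModel":
        return BetaMixedModel(
            self.endog,
            np.ones((len(self.endog), 1)),
            self.group_labels[self.groups],
            ["const"],
            n_nodes=self.n_nodes,
            fix_sigma=self.fix_sigma,
        )

    # -- likelihood ---------------------------------------------------------

    def _group_modes(self, eta0, phi, sigma2):
        """Newton search for the per-group mode of the joint integrand."""
        G = self.n_groups
        u = np.zeros(G)
        for _ in range(50):
            eta = eta0 + u[self.groups]
            s = np.bincount(self.groups, weights=_obs_score_eta(eta, self._ystar, phi),
                            minlength=G) - u / sigma2
            c = np.bincount(self.groups, weights=_obs_curv_eta(eta, self._ystar, phi),
                            minlength=G) - 1.0 / sigma2
            step = s / np.minimum(c, -1e-10)
            step = np.clip(step, -2.0, 2.0)
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + u[self.groups]
        c = np.bincount(self.groups, weights=_obs_curv_eta(eta, self._ystar, phi),
                        minlength=G) - 1.0 / sigma2
        return u, np.minimum(c, -1e-10)

    def _loglike(self, params) -> float:
        p = self.exog.shape[1]
        beta = params[:p]
        phi = np.exp(np.clip(params[p], _LOG_PHI_MIN, _LOG_PHI_MAX))
        eta0 = self.exog @ beta
        if self.fix_sigma is not None and self.fix_sigma == 0.0:
            return float(_obs_loglik(eta0, self._log_y, self._log_1my, phi).sum())
        log_sigma = (
            np.log(self.fix_sigma) if self.fix_sigma is not None else params[p + 1]
        )
        sigma = np.exp(np.clip(log_sigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))
        sigma2 = sigma**2
        G = self.n_groups
        u_hat, curv = self._group_modes(eta0, phi, sigma2)
        tau = 1.0 / np.sqrt(-curv)
        # g(u) = sum_j ll_j(eta + u) + log N(u; 0, sigma^2)
        K = self.n_nodes
        gvals = np.empty((K, G))
        for k in range(K):
            u_k = u_hat + np.sqrt(2.0) * tau * self._nodes[k]
            eta = eta0 + u_k[self.groups]
            obs = _obs_loglik(eta, self._log_y, self._log_1my, phi)
            gvals[k] = (
                np.bincount(self.groups, weights=obs, minlength=G)
                - 0.5 * u_k**2 / sigma2
                - 0.5 * np.log(2.0 * np.pi * sigma2)
            )
        logw = np.log(self._weights)[:, None] + self._nodes[:, None] ** 2 + gvals
        m = logw.max(axis=0)
        group_ll = m + np.log(np.exp(logw - m).sum(axis=0)) + 0.5 * np.log(2.0) + np.log(tau)
        return float(group_ll.sum())

    # -- fitting ------------------------------------------------------------

    def _start(self):
        fe = BetaRegression(self.endog, self.exog, self.exog_names)
        x0 = fe._start()
        if self.fix_sigma is not None and self.fix_sigma == 0.0:
            return x0
        resid = self._ystar - self.exog @ x0[:-1]
        gm = np.bincount(self.groups, weights=resid) / np.bincount(self.groups)
        sig = max(np.std(gm), 0.05)
        if self.fix_sigma is not None:
            return x0
        return np.append(x0, np.log(sig))

    def fit(self, maxiter: int = 200) -> BetaResults:
        p = self.exog.shape[1]
        # precondition: centre non-intercept columns when an intercept
        # column is present, so ill-scaled covariates (e.g. calendar years)
        # do not stall the optimizer; estimates are mapped back exactly
        exog_orig = self.exog
        ones = [
            j for j in range(p) if np.allclose(exog_orig[:, j], 1.0)
        ]
        shift = np.zeros(p)
        if ones:
            j0 = ones[0]
            shift = exog_orig.mean(axis=0)
            shift[j0] = 0.0
            self.exog = exog_orig - shift
        x0 = self._start()
        bounds = [(None, None)] * p + [(_LOG_PHI_MIN, _LOG_PHI_MAX)]
        if not (self.fix_sigma is not None):
            bounds += [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
        nll = lambda q: -self._loglike(q)
        opt = scipy.optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        params = opt.x
        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(params, nll)
        try:
            cov_all = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(H)
        cov = cov_all[:p, :p]
        self.exog = exog_orig
        if ones:
            # b_j unchanged for j != j0; b_j0 = c_j0 - sum_j b_j * shift_j
            J = np.eye(p)
            J[j0, :] = -shift
            J[j0, j0] = 1.0
            params = params.copy()
            params[:p] = J @ params[:p]
            cov = J @ cov @ J.T
        diag = np.diag(cov).copy()
        bse = np.sqrt(np.clip(diag, 0.0, np.inf))
        if self.fix_sigma is not None:
            sigma2 = float(self.fix_sigma) ** 2
        else:
            sigma2 = float(np.exp(params[p + 1]) ** 2)
        converged = bool(opt.success) and np.all(np.isfinite(bse))
        return BetaResults(
            model=self,
            params=params[:p],
            bse=bse,
            phi=float(np.exp(params[p])),
            sigma2=sigma2,
            llf=float(-opt.fun),
            converged=converged,
            exog_names=self.exog_names,
            cov_params=cov,
            n_obs=len(self.endog),
            message="" if converged else f"non-convergence: {opt.message}",
        )
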