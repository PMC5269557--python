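"""Naive longitudinal submodel: quadratic-trend linear mixed-effects model.

Fits ``y_ij = beta0 + beta1*t_ij + beta2*t_ij^2 + b0_i + b1_i*t_ij + e_ij``
with ``b_i ~ N(0, D)`` and ``e_ij ~ N(0, sigma^2)`` by maximising the exact
marginal Gaussian likelihood (ML, not REML, so its criterion is directly
comparable to the joint model's likelihood).  Dropout is ignored: under
informative missingness the fixed-effect trend from this model is biased,
which is precisely the comparison the package exists to make.

Estimation profiles the fixed effects out by GLS and optimises the three
free elements of the Cholesky factor of D plus log sigma^2 by quasi-Newton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import LinkedCohort, build_design

__all__ = ["LMMParams", "EngagementLMM", "LMMResults", "fit_lmm"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMParams:
    """Parameters of the longitudinal submodel."""

    beta: np.ndarray    # (3,) fixed effects: intercept, week, week^2
    D: np.ndarray       # (2, 2) random-effects covariance (intercept, slope)
    sigma2: float       # residual variance

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.beta.shape != (3,) or self.D.shape != (2, 2):
            raise ValueError("beta must be length 3 and D 2x2")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if np.any(np.linalg.eigvalsh(self.D) <= 0):
            raise ValueError("D must be positive definite")


def _theta_to_varparams(theta: np.ndarray) -> tuple[np.ndarray, float]:
    """Unconstrained (log l11, l21, log l22, log sigma2) -> (D, sigma2)."""
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    return L @ L.T, float(np.exp(theta[3]))


def _varparams_to_theta(D: np.ndarray, sigma2: float) -> np.ndarray:
    L = np.linalg.cholesky(D)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), np.log(sigma2)])


class EngagementLMM:
    """Linear mixed model for weekly engagement with random intercept + slope.

    Parameters
    ----------
    cohort : LinkedCohort
        Only the longitudinal component is used; the survival table merely
        defines the subject set.
    """

    def __init__(self, cohort: LinkedCohort):
        design = build_design(cohort)
        self.design = design
        counts = np.bincount(design.subject_index, minlength=design.n_subjects)
        self._n_multi_record = int(np.sum(counts >= 2))
        # per-subject views (records are sorted by subject)
        order = np.argsort(design.subject_index, kind="stable")
        self._splits = np.cumsum(counts)[:-1]
        self._ys = np.split(design.y[order], self._splits)
        self._Xs = np.split(design.X[order], self._splits)
        self._Zs = np.split(design.Z[order], self._splits)
        # subjects observed on an identical time grid share X, Z and V:
        # group them so each V is factorised once per likelihood evaluation
        ts = np.split(design.times[order], self._splits)
        groups: dict[bytes, list[int]] = {}
        for i, t in enumerate(ts):
            groups.setdefault(np.ascontiguousarray(t).tobytes(), []).append(i)
        self._groups = [
            (self._Xs[idx[0]], self._Zs[idx[0]], np.stack([self._ys[i] for i in idx], axis=1))
            for idx in groups.values()
        ]

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params: LMMParams) -> float:
        """Exact marginal log-likelihood sum_i log N(y_i; X_i beta, Z_i D Z_i' + sigma2 I)."""
        total = 0.0
        for y, X, Z in zip(self._ys, self._Xs, self._Zs):
            r = y - X @ params.beta
            V = Z @ params.D @ Z.T + params.sigma2 * np.eye(len(y))
            c = np.linalg.cholesky(V)
            u = np.linalg.solve(c, r)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            total += -0.5 * (len(y) * _LOG2PI + logdet + u @ u)
        return float(total)

    def _profile_neg_loglike(self, theta: np.ndarray) -> float:
        try:
            ll, _, _ = self._profile(theta)
        except np.linalg.LinAlgError:
            return 1e12  # numerically degenerate V: reject the step
        return -ll

    def _profile(self, theta: np.ndarray):
        """Profile out beta by GLS for given variance parameters."""
        D, sigma2 = _theta_to_varparams(theta)
        XtVX = np.zeros((3, 3))
        XtVy = np.zeros(3)
        quad = 0.0
        logdet = 0.0
        nrec = 0
        for X, Z, Y in self._groups:  # Y: (n_i, n_subjects_in_group)
            m = Y.shape[1]
            V = Z @ D @ Z.T + sigma2 * np.eye(len(X))
            c = np.linalg.cholesky(V)
            Xi = np.linalg.solve(c, X)
            Yi = np.linalg.solve(c, Y)
            XtVX += m * (Xi.T @ Xi)
            XtVy += Xi.T @ Yi.sum(axis=1)
            quad += float((Yi**2).sum())
            logdet += 2.0 * m * np.sum(np.log(np.diag(c)))
            nrec += m * len(X)
        beta = np.linalg.solve(XtVX, XtVy)
        ll = -0.5 * (nrec * _LOG2PI + logdet + quad - beta @ XtVX @ beta)
        return float(ll), beta, XtVX

    # -- initialisation -----------------------------------------------------

    def _start(self) -> tuple[np.ndarray, np.ndarray]:
        d = self.design
        beta0, *_ = np.linalg.lstsq(d.X, d.y, rcond=None)
        resid_var = float(np.var(d.y - d.X @ beta0))
        # between-subject spread of per-subject OLS intercept/slope, shrunk to PD
        coefs = []
        for y, Z in zip(self._ys, self._Zs):
            if len(y) >= 2 and np.ptp(Z[:, 1]) > 0:
                coefs.append(np.linalg.lstsq(Z, y, rcond=None)[0])
        if len(coefs) >= 3:
            D0 = np.cov(np.asarray(coefs).T)
            D0 = 0.9 * D0 + 0.1 * np.diag(np.maximum(np.diag(D0), 1e-2))
        else:
            D0 = np.diag([1.0, 0.01])
        if np.any(np.linalg.eigvalsh(D0) <= 1e-8):
            D0 = D0 + 1e-2 * np.eye(2)
        sigma2_0 = max(0.5 * resid_var, 1e-4)
        return beta0, _varparams_to_theta(D0, sigma2_0)

    # -- fitting ------------------------------------------------------------

    def fit(self, start: LMMParams | None = None, maxiter: int = 500) -> "LMMResults":
        """Maximise the marginal likelihood; returns an :class:`LMMResults`."""
        if self.design.n_subjects < 2 or self._n_multi_record < 2:
            raise ValueError(
                "slope identifiability requires at least 2 subjects with >= 2 records each"
            )
        if start is not None:
            theta0 = _varparams_to_theta(start.D, start.sigma2)
        else:
            _, theta0 = self._start()
        # bounds keep V = Z D Z' + sigma2 I factorisable as variances hit the
        # boundary (noiseless or random-intercept-only data)
        bounds = [(-12.0, 10.0), (-60.0, 60.0), (-12.0, 10.0), (-12.0, 10.0)]
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            self._profile_neg_loglike,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
        )
        ll, beta, XtVX = self._profile(res.x)
        D, sigma2 = _theta_to_varparams(res.x)
        cov_beta = np.linalg.inv(XtVX)
        params = LMMParams(beta=beta, D=D, sigma2=sigma2)
        return LMMResults(
            model=self,
            params=params,
            cov_beta=cov_beta,
            llf=ll,
            converged=bool(res.success),
            n_iter=int(res.nit),
            message=str(res.message),
        )


@dataclass
class LMMResults:
    """Maximum-likelihood fit of the naive mixed model."""

    model: EngagementLMM
    params: LMMParams
    cov_beta: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def beta(self) -> np.ndarray:
        return self.params.beta

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def predict_mean(self, times) -> tuple[np.ndarray, np.ndarray]:
        """Population-mean trajectory and delta-method SEs on a week grid."""
        from .joint import predict_mean_trajectory

        return predict_mean_trajectory(self.beta, self.cov_beta, times)

    def summary(self) -> str:
        from scipy.stats import norm

        lines = ["Linear mixed model (ML), quadratic week trend, random intercept+slope"]
        lines.append(f"log-likelihood {self.llf:.4f}   converged: {self.converged}")
        lines.append(f"{'':<14}{'estimate':>12}{'SE':>12}{'z':>9}{'P>|z|':>9}")
        names = ["intercept", "week", "week^2"]
        for name, est, se in zip(names, self.beta, self.se_beta):
            z = est / se
            p = 2 * norm.sf(abs(z))
            lines.append(f"{name:<14}{est:>12.4f}{se:>12.4f}{z:>9.2f}{p:>9.3g}")
        d = self.params.D
        lines.append(
            f"D: var(b0)={d[0, 0]:.4f} var(b1)={d[1, 1]:.5f} cov={d[0, 1]:.5f}; "
            f"sigma^2={self.params.sigma2:.4f}"
        )
        return "\n".join(lines)


def fit_lmm(cohort: LinkedCohort, init: LMMParams | None = None) -> LMMResults:
    """Convenience wrapper: ``EngagementLMM(cohort).fit(init)``."""
    return EngagementLMM(cohort).fit(start=init)
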