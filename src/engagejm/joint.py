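"""Shared-parameter joint model of engagement trajectories and dropout.

The longitudinal submodel is the quadratic-trend linear mixed model

    y_i(t) = m_i(t) + e_i(t),      m_i(t) = beta0 + beta1*t + beta2*t^2
                                            + b0_i + b1_i*t,

with ``b_i ~ N(0, D)`` and ``e_i(t) ~ N(0, sigma^2)``.  The dropout
submodel is a proportional-hazards model in which the *error-free* current
engagement value enters as a time-varying covariate,

    h_i(t) = lambda(t) * exp{gamma' w_i + alpha * m_i(t)},

with a piecewise-constant baseline hazard ``lambda(t)``.  Because the same
random effects ``b_i`` drive both processes, dropout may depend on the
(unobserved) engagement level and the missingness it causes is handled
correctly: maximising the joint likelihood gives unbiased trajectory
estimates where a standalone mixed model is biased.

The marginal likelihood integrates the bivariate random effects out by
adaptive Gauss-Hermite quadrature: for each subject the integrand is
recentred at the posterior mode of ``b_i`` and rescaled by the posterior
curvature, so a modest number of nodes per dimension suffices even with
many repeated measures.  All subject-level quantities are evaluated as
vectorised array operations across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from ._integrate import gauss_legendre
from .data import LinkedCohort, build_design, SURVIVAL_DESIGN_COLUMNS

__all__ = [
    "JointParams",
    "JointModel",
    "JointResults",
    "fit_joint",
    "hazard_ratio",
    "percent_risk_change",
    "predict_mean_trajectory",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class JointParams:
    """Full parameter vector of the shared-parameter joint model."""

    beta: np.ndarray        # (3,) fixed effects of the quadratic week trend
    D: np.ndarray           # (2, 2) random-effects covariance
    sigma2: float           # residual variance
    gamma: np.ndarray       # (5,) hazard coefficients for the baseline covariates
    alpha: float            # association: log hazard ratio per day/week of m_i(t)
    log_lambda: np.ndarray  # (K,) log baseline rates on the knot grid
    knots: np.ndarray       # (K+1,) strictly increasing, spanning [0, max event time]

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.log_lambda = np.asarray(self.log_lambda, dtype=float)
        self.knots = np.asarray(self.knots, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if np.any(np.linalg.eigvalsh(self.D) <= 0):
            raise ValueError("D must be positive definite")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if len(self.log_lambda) != len(self.knots) - 1:
            raise ValueError("need one baseline log-rate per inter-knot piece")


def hazard_ratio(coef: float) -> float:
    """Hazard ratio exp(coef) for a log-hazard coefficient."""
    return float(np.exp(coef))


def percent_risk_change(coef: float) -> float:
    """Percent decrease in risk, 100*(1 - exp(coef)); negative for risk increases."""
    return float(100.0 * (1.0 - np.exp(coef)))


def predict_mean_trajectory(beta, cov_beta, times):
    """Population-mean trajectory ``beta0 + beta1*t + beta2*t^2`` with delta-method SEs.

    Random effects are set to zero (fixed-effects-only prediction).  Returns
    ``(values, se)``; ``se`` is None when no covariance is supplied.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("prediction times must be >= 0")
    beta = np.asarray(beta, dtype=float)
    J = np.column_stack([np.ones_like(times), times, times**2])
    values = J @ beta
    if cov_beta is None:
        return values, None
    se = np.sqrt(np.einsum("ij,jk,ik->i", J, np.asarray(cov_beta, dtype=float), J))
    return values, se


def _default_knots(event_time: np.ndarray, event: np.ndarray, n_pieces: int) -> np.ndarray:
    """Knots at empirical event-time quantiles, spanning [0, max follow-up]."""
    tmax = float(event_time.max())
    obs = np.sort(event_time[event > 0])
    if len(obs) >= n_pieces:
        interior = np.quantile(obs, np.linspace(0, 1, n_pieces + 1)[1:-1])
    else:
        interior = np.linspace(0, tmax, n_pieces + 1)[1:-1]
    knots = np.concatenate([[0.0], interior, [tmax]])
    knots = np.unique(knots)
    if len(knots) < n_pieces + 1:  # ties in the quantiles: fall back to equal width
        knots = np.linspace(0.0, tmax, n_pieces + 1)
    return knots


class JointModel:
    """Shared-parameter joint model on a :class:`LinkedCohort`.

    Parameters
    ----------
    cohort : LinkedCohort
    n_pieces : int
        Number of piecewise-constant baseline-hazard pieces (knots placed at
        empirical event-time quantiles unless ``knots`` is given).
    knots : array-like, optional
        Explicit baseline knots ``0 = s_0 < ... < s_K``.
    quad_order : int
        Gauss-Hermite nodes per random-effect dimension (adaptive rule).
    gl_points : int
        Gauss-Legendre nodes per baseline piece for the cumulative-hazard
        integral (the integrand exp{alpha*m_i(s)} is a smooth exp-quadratic,
        resolved to near machine precision at moderate order).
    """

    def __init__(
        self,
        cohort: LinkedCohort,
        n_pieces: int = 5,
        knots=None,
        quad_order: int = 9,
        gl_points: int = 10,
    ):
        self.cohort = cohort
        design = build_design(cohort)
        self.design = design
        n = design.n_subjects
        if design.event.sum() < 1:
            raise ValueError("joint fitting requires at least one observed dropout event")

        # --- padded longitudinal arrays -----------------------------------
        counts = np.bincount(design.subject_index, minlength=n)
        J = int(counts.max())
        self._cnt = counts.astype(float)
        self._tl = np.zeros((n, J))
        self._yl = np.zeros((n, J))
        self._mask = np.zeros((n, J))
        pos = np.zeros(n, dtype=int)
        for t, y, i in zip(design.times, design.y, design.subject_index):
            self._tl[i, pos[i]] = t
            self._yl[i, pos[i]] = y
            self._mask[i, pos[i]] = 1.0
            pos[i] += 1
        # residual-information blocks sum_j z_j z_j' per subject (constant)
        self._A = np.empty((n, 2, 2))
        self._A[:, 0, 0] = self._mask.sum(1)
        self._A[:, 0, 1] = self._A[:, 1, 0] = (self._mask * self._tl).sum(1)
        self._A[:, 1, 1] = (self._mask * self._tl**2).sum(1)

        # --- survival arrays ----------------------------------------------
        self._Tev = design.event_time
        self._delta = design.event
        self._W = design.W

        if knots is None:
            knots = _default_knots(self._Tev, self._delta, n_pieces)
        self.knots = np.asarray(knots, dtype=float)
        if self.knots[0] != 0.0 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing and start at 0")
        if self.knots[-1] < self._Tev.max():
            raise ValueError("knots must span [0, max event time]")
        self.n_pieces = len(self.knots) - 1

        # --- Gauss-Legendre grid for the cumulative-hazard integral -------
        x, wq = gauss_legendre(gl_points)
        K, Q = self.n_pieces, gl_points
        lo = np.minimum(self.knots[:-1][None, :], self._Tev[:, None])       # (n, K)
        hi = np.minimum(self.knots[1:][None, :], self._Tev[:, None])       # (n, K)
        half = 0.5 * (hi - lo)
        mid = 0.5 * (hi + lo)
        self._Snodes = (mid[:, :, None] + half[:, :, None] * x).reshape(n, K * Q)
        self._Sw = (half[:, :, None] * wq).reshape(n, K * Q)
        self._piece_node = np.repeat(np.arange(K), Q)
        self._pieceT = np.clip(np.searchsorted(self.knots, self._Tev, side="right") - 1, 0, K - 1)

        self.quad_order = int(quad_order)
        self._mode_cache = np.zeros((n, 2))
        self._n_params = 13 + self.n_pieces

    # ------------------------------------------------------------------
    # parameter packing: theta = (beta, logchol(D), log sigma2, gamma,
    #                             alpha, log lambda)
    # ------------------------------------------------------------------

    def pack(self, params: JointParams) -> np.ndarray:
        L = np.linalg.cholesky(params.D)
        return np.concatenate(
            [
                params.beta,
                [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])],
                [np.log(params.sigma2)],
                params.gamma,
                [params.alpha],
                params.log_lambda,
            ]
        )

    def unpack(self, theta: np.ndarray) -> JointParams:
        L = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
        return JointParams(
            beta=theta[0:3].copy(),
            D=L @ L.T,
            sigma2=float(np.exp(theta[6])),
            gamma=theta[7:12].copy(),
            alpha=float(theta[12]),
            log_lambda=theta[13:].copy(),
            knots=self.knots.copy(),
        )

    def _parts(self, theta: np.ndarray) -> dict:
        beta = theta[0:3]
        L = np.array([[np.exp(theta[3]), 0.0], [theta[4], np.exp(theta[5])]])
        D = L @ L.T
        Dinv = np.linalg.inv(D)
        sigma2 = float(np.exp(theta[6]))
        gamma = theta[7:12]
        alpha = float(theta[12])
        loglam = theta[13:]
        gw = self._W @ gamma                                      # (n,)
        mfix_l = beta[0] + beta[1] * self._tl + beta[2] * self._tl**2
        r0 = (self._yl - mfix_l) * self._mask                     # fixed-effect residuals
        mfix_s = beta[0] + beta[1] * self._Snodes + beta[2] * self._Snodes**2
        mfix_T = beta[0] + beta[1] * self._Tev + beta[2] * self._Tev**2
        # hazard-integrand prefactor: everything except exp{alpha*(b0 + b1*s)}
        u_base = self._Sw * np.exp(theta[13:][self._piece_node] + alpha * mfix_s + gw[:, None])
        return dict(
            beta=beta, D=D, Dinv=Dinv, logdetD=float(np.log(np.linalg.det(D))),
            sigma2=sigma2, gamma=gamma, alpha=alpha, loglam=loglam,
            mfix_T=mfix_T, u_base=u_base,
            logh_base=loglam[self._pieceT] + gw,
            # sufficient statistics of the Gaussian part: residual sum of
            # squares is quadratic in b with these per-subject coefficients
            s_r2=(r0**2).sum(1), s_r=r0.sum(1), s_rt=(r0 * self._tl).sum(1),
        )

    # ------------------------------------------------------------------
    # complete-data log-likelihood given b, and its b-derivatives
    # ------------------------------------------------------------------

    def _value_nodes(self, pt: dict, B: np.ndarray) -> np.ndarray:
        """log f(y_i, T_i, delta_i | b) + log N(b; 0, D) for B of shape (n, M, 2)."""
        b0 = B[..., 0]
        b1 = B[..., 1]
        A = self._A
        rss = (
            pt["s_r2"][:, None]
            - 2.0 * (b0 * pt["s_r"][:, None] + b1 * pt["s_rt"][:, None])
            + b0**2 * A[:, None, 0, 0]
            + 2.0 * b0 * b1 * A[:, None, 0, 1]
            + b1**2 * A[:, None, 1, 1]
        )
        ll_long = -0.5 * (
            rss / pt["sigma2"] + self._cnt[:, None] * (_LOG2PI + np.log(pt["sigma2"]))
        )
        a = pt["alpha"]
        E = np.exp(a * b1[:, :, None] * self._Snodes[:, None, :])
        H = np.einsum("nmq,nq->nm", E, pt["u_base"]) * np.exp(a * b0)
        logh = pt["logh_base"][:, None] + a * (pt["mfix_T"][:, None] + b0 + b1 * self._Tev[:, None])
        ll_surv = self._delta[:, None] * logh - H
        Di = pt["Dinv"]
        quad = b0**2 * Di[0, 0] + 2.0 * b0 * b1 * Di[0, 1] + b1**2 * Di[1, 1]
        ll_prior = -0.5 * (2 * _LOG2PI + pt["logdetD"] + quad)
        return ll_long + ll_surv + ll_prior

    def _derivs(self, pt: dict, b: np.ndarray):
        """Gradient and negative Hessian (both PD-guaranteed) of the b-posterior log-density."""
        b0 = b[:, 0]
        b1 = b[:, 1]
        A = self._A
        s2 = pt["sigma2"]
        g0 = (pt["s_r"] - b0 * A[:, 0, 0] - b1 * A[:, 0, 1]) / s2
        g1 = (pt["s_rt"] - b0 * A[:, 0, 1] - b1 * A[:, 1, 1]) / s2
        a = pt["alpha"]
        u = pt["u_base"] * np.exp(a * (b0[:, None] + b1[:, None] * self._Snodes))
        uS = u * self._Snodes
        su, suS, suSS = u.sum(1), uS.sum(1), (uS * self._Snodes).sum(1)
        g0 += self._delta * a - a * su
        g1 += self._delta * a * self._Tev - a * suS
        prior = b @ pt["Dinv"]
        grad = np.stack([g0, g1], axis=1) - prior
        negH = self._A / s2 + pt["Dinv"]
        negH = negH.copy()
        negH[:, 0, 0] += a * a * su
        negH[:, 0, 1] += a * a * suS
        negH[:, 1, 0] += a * a * suS
        negH[:, 1, 1] += a * a * suSS
        return grad, negH

    def _modes(self, pt: dict, warm: np.ndarray, tol: float = 1e-10, maxiter: int = 60):
        """Vectorised Newton ascent to the posterior mode of b for every subject."""
        b = warm.copy()
        phi = self._value_nodes(pt, b[:, None, :])[:, 0]
        for _ in range(maxiter):
            grad, negH = self._derivs(pt, b)
            det = negH[:, 0, 0] * negH[:, 1, 1] - negH[:, 0, 1] ** 2
            step = np.empty_like(b)
            step[:, 0] = (negH[:, 1, 1] * grad[:, 0] - negH[:, 0, 1] * grad[:, 1]) / det
            step[:, 1] = (-negH[:, 0, 1] * grad[:, 0] + negH[:, 0, 0] * grad[:, 1]) / det
            scale = np.ones(len(b))
            for _ in range(40):
                cand = b + scale[:, None] * step
                phic = self._value_nodes(pt, cand[:, None, :])[:, 0]
                bad = phic < phi - 1e-13
                if not bad.any():
                    break
                scale[bad] *= 0.5
            moved = scale[:, None] * step
            b = b + np.where((phic >= phi - 1e-13)[:, None], moved, 0.0)
            phi = np.maximum(phi, phic)
            if np.max(np.abs(moved)) < tol:
                break
        _, negH = self._derivs(pt, b)
        return b, negH

    # ------------------------------------------------------------------
    # marginal likelihood by adaptive Gauss-Hermite quadrature
    # ------------------------------------------------------------------

    def _gh_rule(self, order: int):
        x, w = np.polynomial.hermite.hermgauss(order)
        z1, z2 = np.meshgrid(x, x, indexing="ij")
        Z = np.column_stack([z1.ravel(), z2.ravel()])
        logw = np.add.outer(np.log(w), np.log(w)).ravel()
        return Z, logw, (Z**2).sum(1)

    def _subject_logliks(self, theta: np.ndarray, quad_order: int | None = None) -> np.ndarray:
        pt = self._parts(theta)
        order = self.quad_order if quad_order is None else int(quad_order)
        mu, negH = self._modes(pt, self._mode_cache)
        self._mode_cache = mu
        det = negH[:, 0, 0] * negH[:, 1, 1] - negH[:, 0, 1] ** 2
        S00 = negH[:, 1, 1] / det
        S01 = -negH[:, 0, 1] / det
        S11 = negH[:, 0, 0] / det
        L00 = np.sqrt(S00)
        L10 = S01 / L00
        L11 = np.sqrt(np.maximum(S11 - L10**2, 1e-300))
        Z, logw, normsq = self._gh_rule(order)
        sq2 = np.sqrt(2.0)
        B = np.empty((len(mu), len(Z), 2))
        B[:, :, 0] = mu[:, 0:1] + sq2 * L00[:, None] * Z[:, 0]
        B[:, :, 1] = mu[:, 1:2] + sq2 * (L10[:, None] * Z[:, 0] + L11[:, None] * Z[:, 1])
        g = self._value_nodes(pt, B)
        return np.log(2.0) + np.log(L00 * L11) + logsumexp(logw + normsq + g, axis=1)

    def loglike(self, params: JointParams, quad_order: int | None = None) -> float:
        """Marginal joint log-likelihood, random effects integrated out."""
        ll = self._subject_logliks(self.pack(params), quad_order)
        if not np.all(np.isfinite(ll)):
            bad = self.design.subject_ids[~np.isfinite(ll)][0]
            raise FloatingPointError(f"non-finite marginal likelihood for subject {bad!r}")
        return float(ll.sum())

    def subject_loglik_given_b(self, params: JointParams, subject_id: str, b) -> float | np.ndarray:
        """Complete-data log-likelihood of one subject at fixed random effects.

        ``log[prod_j N(y_ij; m_i, sigma2) * h_i(T_i)^delta_i * exp(-H_i(T_i))]``
        — the random-effects prior is *not* included.  ``b`` may be a single
        pair or an ``(M, 2)`` array.
        """
        idx = int(np.nonzero(self.design.subject_ids == str(subject_id))[0][0])
        pt = self._parts(self.pack(params))
        b_arr = np.atleast_2d(np.asarray(b, dtype=float))
        B = b_arr[None, :, :]
        sl = slice(idx, idx + 1)
        sub = _SubjectView(self, sl)
        val = sub.value_nodes(pt, B)[0]
        return float(val[0]) if np.asarray(b).ndim == 1 else val

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------

    def _start_params(self) -> JointParams:
        from .lmm import EngagementLMM
        from .survival import CoxPH

        lmm = EngagementLMM(self.cohort).fit()
        cox = CoxPH(self.cohort.survival).fit()
        # occurrence/exposure rates per baseline piece
        lo = np.minimum(self.knots[:-1][None, :], self._Tev[:, None])
        hi = np.minimum(self.knots[1:][None, :], self._Tev[:, None])
        exposure = np.maximum(hi - lo, 0.0).sum(0)
        in_piece = (self._pieceT[:, None] == np.arange(self.n_pieces)) & (self._delta[:, None] > 0)
        events = in_piece.sum(0).astype(float)
        rates = np.where(exposure > 0, np.maximum(events, 0.5) / np.maximum(exposure, 1e-8), 1e-3)
        D0 = lmm.params.D
        if np.any(np.linalg.eigvalsh(D0) < 1e-8):
            D0 = D0 + 1e-4 * np.eye(2)
        return JointParams(
            beta=lmm.beta,
            D=D0,
            sigma2=lmm.params.sigma2,
            gamma=cox.gamma,
            alpha=0.0,
            log_lambda=np.log(rates),
            knots=self.knots,
        )

    def fit(
        self,
        start: JointParams | None = None,
        maxiter: int = 400,
        se: bool = True,
        fix_alpha: float | None = None,
        restarts: int = 2,
    ) -> "JointResults":
        """Maximise the marginal joint likelihood; returns a :class:`JointResults`.

        ``fix_alpha`` profiles the fit with the association frozen at the
        given value (``fix_alpha=0`` makes the model factorise into the
        standalone mixed model and a piecewise-exponential hazard model).
        """
        if start is None:
            start = self._start_params()
        theta0 = self.pack(start)
        if fix_alpha is not None:
            theta0[12] = float(fix_alpha)
        free = np.ones(self._n_params, dtype=bool)
        if fix_alpha is not None:
            free[12] = False
        full = theta0.copy()

        self._mode_cache = np.zeros_like(self._mode_cache)

        def negll(x):
            full[free] = x
            return -float(self._subject_logliks(full).sum())

        bounds = self._bounds()[free]
        x0 = theta0[free]
        res = None
        n_iter = 0
        for attempt in range(restarts + 1):
            # precondition: curvature differs by orders of magnitude across
            # parameters (week^2 coefficient vs association), so optimise in
            # coordinates scaled by the inverse root diagonal curvature
            scale = self._diag_scale(negll, x0)
            center = x0.copy()

            def negll_scaled(yv):
                return negll(center + scale * yv)

            scaled_bounds = [
                (
                    (lo - c) / s if np.isfinite(lo) else -np.inf,
                    (hi - c) / s if np.isfinite(hi) else np.inf,
                )
                for (lo, hi), c, s in zip(bounds, center, scale)
            ]
            res = optimize.minimize(
                negll_scaled,
                np.zeros_like(x0),
                method="L-BFGS-B",
                jac="3-point",
                bounds=scaled_bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-5},
            )
            n_iter += int(res.nit)
            x0 = center + scale * res.x
            if res.success:
                break
            # restart quasi-Newton from the incumbent on line-search failure
        res.x = x0
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"joint fit did not converge: {res.message}", RuntimeWarning)
        theta_hat = full.copy()
        theta_hat[free] = res.x
        llf = -float(res.fun)

        cov_theta = None
        se_available = False
        if se:
            H = self._numeric_hessian(negll, res.x)
            H = 0.5 * (H + H.T)
            try:
                cov_free = np.linalg.inv(H)
                if np.all(np.diag(cov_free) > 0):
                    cov_theta = np.zeros((self._n_params, self._n_params))
                    cov_theta[np.ix_(free, free)] = cov_free
                    se_available = True
                else:
                    warnings.warn("observed information not positive definite; SEs unavailable",
                                  RuntimeWarning)
            except np.linalg.LinAlgError:
                warnings.warn("observed information singular; SEs unavailable", RuntimeWarning)

        params = self.unpack(theta_hat)
        pt = self._parts(theta_hat)
        modes, _ = self._modes(pt, self._mode_cache)
        ranef = pd.DataFrame(
            {"subject_id": self.design.subject_ids, "b0": modes[:, 0], "b1": modes[:, 1]}
        )
        return JointResults(
            model=self,
            params=params,
            llf=llf,
            converged=converged,
            n_iter=n_iter,
            cov_theta=cov_theta,
            se_available=se_available,
            random_effects=ranef,
            fixed_alpha=fix_alpha,
            message=str(res.message),
        )

    @staticmethod
    def _diag_scale(f, x: np.ndarray) -> np.ndarray:
        """Inverse-root diagonal curvature of ``f`` at ``x`` (for preconditioning)."""
        h = 1e-4 * np.maximum(np.abs(x), 1.0)
        f0 = f(x)
        curv = np.empty_like(x)
        for j in range(len(x)):
            e = np.zeros_like(x)
            e[j] = h[j]
            curv[j] = (f(x + e) + f(x - e) - 2 * f0) / h[j] ** 2
        return 1.0 / np.sqrt(np.clip(np.abs(curv), 1e-2, None))

    def _bounds(self) -> np.ndarray:
        b = np.full((self._n_params, 2), (-np.inf, np.inf))
        b[3] = b[5] = (-10.0, 5.0)        # log-cholesky diagonals of D
        b[6] = (-10.0, 10.0)              # log sigma2
        b[13:] = (-20.0, 5.0)             # log baseline rates
        return b

    @staticmethod
    def _numeric_hessian(f, x: np.ndarray) -> np.ndarray:
        """Central-difference Hessian; per-parameter steps eps^(1/3)*max(|x|,1)."""
        p = len(x)
        h = np.cbrt(np.finfo(float).eps) * np.maximum(np.abs(x), 1.0)
        H = np.empty((p, p))
        f0 = f(x)
        for j in range(p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[j, j] = (f(x + ej) + f(x - ej) - 2 * f0) / h[j] ** 2
            for k in range(j + 1, p):
                ek = np.zeros(p)
                ek[k] = h[k]
                H[j, k] = H[k, j] = (
                    f(x + ej + ek) - f(x + ej - ek) - f(x - ej + ek) + f(x - ej - ek)
                ) / (4 * h[j] * h[k])
        return H


class _SubjectView:
    """Single-subject slice sharing :class:`JointModel`'s vectorised kernels."""

    def __init__(self, model: JointModel, sl: slice):
        self._m = model
        self._sl = sl

    def value_nodes(self, pt: dict, B: np.ndarray) -> np.ndarray:
        m = self._m
        sl = self._sl
        b0 = B[..., 0]
        b1 = B[..., 1]
        A = m._A[sl]
        rss = (
            pt["s_r2"][sl][:, None]
            - 2.0 * (b0 * pt["s_r"][sl][:, None] + b1 * pt["s_rt"][sl][:, None])
            + b0**2 * A[:, None, 0, 0]
            + 2.0 * b0 * b1 * A[:, None, 0, 1]
            + b1**2 * A[:, None, 1, 1]
        )
        ll_long = -0.5 * (
            rss / pt["sigma2"] + m._cnt[sl][:, None] * (_LOG2PI + np.log(pt["sigma2"]))
        )
        a = pt["alpha"]
        E = np.exp(a * b1[:, :, None] * m._Snodes[sl][:, None, :])
        H = np.einsum("nmq,nq->nm", E, pt["u_base"][sl]) * np.exp(a * b0)
        logh = pt["logh_base"][sl][:, None] + a * (
            pt["mfix_T"][sl][:, None] + b0 + b1 * m._Tev[sl][:, None]
        )
        return ll_long + m._delta[sl][:, None] * logh - H


@dataclass
class JointResults:
    """Maximum-likelihood fit of the shared-parameter joint model."""

    model: JointModel
    params: JointParams
    llf: float
    converged: bool
    n_iter: int
    cov_theta: np.ndarray | None
    se_available: bool
    random_effects: pd.DataFrame = field(repr=False, default=None)
    fixed_alpha: float | None = None
    message: str = ""

    # indices of theta blocks: beta 0:3, gamma 7:12, alpha 12
    @property
    def se_beta(self) -> np.ndarray | None:
        if not self.se_available:
            return None
        return np.sqrt(np.diag(self.cov_theta)[0:3])

    @property
    def cov_beta(self) -> np.ndarray | None:
        if not self.se_available:
            return None
        return self.cov_theta[0:3, 0:3]

    @property
    def se_gamma(self) -> np.ndarray | None:
        if not self.se_available:
            return None
        return np.sqrt(np.diag(self.cov_theta)[7:12])

    @property
    def se_alpha(self) -> float | None:
        if not self.se_available or self.fixed_alpha is not None:
            return None
        return float(np.sqrt(np.diag(self.cov_theta)[12]))

    @property
    def alpha(self) -> float:
        return self.params.alpha

    def alpha_hazard_ratio(self) -> float:
        """exp(alpha): dropout hazard ratio per extra day/week of true engagement."""
        return hazard_ratio(self.params.alpha)

    def predict_mean(self, times):
        """Fixed-effects population-mean engagement with delta-method SEs."""
        return predict_mean_trajectory(self.params.beta, self.cov_beta, times)

    def pvalues(self) -> dict:
        out = {}
        if not self.se_available:
            return out
        for name, est, se in self._coef_rows():
            z = est / se if se and se > 0 else np.nan
            out[name] = float(2 * norm.sf(abs(z)))
        return out

    def _coef_rows(self):
        names = ["intercept", "week", "week^2", *SURVIVAL_DESIGN_COLUMNS, "alpha"]
        ests = [*self.params.beta, *self.params.gamma, self.params.alpha]
        if self.se_available:
            ses = [*self.se_beta, *self.se_gamma,
                   self.se_alpha if self.se_alpha is not None else np.nan]
        else:
            ses = [np.nan] * 9
        return list(zip(names, ests, ses))

    def summary(self) -> str:
        lines = ["Shared-parameter joint model (quadratic trend; current-value association)"]
        lines.append(
            f"log-likelihood {self.llf:.4f}   converged: {self.converged}   "
            f"baseline pieces: {self.model.n_pieces}   GH order: {self.model.quad_order}"
        )
        lines.append(f"{'':<16}{'estimate':>12}{'SE':>10}  {'P>|z|':>10}")
        for name, est, se in self._coef_rows():
            if np.isfinite(se):
                p = 2 * norm.sf(abs(est / se))
                lines.append(f"{name:<16}{est:>12.4f}{se:>10.4f}  {p:>10.3g}")
            else:
                lines.append(f"{name:<16}{est:>12.4f}{'--':>10}  {'--':>10}")
        d = self.params.D
        lines.append(
            f"D: var(b0)={d[0, 0]:.4f} var(b1)={d[1, 1]:.5f} cov={d[0, 1]:.5f}; "
            f"sigma^2={self.params.sigma2:.4f}"
        )
        pct = percent_risk_change(self.params.alpha)
        direction = "lower" if pct >= 0 else "higher"
        lines.append(
            f"alpha hazard ratio exp(alpha) = {self.alpha_hazard_ratio():.3f} "
            f"({abs(pct):.0f}% {direction} dropout risk per day/week of engagement)"
        )
        return "\n".join(lines)


def fit_joint(cohort: LinkedCohort, init: JointParams | None = None, **controls) -> JointResults:
    """Convenience wrapper: ``JointModel(cohort, **controls).fit(start=init)``."""
    fit_kwargs = {k: controls.pop(k) for k in ("se", "fix_alpha", "maxiter", "restarts")
                  if k in controls}
    return JointModel(cohort, **controls).fit(start=init, **fit_kwargs)
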