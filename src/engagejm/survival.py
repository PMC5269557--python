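"""Naive time-to-event pieces: Kaplan-Meier dropout curve and baseline Cox model.

These are the "separate models" side of the comparison: dropout analysed on
its own with baseline covariates only, with no link to the engagement
trajectory.  Conventions used throughout: left-continuous risk sets
(subjects censored at t remain at risk for an event at t), Breslow handling
of tied event times (ties are common on a weekly grid), and the step-function
median (earliest time with S(t) <= 0.5, no interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import LinkedCohort, SurvivalDataset, survival_design, SURVIVAL_DESIGN_COLUMNS

__all__ = ["KMEstimate", "km_estimate", "CoxPH", "CoxResults", "cox_partial_loglik", "fit_cox"]


@dataclass
class KMEstimate:
    """Product-limit estimate of the dropout survival function."""

    event_times: np.ndarray   # sorted distinct times with >= 1 observed event
    survival: np.ndarray      # S(t) immediately after each event time
    n_risk: np.ndarray        # risk-set size just before each event time
    n_events: np.ndarray      # events at each time
    median: float | None      # earliest event time with S <= 0.5, None if never reached

    def survival_at(self, t) -> np.ndarray:
        """Step-function S(t); S(0) = 1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def plot(self, ax=None, **kwargs):  # pragma: no cover - convenience render
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ts = np.concatenate([[0.0], np.repeat(self.event_times, 2)])
        ss = np.concatenate([np.repeat(np.concatenate([[1.0], self.survival[:-1]]), 2), [self.survival[-1]]]) \
            if len(self.event_times) else np.array([1.0])
        ax.step(np.concatenate([[0.0], self.event_times]), np.concatenate([[1.0], self.survival]),
                where="post", **kwargs)
        ax.set_xlabel("weeks since enrollment")
        ax.set_ylabel("probability still providing data")
        ax.set_ylim(0, 1.05)
        return ax


def km_estimate(survival: SurvivalDataset) -> KMEstimate:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j / r_j)."""
    times = survival.frame["event_time_weeks"].to_numpy()
    events = survival.frame["event"].to_numpy()
    distinct = np.unique(times[events == 1])
    surv = []
    n_risk = []
    n_events = []
    s = 1.0
    for t in distinct:
        r = int(np.sum(times >= t))  # censored at t still at risk at t
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / r
        n_risk.append(r)
        n_events.append(d)
        surv.append(s)
    surv = np.asarray(surv)
    median = None
    if len(distinct):
        hit = np.nonzero(surv <= 0.5)[0]
        if len(hit):
            median = float(distinct[hit[0]])
    return KMEstimate(
        event_times=distinct,
        survival=surv,
        n_risk=np.asarray(n_risk),
        n_events=np.asarray(n_events),
        median=median,
    )


# -- Cox proportional hazards ------------------------------------------------


def _event_blocks(times: np.ndarray, events: np.ndarray):
    """Distinct event times with event counts, covariate sums filled by caller."""
    distinct = np.unique(times[events == 1])
    at_risk = [times >= t for t in distinct]
    at_event = [(times == t) & (events == 1) for t in distinct]
    return distinct, at_risk, at_event


def cox_partial_loglik(gamma, survival: SurvivalDataset, covariates: np.ndarray) -> float:
    """Breslow partial log-likelihood at coefficient vector ``gamma``."""
    gamma = np.asarray(gamma, dtype=float)
    times = survival.frame["event_time_weeks"].to_numpy()
    events = survival.frame["event"].to_numpy()
    eta = covariates @ gamma
    ll = 0.0
    _, at_risk, at_event = _event_blocks(times, events)
    for risk, ev in zip(at_risk, at_event):
        d = int(ev.sum())
        ll += float(eta[ev].sum()) - d * float(np.log(np.sum(np.exp(eta[risk]))))
    return ll


class CoxPH:
    """Cox proportional-hazards model of time to dropout on baseline covariates.

    ``covariates`` defaults to the package's fixed hazard design
    (age_centered, male, race dummies with white reference).  Fitted by
    Newton-Raphson on the Breslow partial likelihood with step-halving.
    """

    def __init__(self, survival: SurvivalDataset, covariates: np.ndarray | None = None,
                 names: tuple[str, ...] | None = None):
        self.survival = survival
        if covariates is None:
            covariates, _ = survival_design(survival)
            names = SURVIVAL_DESIGN_COLUMNS
        self.covariates = np.asarray(covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        self.names = tuple(names) if names is not None else tuple(
            f"x{i}" for i in range(self.covariates.shape[1])
        )
        if len(self.covariates) != survival.n_subjects:
            raise ValueError("covariate rows must match the survival table")
        events = survival.frame["event"].to_numpy()
        if events.sum() < 1:
            raise ValueError("Cox fitting requires at least one observed event")
        # collinearity among non-constant columns is a rank error; all-zero
        # columns are allowed (their coefficient is identically 0 by symmetry)
        live = np.ptp(self.covariates, axis=0) > 0
        if live.any() and np.linalg.matrix_rank(self.covariates[:, live]) < int(live.sum()):
            raise np.linalg.LinAlgError("collinear covariates in Cox design")
        self._live = live

    @classmethod
    def from_cohort(cls, cohort: LinkedCohort) -> "CoxPH":
        return cls(cohort.survival)

    def loglike(self, gamma) -> float:
        return cox_partial_loglik(gamma, self.survival, self.covariates)

    def _score_info(self, gamma):
        X = self.covariates
        times = self.survival.frame["event_time_weeks"].to_numpy()
        events = self.survival.frame["event"].to_numpy()
        eta = X @ gamma
        expeta = np.exp(eta)
        ll = 0.0
        score = np.zeros(X.shape[1])
        info = np.zeros((X.shape[1], X.shape[1]))
        _, at_risk, at_event = _event_blocks(times, events)
        for risk, ev in zip(at_risk, at_event):
            d = int(ev.sum())
            w = expeta[risk]
            s0 = float(w.sum())
            s1 = w @ X[risk]
            s2 = (X[risk] * w[:, None]).T @ X[risk]
            xbar = s1 / s0
            ll += float(eta[ev].sum()) - d * float(np.log(s0))
            score += X[ev].sum(axis=0) - d * xbar
            info += d * (s2 / s0 - np.outer(xbar, xbar))
        return ll, score, info

    def fit(self, maxiter: int = 50, tol: float = 1e-10) -> "CoxResults":
        p = self.covariates.shape[1]
        gamma = np.zeros(p)
        ll, score, info = self._score_info(gamma)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            step = np.linalg.pinv(info) @ score
            new = gamma + step
            new_ll, new_score, new_info = self._score_info(new)
            halves = 0
            while new_ll < ll and halves < 30:
                step *= 0.5
                new = gamma + step
                new_ll, new_score, new_info = self._score_info(new)
                halves += 1
            if new_ll < ll:
                break
            improved = new_ll - ll
            gamma, ll, score, info = new, new_ll, new_score, new_info
            if improved < tol:
                converged = True
                break
        if np.any(np.abs(gamma) > 50):
            warnings.warn(
                "Cox estimates diverging: likely monotone partial likelihood (perfect separation)",
                RuntimeWarning,
            )
            converged = False
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        baseline_times, baseline_cumhaz = self._breslow_baseline(gamma)
        return CoxResults(
            model=self,
            gamma=gamma,
            cov_gamma=cov,
            se_gamma=se,
            partial_loglik=ll,
            converged=converged,
            n_iter=it,
            baseline_times=baseline_times,
            baseline_cumhaz=baseline_cumhaz,
        )

    def _breslow_baseline(self, gamma):
        times = self.survival.frame["event_time_weeks"].to_numpy()
        events = self.survival.frame["event"].to_numpy()
        expeta = np.exp(self.covariates @ gamma)
        distinct, at_risk, at_event = _event_blocks(times, events)
        increments = [ev.sum() / expeta[risk].sum() for risk, ev in zip(at_risk, at_event)]
        return distinct, np.cumsum(increments)


@dataclass
class CoxResults:
    """Newton-Raphson fit of the Breslow partial likelihood."""

    model: CoxPH
    gamma: np.ndarray
    cov_gamma: np.ndarray
    se_gamma: np.ndarray
    partial_loglik: float
    converged: bool
    n_iter: int
    baseline_times: np.ndarray = field(repr=False, default=None)
    baseline_cumhaz: np.ndarray = field(repr=False, default=None)

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.gamma)

    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_gamma > 0, self.gamma / self.se_gamma, 0.0)
        return 2 * norm.sf(np.abs(z))

    def cumhaz_at(self, t) -> np.ndarray:
        """Breslow baseline cumulative hazard step function."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.baseline_times, t, side="right")
        h = np.concatenate([[0.0], self.baseline_cumhaz])
        return h[idx]

    def summary(self) -> str:
        lines = ["Cox proportional hazards (Breslow ties), baseline covariates only"]
        lines.append(f"partial log-likelihood {self.partial_loglik:.4f}   converged: {self.converged}")
        lines.append(f"{'':<16}{'coef':>10}{'HR':>9}{'SE':>10}{'P>|z|':>9}")
        for name, g, se, p in zip(self.model.names, self.gamma, self.se_gamma, self.pvalues()):
            lines.append(f"{name:<16}{g:>10.4f}{np.exp(g):>9.3f}{se:>10.4f}{p:>9.3g}")
        return "\n".join(lines)


def fit_cox(survival: SurvivalDataset, covariates: np.ndarray | None = None) -> CoxResults:
    """Convenience wrapper: ``CoxPH(survival, covariates).fit()``."""
    return CoxPH(survival, covariates).fit()
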