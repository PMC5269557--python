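"""Joint engine: complete-data likelihood, Gauss-Hermite marginal, fitting."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from engagejm import (
    EngagementLMM,
    JointModel,
    JointParams,
    predict_mean_trajectory,
)

from conftest import make_cohort


@pytest.fixture(scope="module")
def toy_joint():
    """Two-subject cohort with explicit parameters for hand-worked checks."""
    cohort = make_cohort(
        [("A", 0, 4.5), ("A", 1, 3.8), ("B", 0, 5.5), ("B", 2, 5.0), ("B", 3, 4.0)],
        [("A", 2.0, 1, 35.0, 1, "white"), ("B", 4.0, 0, 45.0, 0, "black")],
    )
    knots = np.array([0.0, 2.0, 4.0])
    params = JointParams(
        beta=np.array([4.2, -0.15, 0.002]),
        D=np.array([[1.2, -0.04], [-0.04, 0.03]]),
        sigma2=0.9,
        gamma=np.array([0.02, -0.1, 0.3, 0.0, 0.0]),
        alpha=-0.3,
        log_lambda=np.log([0.08, 0.12]),
        knots=knots,
    )
    model = JointModel(cohort, knots=knots, quad_order=9)
    return cohort, model, params


def hand_subject_loglik(model, params, sid, b, delta):
    """Independent evaluation: explicit Gaussian terms + scipy.quad hazard integral."""
    d = model.design
    idx = int(np.nonzero(d.subject_ids == sid)[0][0])
    sel = d.subject_index == idx
    w = d.W[idx]
    gw = float(params.gamma @ w)
    beta = params.beta

    def m(t):
        return beta[0] + beta[1] * t + beta[2] * t * t + b[0] + b[1] * t

    ll = sum(
        norm.logpdf(y, loc=m(t), scale=math.sqrt(params.sigma2))
        for t, y in zip(d.times[sel], d.y[sel])
    )
    T = d.event_time[idx]
    knots = params.knots

    def hazard(s):
        k = min(np.searchsorted(knots, s, side="right") - 1, len(params.log_lambda) - 1)
        return math.exp(params.log_lambda[k] + gw + params.alpha * m(s))

    H, _ = integrate.quad(hazard, 0.0, T, points=list(knots[knots < T]), limit=200)
    if delta:
        ll += math.log(hazard(T))  # right-continuous piece lookup at knots
    return ll - H


class TestSubjectLoglik:
    @pytest.mark.parametrize("b", [(0.0, 0.0), (1.1, -0.2), (-0.7, 0.15)])
    def test_event_subject_matches_hand_oracle(self, toy_joint, b):
        cohort, model, params = toy_joint
        expected = hand_subject_loglik(model, params, "A", b, delta=1)
        assert model.subject_loglik_given_b(params, "A", np.array(b)) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("b", [(0.0, 0.0), (0.9, 0.1)])
    def test_censored_subject_is_gaussian_minus_cumhaz(self, toy_joint, b):
        cohort, model, params = toy_joint
        expected = hand_subject_loglik(model, params, "B", b, delta=0)
        assert model.subject_loglik_given_b(params, "B", np.array(b)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_alpha_zero_separates(self, toy_joint):
        cohort, model, params = toy_joint
        p0 = JointParams(
            beta=params.beta, D=params.D, sigma2=params.sigma2, gamma=params.gamma,
            alpha=0.0, log_lambda=params.log_lambda, knots=params.knots,
        )
        # survival contribution no longer depends on b: differences across b
        # equal the Gaussian-part differences exactly
        bs = [np.array([0.0, 0.0]), np.array([1.0, -0.1]), np.array([-2.0, 0.3])]
        d = model.design
        sel = d.subject_index == 0

        def gauss(b):
            mvals = (
                p0.beta[0] + p0.beta[1] * d.times[sel] + p0.beta[2] * d.times[sel] ** 2
                + b[0] + b[1] * d.times[sel]
            )
            return float(norm.logpdf(d.y[sel], mvals, math.sqrt(p0.sigma2)).sum())

        gaps = [model.subject_loglik_given_b(p0, "A", b) - gauss(b) for b in bs]
        assert np.ptp(gaps) < 1e-10


class TestMarginalLoglik:
    def test_matches_grid_integration_oracle(self, toy_joint):
        cohort, model, params = toy_joint
        sd0 = math.sqrt(params.D[0, 0])
        sd1 = math.sqrt(params.D[1, 1])
        g0 = np.linspace(-8 * sd0, 8 * sd0, 201)
        g1 = np.linspace(-8 * sd1, 8 * sd1, 201)
        B = np.column_stack([np.repeat(g0, len(g1)), np.tile(g1, len(g0))])
        Dinv = np.linalg.inv(params.D)
        logprior = (
            -np.log(2 * np.pi)
            - 0.5 * np.log(np.linalg.det(params.D))
            - 0.5 * np.einsum("ni,ij,nj->n", B, Dinv, B)
        )
        total = 0.0
        for sid in ("A", "B"):
            g = model.subject_loglik_given_b(params, sid, B) + logprior
            integrand = np.exp(g).reshape(len(g0), len(g1))
            total += math.log(
                np.trapezoid(np.trapezoid(integrand, g1, axis=1), g0)
            )
        mine = model.loglike(params)
        assert abs(mine - total) < 1e-6 * abs(total)

    def test_point_mass_limit(self, toy_joint):
        cohort, model, params = toy_joint
        tiny = JointParams(
            beta=params.beta, D=np.diag([1e-12, 1e-12]), sigma2=params.sigma2,
            gamma=params.gamma, alpha=params.alpha, log_lambda=params.log_lambda,
            knots=params.knots,
        )
        at_zero = sum(
            model.subject_loglik_given_b(tiny, sid, np.zeros(2)) for sid in ("A", "B")
        )
        assert model.loglike(tiny) == pytest.approx(at_zero, abs=1e-3)

    def test_quadrature_self_convergence(self, small_mnar_cohort):
        cohort, _ = small_mnar_cohort
        model = JointModel(cohort, n_pieces=3)
        params = model._start_params()
        params.alpha = -0.3
        lls = {o: model.loglike(params, quad_order=o) for o in (5, 9, 15)}
        d1 = abs(lls[9] - lls[5])
        d2 = abs(lls[15] - lls[9])
        assert d2 <= max(d1, 1e-9)

    def test_subject_order_invariance(self, small_mnar_cohort):
        cohort, _ = small_mnar_cohort
        model = JointModel(cohort, n_pieces=3)
        params = model._start_params()
        params.alpha = -0.2
        ll = model.loglike(params)
        lf = cohort.longitudinal.frame.sample(frac=1.0, random_state=5)
        sf = cohort.survival.frame.sample(frac=1.0, random_state=6)
        shuffled = make_cohort(
            list(lf.itertuples(index=False, name=None)),
            list(sf.itertuples(index=False, name=None)),
        )
        model2 = JointModel(shuffled, knots=model.knots)
        ll2 = model2.loglike(params)
        assert ll == pytest.approx(ll2, abs=1e-8)


class TestFit:
    def test_alpha_zero_profile_factorises(self, small_mnar_cohort):
        cohort, _ = small_mnar_cohort
        model = JointModel(cohort, n_pieces=3, quad_order=5)
        res = model.fit(fix_alpha=0.0, se=False)
        lmm = EngagementLMM(cohort).fit()
        assert np.allclose(res.params.beta[:2], lmm.beta[:2], atol=2e-3)
        assert res.params.beta[2] == pytest.approx(lmm.beta[2], abs=1e-4)
        assert res.params.sigma2 == pytest.approx(lmm.params.sigma2, rel=1e-2)
        # survival block equals a piecewise-exponential PH fit (Poisson-GLM oracle)
        gamma_oracle = piecewise_exponential_oracle(model)
        assert np.allclose(res.params.gamma, gamma_oracle, atol=5e-3)

    def test_fit_never_below_start(self, small_mnar_cohort):
        cohort, _ = small_mnar_cohort
        model = JointModel(cohort, n_pieces=3, quad_order=5)
        start = model._start_params()
        res = model.fit(start=start, se=False)
        assert res.llf >= model.loglike(start) - 1e-8

    def test_empirical_bayes_modes_shrink(self, small_mnar_cohort):
        cohort, truth = small_mnar_cohort
        model = JointModel(cohort, n_pieces=3, quad_order=5)
        res = model.fit(se=False)
        merged = res.random_effects.merge(truth.table, on="subject_id",
                                          suffixes=("_hat", "_true"))
        r = np.corrcoef(merged["b0_hat"], merged["b0_true"])[0, 1]
        assert r > 0.6  # posterior modes track the realised intercepts
        assert np.abs(merged["b0_hat"]).mean() < np.abs(merged["b0_true"]).mean() + 0.5


def piecewise_exponential_oracle(model: JointModel) -> np.ndarray:
    """Piecewise-exponential PH fit via the Poisson person-period trick."""
    import statsmodels.api as sm

    d = model.design
    K = model.n_pieces
    rows_y, rows_X, rows_off = [], [], []
    for i in range(d.n_subjects):
        T = d.event_time[i]
        for k in range(K):
            lo, hi = model.knots[k], min(model.knots[k + 1], T)
            if hi <= lo:
                continue
            exposure = hi - lo
            died = int(d.event[i] == 1 and model._pieceT[i] == k)
            piece = np.zeros(K)
            piece[k] = 1.0
            rows_y.append(died)
            rows_X.append(np.concatenate([piece, d.W[i]]))
            rows_off.append(np.log(exposure))
    fit = sm.GLM(
        np.array(rows_y), np.array(rows_X),
        family=sm.families.Poisson(), offset=np.array(rows_off),
    ).fit()
    return np.asarray(fit.params[K:])


class TestPrediction:
    def test_intercept_at_time_zero(self):
        vals, se = predict_mean_trajectory([4.05, -0.14, 0.0021], None, [0.0])
        assert vals[0] == 4.05
        assert se is None

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            predict_mean_trajectory([4.0, -0.1, 0.001], None, [-1.0])

    def test_delta_method_se(self):
        cov = np.diag([0.01, 0.0001, 1e-8])
        vals, se = predict_mean_trajectory([4.0, -0.1, 0.001], cov, [0.0, 10.0])
        assert se[0] == pytest.approx(0.1)
        assert se[1] == pytest.approx(
            math.sqrt(0.01 + 100 * 0.0001 + 1e4 * 1e-8)
        )
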