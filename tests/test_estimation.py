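"""ML estimation: implied moments, discrepancy, closed-form oracles,
standardization, and the structural invariances of the fit statistic."""

import numpy as np
import pytest

from mgcfa.data_io import GroupSummary
from mgcfa.estimation import (
    ParameterSet,
    discrepancy,
    fit,
    implied_moments,
    standardize,
)
from mgcfa.model_spec import ConstraintProfile, ItemBattery, ModelSpec, builtin_spec
from mgcfa.synthetic import default_config, generate
from mgcfa.data_io import summarize_all


def _one_factor_params(lam, phi, theta, nu=None, kappa=0.0):
    lam = np.asarray(lam, dtype=float)
    p = lam.size
    return ParameterSet(
        Lambda=lam.reshape(p, 1),
        nu=np.zeros(p) if nu is None else np.asarray(nu, dtype=float),
        Theta=np.asarray(theta, dtype=float),
        Phi=np.array([[phi]]),
        kappa=np.array([kappa]),
    )


class TestImpliedMoments:
    def test_zero_loadings_give_diagonal(self):
        ps = _one_factor_params([0, 0, 0], 2.0, [1, 2, 3], nu=[4, 5, 6])
        Sigma, mu = implied_moments(ps)
        assert np.allclose(Sigma, np.diag([1, 2, 3]))
        assert np.allclose(mu, [4, 5, 6])

    def test_zero_factor_mean_gives_intercepts(self):
        ps = _one_factor_params([1, 0.5], 2.0, [1, 1], nu=[0.3, 0.7], kappa=0.0)
        _, mu = implied_moments(ps)
        assert np.allclose(mu, [0.3, 0.7])

    def test_hand_computed_covariance(self):
        ps = _one_factor_params([1, 0.5], 2.0, [1, 1])
        Sigma, _ = implied_moments(ps)
        assert np.allclose(Sigma, [[3, 1], [1, 1.5]])

    def test_dimension_mismatch(self):
        ps = _one_factor_params([1, 0.5], 2.0, [1, 1])
        ps.Phi = np.eye(2)
        with pytest.raises(ValueError):
            implied_moments(ps)


class TestDiscrepancy:
    def test_perfect_fit_is_zero(self, rng):
        A = rng.normal(size=(30, 4))
        S = np.cov(A, rowvar=False)
        xbar = A.mean(axis=0)
        summ = GroupSummary(item_names=("a", "b", "c", "d"), S=S, xbar=xbar, n=30)
        assert discrepancy(summ, S, xbar) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_closed_form(self):
        summ = GroupSummary(item_names=("x",), S=np.array([[2.0]]),
                            xbar=np.array([0.0]), n=50)
        val = discrepancy(summ, np.array([[1.0]]), np.array([0.0]))
        assert val == pytest.approx(1.0 - np.log(2.0), abs=1e-12)

    def test_mean_misfit_is_mahalanobis(self, rng):
        A = rng.normal(size=(40, 3))
        S = np.cov(A, rowvar=False)
        xbar = A.mean(axis=0)
        delta = np.array([0.3, -0.2, 0.1])
        summ = GroupSummary(item_names=("a", "b", "c"), S=S, xbar=xbar, n=40)
        val = discrepancy(summ, S, xbar - delta)
        assert val == pytest.approx(delta @ np.linalg.solve(S, delta), rel=1e-10)


def _three_item_battery():
    return ItemBattery(item_names=("x1", "x2", "x3"), scale_min=1, scale_max=4)


def _three_item_spec():
    b = _three_item_battery()
    return ModelSpec(battery=b, factors=("F",),
                     loading_pattern={i: "F" for i in b.item_names},
                     markers={"F": "x1"})


class TestTetradOracle:
    """A 3-item one-factor model with marker scaling is just-identified; the
    ML solution equals the closed-form tetrad expressions and T ~ 0."""

    def _summary(self):
        rng = np.random.default_rng(7)
        n = 400
        eta = rng.normal(0, 1.2, size=n)
        lam = np.array([1.0, 0.8, 1.3])
        y = 0.5 + eta[:, None] * lam[None, :] + rng.normal(0, 0.7, size=(n, 3))
        return GroupSummary(item_names=("x1", "x2", "x3"),
                            S=np.cov(y, rowvar=False), xbar=y.mean(axis=0), n=n)

    def test_matches_closed_form(self):
        summ = self._summary()
        S, xbar = summ.S, summ.xbar
        phi = S[0, 1] * S[0, 2] / S[1, 2]
        lam = np.array([1.0, S[1, 2] / S[0, 2], S[1, 2] / S[0, 1]])
        theta = np.diag(S) - lam**2 * phi
        m = fit(_three_item_spec(), [summ])
        assert m.converged
        assert m.df == 0
        assert m.T == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(m.params[0].Lambda[:, 0], lam, atol=1e-5)
        assert m.params[0].Phi[0, 0] == pytest.approx(phi, abs=1e-5)
        assert np.allclose(m.params[0].Theta, theta, atol=1e-5)
        assert np.allclose(m.params[0].nu, xbar, atol=1e-5)

    def test_scale_equivariance(self):
        # scaling item 3 by c scales its loading and intercept by c, its
        # uniqueness by c^2, and leaves the fit statistic unchanged
        summ = self._summary()
        c = 2.5
        D = np.diag([1.0, 1.0, c])
        scaled = GroupSummary(item_names=summ.item_names, S=D @ summ.S @ D,
                              xbar=D @ summ.xbar, n=summ.n)
        m0 = fit(_three_item_spec(), [summ])
        m1 = fit(_three_item_spec(), [scaled])
        assert m1.T == pytest.approx(m0.T, abs=1e-6)
        assert m1.params[0].Lambda[2, 0] == pytest.approx(
            c * m0.params[0].Lambda[2, 0], rel=1e-5)
        assert m1.params[0].nu[2] == pytest.approx(c * m0.params[0].nu[2], rel=1e-5)
        assert m1.params[0].Theta[2] == pytest.approx(
            c**2 * m0.params[0].Theta[2], rel=1e-4)


class TestStandardize:
    def test_worked_examples(self):
        ps = _one_factor_params([1.0, 1.0], 0.25, [0.75, 1.0])
        # implied var of item 1: 1*0.25 + 0.75 = 1 -> lam* = 1*0.5/1 = 0.5
        std = standardize(ps)
        assert std.Lambda[0, 0] == pytest.approx(0.5)
        assert std.Theta[0] == pytest.approx(0.75)

    def test_unifactorial_identity(self, rng):
        # lam*^2 + theta* = 1 for any item loading on one factor
        for _ in range(5):
            lam = rng.uniform(0.3, 2.0, size=4)
            theta = rng.uniform(0.2, 1.5, size=4)
            ps = _one_factor_params(lam, rng.uniform(0.3, 2.0), theta)
            std = standardize(ps)
            assert np.allclose(std.Lambda[:, 0] ** 2 + std.Theta, 1.0)

    def test_phi_becomes_correlation(self, study_groups, four_factor):
        groups, _ = study_groups
        m = fit(four_factor, [groups[0]])
        std = standardize(m.params[0])
        assert np.allclose(np.diag(std.Phi), 1.0)
        assert np.all(np.abs(std.Phi) <= 1.0 + 1e-10)


class TestMultiGroupFit:
    def test_nesting_monotonicity(self, study_groups, four_factor):
        groups, _ = study_groups
        Ts = []
        for level in ("configural", "metric", "scalar", "uniqueness"):
            m = fit(four_factor, groups,
                    ConstraintProfile(level, reference_group=groups[0].label))
            assert m.converged
            Ts.append(m.T)
        for a, b in zip(Ts, Ts[1:]):
            assert b >= a - 1e-4 * max(1.0, a)

    def test_constraints_hold_exactly(self, study_groups, four_factor):
        groups, _ = study_groups
        m = fit(four_factor, groups,
                ConstraintProfile("metric", reference_group=groups[0].label))
        assert np.allclose(m.params[0].Lambda, m.params[1].Lambda)
        assert not np.allclose(m.params[0].nu, m.params[1].nu)

    def test_recovery_improves_with_n(self, four_factor):
        # consistency: parameter error shrinks as group sizes grow
        errs = []
        for n in (250, 4000):
            cfg = default_config(seed=9, sizes=(n, n), missing_rate=0.0)
            groups = summarize_all(generate(cfg))
            m = fit(four_factor, groups,
                    ConstraintProfile("configural", reference_group="chinese"))
            errs.append(np.max(np.abs(m.params[0].Lambda - cfg.params[0].Lambda)))
        assert errs[1] < errs[0]

    def test_standard_errors_reasonable(self, four_factor):
        cfg = default_config(seed=3, sizes=(1500, 1500), missing_rate=0.0)
        groups = summarize_all(generate(cfg))
        prof = ConstraintProfile("scalar",
                                 frozenset({("intercept", "Failure"),
                                            ("intercept", "Good")}),
                                 reference_group="chinese")
        m = fit(four_factor, groups, prof)
        se = m.standard_errors()
        assert all(v > 0 for v in se.values())
        # free kappa estimates should sit within ~4 SE of the truth
        for j, f in enumerate(four_factor.factors):
            kap = m.params[1].kappa[j]
            s = se[f"kappa[{f}]@dutch"]
            assert abs(kap - cfg.params[1].kappa[j]) < 4 * s

    def test_empty_group_list_rejected(self, four_factor):
        with pytest.raises(ValueError):
            fit(four_factor, [])
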