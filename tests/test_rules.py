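"""Comparison learning rules: fixed points, relations, and documented behaviors."""

import math

import numpy as np
import pytest

from eghr import (AuxState, DivergenceError, Prior, Schedule, SourceSpec,
                  b_from_prior, make_mixing, recovery_report, train)
from eghr.metrics import _source_grid
from eghr.rules import (amari_update, bell_sejnowski_update, cichocki_update,
                        cubic_logistic_fF, foldiak_step, linsker_step,
                        logistic_fF, make_rule, rescale_rows)


def _quadrature_mean_update(update_fn, W, A, prior, ds=0.05, lim=12):
    """Expectation of a functional rule update over the source density."""
    S, wts = _source_grid(prior, ds=ds, lim=lim)
    X = S @ A.T
    # weighted empirical batch: replicate via importance weights
    # (update_fn takes a plain batch; emulate the expectation with a large
    # weighted grid by passing the weighted average directly)
    U = X @ W.T
    G = prior.g(U)
    Gw = G * wts[:, None]
    if update_fn is amari_update:
        return (np.eye(W.shape[0]) - Gw.T @ U) @ W
    if update_fn is bell_sejnowski_update:
        return np.linalg.inv(W).T - Gw.T @ X
    if update_fn is cichocki_update:
        return np.eye(W.shape[0]) - Gw.T @ U
    raise AssertionError


@pytest.fixture(scope="module")
def batch(rotation_mixing):
    from eghr import sample_iid

    s = sample_iid(SourceSpec(family="laplace", M=2), 500, 11)
    return s @ rotation_mixing.A.T


class TestFunctionalUpdates:
    def test_amari_bs_natural_gradient_relation(self, laplace_prior, batch):
        """amari dW = (bell-sejnowski dW) W^T W exactly, on identical batches."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            W = rng.standard_normal((2, 2)) + 0.5 * np.eye(2)
            a = amari_update(W, batch, laplace_prior)
            b = bell_sejnowski_update(W, batch, laplace_prior)
            np.testing.assert_allclose(a, b @ W.T @ W, rtol=1e-10, atol=1e-10)

    @pytest.mark.parametrize("fn", [amari_update, bell_sejnowski_update, cichocki_update],
                             ids=["amari", "bell_sejnowski", "cichocki"])
    def test_mean_update_vanishes_at_unmixing_solution(self, fn, laplace_prior, rotation_mixing):
        Winv = np.linalg.inv(rotation_mixing.A)
        dW = _quadrature_mean_update(fn, Winv, rotation_mixing.A, laplace_prior)
        assert np.abs(dW).max() < 5e-3

    def test_square_requirement(self, laplace_prior):
        with pytest.raises(ValueError):
            amari_update(np.ones((2, 3)), np.ones((1, 3)), laplace_prior)

    def test_bs_scalar_gaussian_fixed_point(self):
        """N = 1 with a Gaussian prior: the fixed point is |W sigma_x| = 1."""
        p = Prior(family="gen_gaussian", alpha=2.0, beta=0.5)
        rng = np.random.default_rng(0)
        x = (2.0 * rng.standard_normal(200_000)).reshape(-1, 1)  # sigma_x = 2
        from scipy.optimize import brentq

        f = lambda w: float(bell_sejnowski_update(np.array([[w]]), x, p)[0, 0])
        w_star = brentq(f, 0.1, 2.0)
        assert w_star * 2.0 == pytest.approx(1.0, abs=0.02)


class TestLinsker:
    def test_fast_dynamics_fixed_point(self, laplace_prior):
        """With stationary input and v = W x, the neural state stays put."""
        W = np.array([[0.4, 0.1], [-0.2, 0.5]])
        x = np.array([0.3, -0.7])
        aux = AuxState.zeros(2, tau_v=10.0, tau_Q=1e9)
        aux.v = W @ x
        _, aux2 = linsker_step(W, aux, x, laplace_prior, dt_update=10.0, eta=0.0)
        np.testing.assert_allclose(aux2.v, W @ x, atol=1e-12)

    def test_good_start_reaches_ica_solution(self, laplace_prior, rotation_mixing):
        spec = SourceSpec(family="laplace", M=2, temporal="langevin", tau_s=50, dt=1)
        sch = Schedule(T=2_000_000, dt_update=10, tau_W=1e4, checkpoint_every=2000)
        tr = train(make_rule("linsker", laplace_prior), spec, rotation_mixing,
                   schedule=sch, W0=-0.8 * np.eye(2), seed=0)
        rep = recovery_report(tr.averaged_W(), rotation_mixing.A)
        assert rep.aligned_count == 2 and rep.sources_covered == 2

    def test_small_start_collapses_to_zero(self, laplace_prior, rotation_mixing):
        spec = SourceSpec(family="laplace", M=2, temporal="langevin", tau_s=50, dt=1)
        sch = Schedule(T=1_000_000, dt_update=10, tau_W=1e4, checkpoint_every=2000)
        tr = train(make_rule("linsker", laplace_prior), spec, rotation_mixing,
                   schedule=sch, W0=-0.05 * np.eye(2), seed=0)
        assert np.linalg.norm(tr.final_W) < 0.01

    def test_large_start_runs_away(self, laplace_prior, rotation_mixing):
        spec = SourceSpec(family="laplace", M=2, temporal="langevin", tau_s=50, dt=1)
        sch = Schedule(T=1_000_000, dt_update=10, tau_W=1e4, checkpoint_every=2000)
        try:
            tr = train(make_rule("linsker", laplace_prior), spec, rotation_mixing,
                       schedule=sch, W0=-40.0 * np.eye(2), seed=0)
            assert np.linalg.norm(tr.final_W) > 100.0
        except DivergenceError:
            pass  # running off to infinity is the documented outcome


class TestFoldiak:
    def test_row_rescaling_exact(self):
        W = np.array([[3.0, 4.0], [0.3, 0.4]])  # first row has norm 5
        W2 = rescale_rows(W)
        assert np.linalg.norm(W2[0]) == pytest.approx(4.0)
        np.testing.assert_array_equal(W2[1], W[1])

    def test_b_from_prior(self, uniform_prior, sharp_laplace):
        assert b_from_prior(uniform_prior, logistic_fF) == pytest.approx(0.5, abs=1e-6)
        assert b_from_prior(sharp_laplace, lambda u: 0.3 * np.ones_like(np.asarray(u, dtype=float))) == pytest.approx(0.3, abs=1e-9)
        assert b_from_prior(sharp_laplace, lambda u: np.asarray(u, dtype=float) ** 3) == pytest.approx(0.0, abs=1e-6)

    def test_rotation_uniform_good_start_converges(self, uniform_prior, rotation_mixing):
        spec = SourceSpec(family="uniform", M=2, temporal="langevin", tau_s=50, dt=1)
        sch = Schedule(T=2_000_000, dt_update=1, tau_W=1e5, checkpoint_every=50_000)
        tr = train(make_rule("foldiak", uniform_prior), spec, rotation_mixing,
                   schedule=sch, W0=1.5 * rotation_mixing.A, seed=0)
        rep = recovery_report(tr.averaged_W(), rotation_mixing.A)
        assert rep.aligned_count == 2 and rep.sources_covered == 2

    def test_cubic_logistic_shape(self):
        # normalized so that f_F(large positive) = 1/0.225
        assert float(cubic_logistic_fF(1.0)) == pytest.approx(1.0 / 0.225, rel=1e-6)
        assert float(cubic_logistic_fF(-1.0)) == pytest.approx(0.0, abs=1e-6)

    def test_timescale_ordering_warning(self):
        aux = AuxState.zeros(2, tau_v=100.0, tau_Q=10.0)
        with pytest.warns(UserWarning):
            aux.check_timescales(tau_s=50.0, tau_W=1e3)


class TestStepperInterface:
    @pytest.mark.parametrize("name", ["eghr", "amari", "bell_sejnowski", "cichocki", "linsker", "foldiak"])
    def test_all_rules_run_and_produce_traces(self, name, laplace_prior, rotation_mixing):
        spec = SourceSpec(family="laplace", M=2, temporal="langevin", tau_s=50, dt=1)
        sch = Schedule(T=20_000, dt_update=10, tau_W=1e5, checkpoint_every=500)
        tr = train(make_rule(name, laplace_prior), spec, rotation_mixing,
                   schedule=sch, W0=0.9 * np.eye(2), seed=0)
        assert tr.meta["rule"] == name
        assert np.all(np.isfinite(tr.final_W))
        assert tr.steps[-1] == sch.n_updates

    def test_unknown_rule_rejected(self, laplace_prior):
        with pytest.raises(ValueError):
            make_rule("fastica", laplace_prior)
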