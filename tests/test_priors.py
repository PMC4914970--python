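"""Prior families: surprise, score, moments, equilibrium scale, stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from eghr import (Prior, default_E0, equilibrium_scale, expected_z, score,
                  stability_constants, surprise)
from eghr.priors import _equilibrium_residual

LN_SQRT2 = math.log(math.sqrt(2.0))

FAMILIES = [
    Prior(family="laplace", gamma=1000.0),
    Prior(family="uniform", gamma=1000.0),
    Prior(family="gen_gaussian", alpha=2.0, beta=0.5),
    Prior(family="gen_gaussian", alpha=1.5),
]


def test_invalid_configuration_rejected():
    with pytest.raises(ValueError):
        Prior(family="cauchy")
    with pytest.raises(ValueError):
        Prior(family="laplace", variance=-1.0)
    with pytest.raises(ValueError):
        Prior(family="gen_gaussian", alpha=-2.0)


@pytest.mark.parametrize("prior", FAMILIES, ids=lambda p: f"{p.family}-a{p.alpha}")
def test_density_normalized_and_z_even(prior):
    """exp(-z) integrates to 1 (z carries the normalizing constant)."""
    assert prior._Z == pytest.approx(1.0, abs=2e-3)
    u = np.linspace(0.1, 3.0, 7)
    np.testing.assert_allclose(prior.z(u), prior.z(-u), rtol=1e-12)


@pytest.mark.parametrize("prior", FAMILIES, ids=lambda p: f"{p.family}-a{p.alpha}")
def test_score_is_odd_and_monotone(prior):
    u = np.linspace(-3, 3, 301)
    g = prior.g(u)
    np.testing.assert_allclose(prior.g(-u), -g, atol=1e-10)
    assert np.all(np.diff(g) >= -1e-9)
    assert prior.g(0.0) == pytest.approx(0.0, abs=1e-12)


def test_smoothed_score_converges_to_exact_score():
    """As gamma grows the tanh-smoothed Laplace score approaches sqrt(2) sgn."""
    u = 0.02
    errs = [abs(float(Prior(family="laplace", gamma=g).g(u)) - math.sqrt(2.0))
            for g in (10.0, 100.0, 1000.0)]
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-6


def test_surprise_examples(sharp_laplace):
    # z(0) = ln sqrt(2) for the normalized unit-variance Laplace
    assert surprise(sharp_laplace, [0.0, 0.0]) == pytest.approx(2 * LN_SQRT2, abs=2e-3)
    u = np.array([0.7, -1.2])
    assert surprise(sharp_laplace, u) == pytest.approx(surprise(sharp_laplace, -u))
    assert surprise(sharp_laplace, u) == pytest.approx(
        surprise(sharp_laplace, u[:1]) + surprise(sharp_laplace, u[1:])
    )
    with pytest.raises(ValueError):
        surprise(sharp_laplace, [np.nan, 0.0])


def test_score_examples():
    p = Prior(family="laplace", gamma=100.0)
    assert float(score(p, 1.0)) == pytest.approx(math.sqrt(2.0) * math.tanh(100.0), rel=1e-9)
    pu = Prior(family="uniform", gamma=100.0)
    assert abs(float(score(pu, 0.5))) < 1e-6  # interior of the support


@given(st.floats(-3, 3), st.floats(-3, 3))
@settings(max_examples=25, deadline=None)
def test_surprise_additive_over_components(u1, u2):
    p = Prior(family="laplace", gamma=100.0)
    total = surprise(p, [u1, u2])
    assert total == pytest.approx(surprise(p, [u1]) + surprise(p, [u2]), rel=1e-10)


@pytest.mark.parametrize(
    "prior, expected",
    [
        (Prior(family="laplace", gamma=10000.0), 1.0 + math.log(2.0) / 2.0),
        (Prior(family="uniform", gamma=10000.0), math.log(2.0 * math.sqrt(3.0))),
        (Prior(family="gen_gaussian", alpha=2.0, beta=0.5), (1.0 + math.log(2 * math.pi)) / 2.0),
    ],
    ids=["laplace", "uniform", "gaussian"],
)
def test_expected_z_matches_closed_form(prior, expected):
    assert expected_z(prior) == pytest.approx(expected, abs=1e-3)


def test_default_E0(sharp_laplace):
    zbar = expected_z(sharp_laplace)
    assert default_E0(sharp_laplace, 2) == pytest.approx(2 * zbar + 1.0)
    assert default_E0(sharp_laplace, 2) == pytest.approx(3.693, abs=5e-3)
    assert default_E0(sharp_laplace, 0) == 1.0


@pytest.mark.parametrize("prior", FAMILIES, ids=lambda p: f"{p.family}-a{p.alpha}")
def test_integration_by_parts_identities(prior):
    """<g s> = 1 and <z g s> = <z> + 1 under the self-consistent density."""
    m = prior.moments
    assert m["gs"] == pytest.approx(1.0, abs=1e-3)
    assert m["zgs"] - m["z"] == pytest.approx(1.0, abs=1e-3)


def test_expected_z_matches_monte_carlo(sharp_laplace):
    from eghr import SourceSpec, sample_iid

    s = sample_iid(SourceSpec(family="laplace", M=1), 100_000, 7)[:, 0]
    mc = float(np.mean(sharp_laplace.z(s)))
    se = float(np.std(sharp_laplace.z(s)) / math.sqrt(s.size))
    assert abs(mc - expected_z(sharp_laplace)) < 5 * se


class TestEquilibriumScale:
    def test_default_E0_gives_unit_gain(self, sharp_laplace):
        assert equilibrium_scale(sharp_laplace, 2, default_E0(sharp_laplace, 2)) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "prior, alpha",
        [(Prior(family="laplace", gamma=1000.0), 1.0),
         (Prior(family="gen_gaussian", alpha=2.0, beta=0.5), 2.0)],
        ids=["laplace", "gaussian"],
    )
    def test_power_family_scaling(self, prior, alpha):
        """E0 = N k + c^alpha (N <z-k> + 1) gives equilibrium gain c (k = the
        normalization constant carried by z); verified against the quadrature
        zero of the equilibrium expectation."""
        N, c_target = 2, 2.0
        k = prior.log_norm
        ztil = expected_z(prior) - k
        E0 = N * k + c_target**alpha * (N * ztil + 1.0)
        c = equilibrium_scale(prior, N, E0)
        # the closed form is exact up to the tanh smoothing of z
        assert c == pytest.approx(c_target, rel=1e-2)
        # independent check: the equilibrium expectation vanishes at c
        assert _equilibrium_residual(prior, N, E0, c) == pytest.approx(0.0, abs=1e-6)
        # ... and is nonzero away from it
        assert abs(_equilibrium_residual(prior, N, E0, 0.5 * c)) > 1e-2

    def test_uniform_family_root_solve(self):
        p = Prior(family="uniform", gamma=1000.0)
        E0 = 2.0 * default_E0(p, 2)
        c = equilibrium_scale(p, 2, E0)
        assert c > 1.0
        assert _equilibrium_residual(p, 2, E0, c) == pytest.approx(0.0, abs=1e-6)

    def test_invalid_E0(self, sharp_laplace):
        with pytest.raises(ValueError):
            equilibrium_scale(sharp_laplace, 2, -1.0)


class TestStabilityConstants:
    @pytest.mark.parametrize("alpha", [1.5, 2.0, 3.0])
    def test_rho_equals_alpha_minus_one(self, alpha):
        sc = stability_constants(Prior(family="gen_gaussian", alpha=alpha))
        assert sc.rho == pytest.approx(alpha - 1.0, abs=1e-3)

    def test_laplace_omega_is_two(self):
        """omega = <s^2><g^2> = 2 for the unit-variance Laplace."""
        sc = stability_constants(Prior(family="laplace", gamma=1000.0))
        assert sc.omega == pytest.approx(2.0, abs=2e-3)
        assert sc.rho == pytest.approx(0.0, abs=2e-2)
        assert sc.is_stable

    def test_uniform_constants_finite_and_stable(self, uniform_prior):
        sc = stability_constants(uniform_prior)
        assert math.isfinite(sc.rho) and math.isfinite(sc.omega)
        assert sc.is_stable

    def test_gaussian_is_marginal(self, gaussian_prior):
        """The Gaussian sits exactly on the omega = 1 stability boundary."""
        sc = stability_constants(gaussian_prior)
        assert sc.omega == pytest.approx(1.0, abs=1e-6)
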