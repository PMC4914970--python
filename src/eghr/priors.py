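"""Source priors and their derived quantities.

The learning rules in this package are matched to an assumed source
distribution ``p0``.  Everything they need from it is derived from the
*surprise density* ``z(u) = -log p0(u)``:

* the per-sample surprise ``E(u) = sum_m z(u_m)``,
* the score function ``g(u) = z'(u) = -d log p0(u)/du``,
* its derivative ``g'(u)`` (needed for linear-stability analysis),
* scalar moments such as ``<z>`` used to set the gating constant ``E0``.

Three families are supported: Laplace, uniform, and the generalized
Gaussian ``p0 ∝ exp(-beta |s|^alpha)``.  For families whose exact score is
discontinuous (Laplace) or distributional (uniform) a tanh-smoothed score
with sharpness ``gamma`` is used, and ``z`` is defined as the exact
antiderivative of the smoothed score so that surprise and score stay
mutually consistent (this matters for the gradient-descent identity of the
error-gated rule).

Moments are computed by adaptive quadrature against the smoothed density
``exp(-z)/Z``; with this self-consistent measure the integration-by-parts
identities ``<g(s) s> = 1`` and ``<z(s) g(s) s> = <z(s)> + 1`` hold for
every family, including the soft-walled uniform one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "Prior",
    "StabilityConstants",
    "surprise",
    "score",
    "expected_z",
    "default_E0",
    "equilibrium_scale",
    "stability_constants",
]

_FAMILIES = ("laplace", "uniform", "gen_gaussian")


def _logcosh(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(cosh(x))."""
    x = np.abs(x)
    return x + np.log1p(np.exp(-2.0 * x)) - math.log(2.0)


def _sech2(x: np.ndarray) -> np.ndarray:
    """Numerically stable sech(x)^2 = 1/cosh(x)^2."""
    e = np.exp(-np.abs(x))
    return (2.0 * e / (1.0 + e * e)) ** 2


def gen_gaussian_beta_for_variance(alpha: float, variance: float = 1.0) -> float:
    """Scale coefficient beta giving the requested variance for exp(-beta|s|^alpha)."""
    return (special.gamma(3.0 / alpha) / (special.gamma(1.0 / alpha) * variance)) ** (alpha / 2.0)


@dataclass(frozen=True)
class Prior:
    """Assumed source distribution p0 and its derived functions.

    Parameters
    ----------
    family:
        One of ``laplace``, ``uniform``, ``gen_gaussian``.
    alpha, beta:
        Shape exponent and scale coefficient of the generalized Gaussian
        ``p0 ∝ exp(-beta |s|^alpha)``.  If ``beta`` is omitted it is solved
        from ``variance``.  Ignored by the other families.
    gamma:
        Sharpness of the tanh smoothing used where the exact score is not a
        function (Laplace kink, uniform walls).  Larger is closer to exact.
    variance:
        Reference variance of p0 (sets the Laplace scale and the uniform
        half-width ``sqrt(3*variance)``).
    """

    family: str
    alpha: float = 2.0
    beta: float | None = None
    gamma: float | None = None
    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}; expected one of {_FAMILIES}")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.gamma is None:
            # the uniform family's wall forces scale as gamma^2, so its
            # default smoothing is softer to keep explicit integration stable
            object.__setattr__(self, "gamma", 10.0 if self.family == "uniform" else 100.0)
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.family == "gen_gaussian":
            if self.alpha <= 0:
                raise ValueError("alpha must be positive")
            if self.beta is None:
                object.__setattr__(self, "beta", gen_gaussian_beta_for_variance(self.alpha, self.variance))
            elif self.beta <= 0:
                raise ValueError("beta must be positive")

    # -- family-specific scale parameters ------------------------------------
    @property
    def laplace_scale(self) -> float:
        """b of p0 = exp(-|s|/b)/(2b); unit variance gives b = 1/sqrt(2)."""
        return math.sqrt(self.variance / 2.0)

    @property
    def half_width(self) -> float:
        """Half-width of the uniform support, sqrt(3*variance)."""
        return math.sqrt(3.0 * self.variance)

    @property
    def log_norm(self) -> float:
        """-log of the normalization constant of the exact p0 (the additive
        constant carried by z)."""
        if self.family == "laplace":
            return math.log(2.0 * self.laplace_scale)
        if self.family == "uniform":
            return math.log(2.0 * self.half_width)
        a, b = self.alpha, self.beta
        # C = a * b^(1/a) / (2 Gamma(1/a))
        return -(math.log(a) + math.log(b) / a - math.log(2.0) - math.lgamma(1.0 / a))

    @property
    def support_radius(self) -> float:
        """Integration range used for quadrature (mirrors the |s| <= 20 range
        used for the velocity-map integrals at unit variance)."""
        return 20.0 * math.sqrt(self.variance)

    # -- z, g, g' -------------------------------------------------------------
    def z(self, u):
        """Surprise density z(u) = -log p0(u), smoothed, normalization included."""
        u = np.asarray(u, dtype=float)
        if self.family == "laplace":
            b, gm = self.laplace_scale, self.gamma
            return self.log_norm + _logcosh(gm * u) / (b * gm)
        if self.family == "uniform":
            w, gm = self.half_width, self.gamma
            return (
                self.log_norm
                + _logcosh(gm * (u - w))
                + _logcosh(gm * (u + w))
                - 2.0 * _logcosh(gm * w)
            )
        a, b = self.alpha, self.beta
        if a > 1.0:
            return self.log_norm + b * np.abs(u) ** a
        eps = 1.0 / self.gamma**2
        return self.log_norm + b * (u * u + eps) ** (a / 2.0) - b * eps ** (a / 2.0)

    def g(self, u):
        """Score g(u) = z'(u); odd and (for these families) nondecreasing."""
        u = np.asarray(u, dtype=float)
        if self.family == "laplace":
            return np.tanh(self.gamma * u) / self.laplace_scale
        if self.family == "uniform":
            w, gm = self.half_width, self.gamma
            return gm * (np.tanh(gm * (u - w)) + np.tanh(gm * (u + w)))
        a, b = self.alpha, self.beta
        if a > 1.0:
            return a * b * np.abs(u) ** (a - 1.0) * np.sign(u)
        eps = 1.0 / self.gamma**2
        return a * b * u * (u * u + eps) ** (a / 2.0 - 1.0)

    def g_prime(self, u):
        """Derivative of the (smoothed) score."""
        u = np.asarray(u, dtype=float)
        if self.family == "laplace":
            gm = self.gamma
            return gm / self.laplace_scale * _sech2(gm * u)
        if self.family == "uniform":
            w, gm = self.half_width, self.gamma
            return gm * gm * (_sech2(gm * (u - w)) + _sech2(gm * (u + w)))
        a, b = self.alpha, self.beta
        if a > 1.0:
            return a * (a - 1.0) * b * np.abs(u) ** (a - 2.0)
        eps = 1.0 / self.gamma**2
        q = (u * u + eps) ** (a / 2.0 - 2.0)
        return a * b * q * ((a - 1.0) * u * u + eps)

    def g_exact(self, u):
        """Exact (unsmoothed) score where it exists as a function."""
        u = np.asarray(u, dtype=float)
        if self.family == "laplace":
            return np.sign(u) / self.laplace_scale
        if self.family == "uniform":
            return np.zeros_like(u)  # zero in the interior; walls are distributional
        return self.g(u)

    def log_p0(self, s):
        """Exact log density of the family (used as sampling reference)."""
        s = np.asarray(s, dtype=float)
        if self.family == "laplace":
            return -np.abs(s) / self.laplace_scale - self.log_norm
        if self.family == "uniform":
            w = self.half_width
            out = np.where(np.abs(s) <= w, -self.log_norm, -np.inf)
            return out
        return -self.beta * np.abs(s) ** self.alpha - self.log_norm

    # -- quadrature moments ---------------------------------------------------
    def _quad(self, f, rel_tol: float = 1e-10) -> float:
        """Integrate f(s)*exp(-z(s)) over the support with breakpoints at the
        kinks/walls of the integrand."""
        R = self.support_radius
        # breakpoints at kinks plus the O(1/gamma) smoothing scale around
        # them, so adaptive quadrature resolves the narrow tanh transitions
        eps = [k / self.gamma for k in (2.0, 20.0)]
        pts = {0.0}
        pts.update(+e for e in eps)
        pts.update(-e for e in eps)
        if self.family == "uniform":
            w = self.half_width
            for c in (-w, w):
                pts.add(c)
                pts.update(c + e for e in eps)
                pts.update(c - e for e in eps)
        pts = [p for p in pts if -R < p < R]
        val, _ = integrate.quad(
            lambda s: f(s) * math.exp(-float(self.z(s))),
            -R,
            R,
            points=sorted(pts),
            limit=400,
            epsabs=1e-12,
            epsrel=rel_tol,
        )
        return val

    @cached_property
    def _Z(self) -> float:
        """Normalization of the smoothed density (1 up to O(1/gamma))."""
        return self._quad(lambda s: 1.0)

    def moment(self, f) -> float:
        """<f(s)> under the smoothed density exp(-z)/Z."""
        return self._quad(f) / self._Z

    @cached_property
    def moments(self) -> dict[str, float]:
        """Scalar moments used by the equilibrium and stability analyses."""
        m = {
            "z": self.moment(lambda s: float(self.z(s))),
            "gs": self.moment(lambda s: float(self.g(s)) * s),
            "zgs": self.moment(lambda s: float(self.z(s)) * float(self.g(s)) * s),
            "s2": self.moment(lambda s: s * s),
            "g2": self.moment(lambda s: float(self.g(s)) ** 2),
            "gp": self.moment(lambda s: float(self.g_prime(s))),
            "gps2": self.moment(lambda s: float(self.g_prime(s)) * s * s),
            "zgp": self.moment(lambda s: float(self.z(s)) * float(self.g_prime(s))),
            "zgps2": self.moment(lambda s: float(self.z(s)) * float(self.g_prime(s)) * s * s),
            "zs2": self.moment(lambda s: float(self.z(s)) * s * s),
        }
        return m


@dataclass(frozen=True)
class StabilityConstants:
    """Covariance constants governing linear stability of the ICA solutions.

    ``rho = cov(z(s), g'(s) s^2)`` and
    ``omega = cov(z(s), g'(s)) <s^2> + cov(z(s), s^2) <g'(s)>``;
    the solution W = A^-1 is a stable equilibrium of the error-gated rule
    iff rho > -1 and omega > 1.
    """

    rho: float
    omega: float

    @property
    def is_stable(self) -> bool:
        return self.rho > -1.0 and self.omega > 1.0


# -- module-level operations ------------------------------------------------

def surprise(prior: Prior, u) -> float:
    """Total surprise E(u) = sum_m z(u_m) of an output vector."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("surprise: non-finite input")
    return float(np.sum(prior.z(u)))


def score(prior: Prior, u) -> np.ndarray:
    """Elementwise score g(u) of an output vector."""
    return prior.g(u)


def expected_z(prior: Prior) -> float:
    """<z(s)> under p0, by adaptive quadrature."""
    return prior.moments["z"]


def default_E0(prior: Prior, N: int) -> float:
    """Gating constant E0 = N <z(s)> + 1 for which W = A^-1 is an equilibrium."""
    if N < 0:
        raise ValueError("N must be nonnegative")
    if N == 0:
        return 1.0
    return N * expected_z(prior) + 1.0


def _equilibrium_residual(prior: Prior, N: int, E0: float, c: float) -> float:
    """<(E0 - E(c s)) g(c s_i) c s_i> for N i.i.d. sources, by quadrature.

    Separability over channels: with E(c s) = sum_m z(c s_m),
    the expectation equals (E0 - (N-1)<z(c s)>) <g(c s) c s> - <z(c s) g(c s) c s>.
    """
    zc = prior.moment(lambda s: float(prior.z(c * s)))
    gcs = prior.moment(lambda s: float(prior.g(c * s)) * c * s)
    zgcs = prior.moment(lambda s: float(prior.z(c * s)) * float(prior.g(c * s)) * c * s)
    return (E0 - (N - 1) * zc) * gcs - zgcs


def equilibrium_scale(prior: Prior, N: int, E0: float) -> float:
    """Output gain c at which W = c A^-1 is an equilibrium for a given E0.

    For power-law families exp(-beta|s|^alpha) the closed form is
    ``E0 - N k = c^alpha (N <z - k> + 1)`` with k the normalization constant
    carried by z; for other families the scalar equilibrium condition
    ``<(E0 - E(c s)) g(c s_i) c s_i> = 0`` is solved by bracketing.
    """
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    k = prior.log_norm
    f = lambda c: _equilibrium_residual(prior, N, E0, c)
    # initial guess: the closed form for power-law families (exact up to the
    # tanh smoothing), unit gain otherwise
    c0 = 1.0
    if prior.family in ("laplace", "gen_gaussian"):
        alpha = 1.0 if prior.family == "laplace" else prior.alpha
        ztil = expected_z(prior) - k
        num = E0 - N * k
        if num <= 0:
            raise ValueError("E0 too small: no positive-gain equilibrium for this family")
        c0 = (num / (N * ztil + 1.0)) ** (1.0 / alpha)
    # the residual is decreasing in c through the equilibrium: bracket it
    # outward from the guess (avoiding the trivial root at c = 0)
    lo = hi = c0
    flo = f(c0)
    for _ in range(60):
        if flo > 0:
            hi = lo * 1.3
            if f(hi) <= 0:
                return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
            lo = hi
        else:
            lo = hi / 1.3
            if f(lo) >= 0:
                return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
            hi = lo
        if not (1e-6 < lo < 1e6):
            break
    raise ArithmeticError("equilibrium_scale: no sign change found in bracket")


def stability_constants(prior: Prior) -> StabilityConstants:
    """rho and omega by quadrature against p0."""
    m = prior.moments
    rho = m["zgps2"] - m["z"] * m["gps2"]
    omega = (m["zgp"] - m["z"] * m["gp"]) * m["s2"] + (m["zs2"] - m["z"] * m["s2"]) * m["gp"]
    if not (math.isfinite(rho) and math.isfinite(omega)):
        raise ArithmeticError("stability constants did not converge")
    return StabilityConstants(rho=rho, omega=omega)


def with_gamma(prior: Prior, gamma: float) -> Prior:
    """Copy of the prior with a different smoothing sharpness."""
    return replace(prior, gamma=gamma)
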