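"""The five comparison ICA learning rules.

All rules see the same mixed input ``x = A s`` and drive the same linear
readout ``u = W x``; they differ in how W (and, for the Linsker and Foldiak
rules, auxiliary neural state ``v``, lateral weights ``Q`` and thresholds
``h``) evolve:

* Bell-Sejnowski (infomax, non-local):   tau_W dW = W^-T - <g(u) x^T>
* Amari (natural gradient, non-local):   tau_W dW = (I - <g(u) u^T>) W
* Cichocki (local):                      tau_W dW = I - <g(u) u^T>
* Linsker (local, lateral loop):         a fast state v relaxes through
  lateral weights Q toward v = (I-Q)^-1 u while Q tracks I - <u u^T>; at
  equilibrium <v x^T> equals the infomax term W^-T, so
  tau_W dW = <(v - g(u)) x^T> reduces to the Bell-Sejnowski rule when the
  input changes slowly compared to tau_v.
* Foldiak (local, anti-Hebbian + adaptive threshold): nonlinear units
  y = f_F(v) with lateral decorrelation of y toward target rate b,
  Hebbian-with-decay feedforward learning, and threshold homeostasis.

The time constants must satisfy tau_v < tau_s << tau_Q < tau_W for the
rules with auxiliary dynamics; a configuration warning is emitted if the
ordering is violated.

The exact printed forms of the Linsker and Foldiak adaptations are not
recoverable from the available text, so both are implemented from their
original published versions (Linsker 1997; Foldiak 1990) in this paper's
notation; the implementations reproduce the documented behaviors (shared
fixed points and the natural-gradient relation for Bell-Sejnowski/Amari,
instability of two of the four rotation-manifold solutions for Cichocki,
spurious attractors at W = 0 and infinity for Linsker, failure of Foldiak
on non-rotation mixing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .learning import EGHR, Rule
from .priors import Prior

__all__ = [
    "AuxState",
    "amari_update",
    "bell_sejnowski_update",
    "cichocki_update",
    "linsker_step",
    "foldiak_step",
    "b_from_prior",
    "logistic_fF",
    "cubic_logistic_fF",
    "Amari",
    "BellSejnowski",
    "Cichocki",
    "Linsker",
    "Foldiak",
    "make_rule",
    "RULES",
]

FOLDIAK_ROW_NORM_LIMIT = 4.0


# -- nonlinearities ----------------------------------------------------------

def logistic_fF(u, gain: float = 100.0):
    """f_F(u) = 1/(1+exp(-gain*u)); the sharp logistic used with uniform sources."""
    return special.expit(gain * np.asarray(u, dtype=float))


def cubic_logistic_fF(u, gain: float = 100.0):
    """f_F(u) = logistic(gain*u^3)/0.225; the variant used with Laplace sources."""
    u = np.asarray(u, dtype=float)
    return special.expit(gain * u**3) / 0.225


def b_from_prior(prior: Prior, f_F) -> float:
    """Target mean b = <f_F(s)> under p0, by quadrature."""
    return prior.moment(lambda s: float(f_F(s)))


# -- auxiliary state ----------------------------------------------------------

@dataclass
class AuxState:
    """Neural state and lateral/threshold variables of the Linsker and
    Foldiak rules, with their time constants."""

    v: np.ndarray
    Q: np.ndarray
    h: np.ndarray
    a: float = 1.0
    b: float = 0.5
    tau_v: float = 10.0
    tau_Q: float = 100.0
    tau_h: float = 100.0
    dt: float = 1.0

    @classmethod
    def zeros(cls, N: int, **kw) -> "AuxState":
        return cls(v=np.zeros(N), Q=np.zeros((N, N)), h=np.zeros(N), **kw)

    def check_timescales(self, tau_s: float, tau_W: float) -> None:
        """Warn unless tau_v < tau_s << tau_Q < tau_W."""
        if not (self.tau_v < tau_s < self.tau_Q < tau_W):
            warnings.warn(
                f"time-scale ordering tau_v < tau_s << tau_Q < tau_W violated: "
                f"tau_v={self.tau_v}, tau_s={tau_s}, tau_Q={self.tau_Q}, tau_W={tau_W}",
                stacklevel=2,
            )


# -- functional updates (unit learning rate; the stepper applies eta) ---------

def amari_update(W: np.ndarray, x_batch: np.ndarray, prior: Prior) -> np.ndarray:
    """Natural-gradient update direction (I - <g(u) u^T>) W."""
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("Amari rule requires square W")
    X = np.atleast_2d(np.asarray(x_batch, dtype=float))
    U = X @ W.T
    G = prior.g(U)
    return (np.eye(W.shape[0]) - G.T @ U / X.shape[0]) @ W


def bell_sejnowski_update(W: np.ndarray, x_batch: np.ndarray, prior: Prior) -> np.ndarray:
    """Infomax update direction W^-T - <g(u) x^T>."""
    W = np.asarray(W, dtype=float)
    X = np.atleast_2d(np.asarray(x_batch, dtype=float))
    U = X @ W.T
    G = prior.g(U)
    return np.linalg.inv(W).T - G.T @ X / X.shape[0]


def cichocki_update(W: np.ndarray, x_batch: np.ndarray, prior: Prior) -> np.ndarray:
    """Local update direction I - <g(u) u^T> (no trailing W, no lateral
    variables); each synapse sees only its own pre/post activities."""
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("Cichocki rule requires square W")
    X = np.atleast_2d(np.asarray(x_batch, dtype=float))
    U = X @ W.T
    G = prior.g(U)
    return np.eye(W.shape[0]) - G.T @ U / X.shape[0]


def _cap_spectral_radius(Q: np.ndarray, limit: float = 0.98) -> np.ndarray:
    """Scale Q down if its spectral radius exceeds `limit` (keeps the lateral
    relaxation v = (I - Q)^-1 u well defined between learning updates)."""
    r = np.max(np.abs(np.linalg.eigvals(Q)))
    if r > limit:
        Q = Q * (limit / r)
    return Q


def linsker_step(
    W: np.ndarray, aux: AuxState, x_t: np.ndarray, prior: Prior, dt_update: float, eta: float
) -> tuple[np.ndarray, AuxState]:
    """One step of the Linsker rule on a single input sample.

    The neural state relaxes through symmetric lateral weights toward
    v = (I - Q)^-1 u with time constant tau_v, while anti-Hebbian learning
    drives Q toward the point where <v v^T> = I, i.e. the lateral loop
    whitens the output: (I - Q)^-1 -> <u u^T>^(-1/2).  A second pass of the
    relaxed state through the same lateral loop (stored in aux.h) then
    satisfies <y x^T> = <u u^T>^-1 W <x x^T> = W^-T, which lets the infomax
    direction W^-T - <g(u) x^T> be computed from locally available
    quantities: dW = eta (y - g(u)) x^T.  When the input decorrelates or
    changes faster than tau_v the whitened estimate cannot keep up and the
    anti-Hebbian term dominates, reproducing the spurious attractor at
    W = 0 (and runaway growth for large initial W).
    """
    x = np.asarray(x_t, dtype=float).ravel()
    u = W @ x
    lam = min(dt_update / aux.tau_v, 1.0)
    v = aux.v + lam * (-aux.v + aux.a * u + aux.Q @ aux.v)
    y = aux.h + lam * (-aux.h + v + aux.Q @ aux.h)  # second lateral pass
    Q = aux.Q + (dt_update / aux.tau_Q) * (np.eye(len(u)) - np.outer(v, v))
    Q = _cap_spectral_radius(Q)
    g = prior.g(u)
    W_new = W + eta * np.outer(y - g, x)
    aux.v, aux.Q, aux.h = v, Q, y
    return W_new, aux


def foldiak_step(
    W: np.ndarray, aux: AuxState, x_t: np.ndarray, prior: Prior, dt_update: float,
    eta: float, f_F=logistic_fF,
) -> tuple[np.ndarray, AuxState]:
    """One step of the Foldiak rule on a single input sample.

    Nonlinear units y = f_F(v) with lateral anti-Hebbian decorrelation
    toward the target coincidence rate b^2, Hebbian-with-decay feedforward
    learning dW_ij = y_i (x_j - W_ij), and threshold homeostasis keeping
    <y> = b.  Rows of W are rescaled to norm 4 whenever they exceed it.
    """
    x = np.asarray(x_t, dtype=float).ravel()
    y = f_F(aux.v)
    v = aux.v + (dt_update / aux.tau_v) * (-aux.v + aux.a * (W @ x) + aux.Q @ y - aux.h)
    dQ = -(np.outer(y, y) - aux.b**2)
    np.fill_diagonal(dQ, 0.0)
    Q = aux.Q + (dt_update / aux.tau_Q) * dQ
    h = aux.h + (dt_update / aux.tau_h) * (y - aux.b)
    W_new = W + eta * (np.outer(y, x) - y[:, None] * W)
    W_new = rescale_rows(W_new)
    aux.v, aux.Q, aux.h = v, Q, h
    return W_new, aux


def rescale_rows(W: np.ndarray, limit: float = FOLDIAK_ROW_NORM_LIMIT) -> np.ndarray:
    """Rescale any row with norm above `limit` back to exactly `limit`."""
    norms = np.linalg.norm(W, axis=1)
    over = norms > limit
    if np.any(over):
        W = W.copy()
        W[over] *= (limit / norms[over])[:, None]
    return W


# -- stepper classes -----------------------------------------------------------

class Amari(Rule):
    name = "amari"

    def update(self, W, aux, X, eta):
        return W + eta * amari_update(W, X, self.prior)


class BellSejnowski(Rule):
    name = "bell_sejnowski"

    def update(self, W, aux, X, eta):
        return W + eta * bell_sejnowski_update(W, X, self.prior)


class Cichocki(Rule):
    name = "cichocki"

    def update(self, W, aux, X, eta):
        return W + eta * cichocki_update(W, X, self.prior)


class Linsker(Rule):
    name = "linsker"
    default_dt_update = 10.0
    default_tau_W = 1e4

    def __init__(self, prior, E0=None, a: float = 1.0, tau_v: float = 10.0,
                 tau_Q: float | None = None):
        super().__init__(prior, E0)
        self.a = a
        self.tau_v = tau_v
        self.tau_Q = tau_Q
        self.dt_update = self.default_dt_update

    def prepare(self, N, Nin, schedule):
        super().prepare(N, Nin, schedule)
        self.dt_update = schedule.dt_update
        if self.tau_Q is None:
            self.tau_Q = schedule.tau_W / 10.0

    def init_aux(self, N):
        return AuxState.zeros(N, a=self.a, tau_v=self.tau_v, tau_Q=self.tau_Q or 1e3)

    def update(self, W, aux, X, eta):
        W, _ = linsker_step(W, aux, X[-1], self.prior, self.dt_update, eta)
        return W


class Foldiak(Rule):
    name = "foldiak"
    default_dt_update = 1.0
    default_tau_W = 1e6

    def __init__(self, prior, E0=None, a: float = 1.1, b: float | None = None,
                 f_F=logistic_fF, tau_v: float = 10.0, tau_Q: float | None = None,
                 tau_h: float | None = None):
        super().__init__(prior, E0)
        self.a = a
        self.b = b
        self.f_F = f_F
        self.tau_v = tau_v
        self.tau_Q = tau_Q
        self.tau_h = tau_h
        self.dt_update = self.default_dt_update

    def prepare(self, N, Nin, schedule):
        super().prepare(N, Nin, schedule)
        self.dt_update = schedule.dt_update
        if self.b is None:
            self.b = b_from_prior(self.prior, self.f_F)
        if self.tau_Q is None:
            self.tau_Q = schedule.tau_W / 10.0
        if self.tau_h is None:
            self.tau_h = schedule.tau_W / 10.0

    def init_aux(self, N):
        return AuxState.zeros(
            N, a=self.a, b=self.b if self.b is not None else 0.5,
            tau_v=self.tau_v, tau_Q=self.tau_Q or 1e5, tau_h=self.tau_h or 1e5,
        )

    def update(self, W, aux, X, eta):
        W, _ = foldiak_step(W, aux, X[-1], self.prior, self.dt_update, eta, f_F=self.f_F)
        return W


RULES = {
    "eghr": EGHR,
    "amari": Amari,
    "bell_sejnowski": BellSejnowski,
    "cichocki": Cichocki,
    "linsker": Linsker,
    "foldiak": Foldiak,
}


def make_rule(name: str, prior: Prior, E0: float | None = None, **kw) -> Rule:
    """Instantiate a rule by its config key."""
    try:
        cls = RULES[name]
    except KeyError:
        raise ValueError(f"unknown rule {name!r}; expected one of {sorted(RULES)}") from None
    return cls(prior, E0=E0, **kw)
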