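"""Independent-source simulators and mixing models.

Sources are zero-mean, i.i.d. across channels, and drawn from one of three
marginal families (Laplace, uniform, generalized Gaussian).  Two temporal
modes are provided:

* ``iid`` — every time step is an independent draw;
* ``langevin`` — overdamped Langevin dynamics
  ``ds = -U'(s)/tau_s dt + sqrt(2/tau_s) dW`` whose stationary marginal is
  ``p0 ∝ exp(-U)``; this produces the temporally correlated ("colored")
  sources with time constant ``tau_s`` used by rules that must integrate a
  fast neural state.

Mixing is linear, ``x = A s``, with constructors for rotation, random
square, stacked-rotation (undercomplete), and explicit matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .priors import Prior

__all__ = [
    "SourceSpec",
    "MixingModel",
    "sample_iid",
    "simulate_langevin",
    "sample",
    "make_mixing",
    "mix",
    "write_signals",
    "read_signals",
]


@dataclass(frozen=True)
class SourceSpec:
    """Configuration of the independent-source generator.

    ``family``/``alpha``/``beta``/``variance`` define the marginal law
    (see :class:`~eghr.priors.Prior`); ``M`` is the number of channels;
    ``temporal`` selects i.i.d. draws or the Langevin process with time
    constant ``tau_s`` integrated at resolution ``dt``.
    """

    family: str = "laplace"
    alpha: float = 2.0
    beta: float | None = None
    variance: float = 1.0
    M: int = 2
    temporal: str = "iid"
    tau_s: float = 50.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("laplace", "uniform", "gen_gaussian"):
            raise ValueError(f"unknown source family {self.family!r}")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.temporal not in ("iid", "langevin"):
            raise ValueError(f"unknown temporal mode {self.temporal!r}")
        if self.temporal == "langevin":
            if self.tau_s <= 0 or self.dt <= 0:
                raise ValueError("tau_s and dt must be positive")
            if self.dt >= self.tau_s:
                raise ValueError(
                    f"dt={self.dt} >= tau_s={self.tau_s}: Langevin integration unstable"
                )

    @property
    def prior(self) -> Prior:
        """Matched prior (same family/scale) for this source law."""
        return Prior(family=self.family, alpha=self.alpha, beta=self.beta, variance=self.variance)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _channel_rngs(seed, M: int) -> list[np.random.Generator]:
    """One root seed expanded into independent per-channel streams."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(M)]


def _draw_marginal(spec: SourceSpec, rng: np.random.Generator, size) -> np.ndarray:
    v = spec.variance
    if spec.family == "laplace":
        return rng.laplace(0.0, math.sqrt(v / 2.0), size=size)
    if spec.family == "uniform":
        w = math.sqrt(3.0 * v)
        return rng.uniform(-w, w, size=size)
    if spec.family == "gen_gaussian":
        # |s| = (G/beta)^(1/alpha) with G ~ Gamma(1/alpha, 1), random sign.
        p = spec.prior
        gmm = rng.gamma(1.0 / p.alpha, 1.0, size=size)
        mag = (gmm / p.beta) ** (1.0 / p.alpha)
        return mag * rng.choice([-1.0, 1.0], size=size)
    raise ValueError(f"unknown family {spec.family!r}")


def sample_iid(spec: SourceSpec, T: int, seed) -> np.ndarray:
    """T x M matrix of i.i.d. source draws, reproducible given the seed."""
    if spec.temporal != "iid":
        raise ValueError("sample_iid requires temporal='iid'")
    if T < 1:
        raise ValueError("T must be >= 1")
    rngs = _channel_rngs(seed, spec.M)
    cols = [_draw_marginal(spec, r, T) for r in rngs]
    return np.column_stack(cols)


def simulate_langevin(
    spec: SourceSpec,
    T: int,
    seed,
    s0: np.ndarray | None = None,
    noise_scale: float = 1.0,
) -> np.ndarray:
    """Euler-Maruyama integration of the overdamped Langevin source model.

    ``ds = -U'(s)/tau_s dt + sqrt(2 dt/tau_s) * noise_scale * xi`` with
    ``U = -log p0`` up to a constant.  ``noise_scale=0`` gives the
    deterministic drift flow (useful for testing fixed points).  The uniform
    family uses zero drift inside reflecting walls at ±sqrt(3*variance),
    which preserves the uniform stationary law exactly.
    """
    if spec.temporal != "langevin":
        raise ValueError("simulate_langevin requires temporal='langevin'")
    if T < 1:
        raise ValueError("T must be >= 1")
    M, dt, tau = spec.M, spec.dt, spec.tau_s
    prior = spec.prior
    rng = _rng(seed)
    s = np.zeros(M) if s0 is None else np.asarray(s0, dtype=float).copy()
    out = np.empty((T, M))
    amp = noise_scale * math.sqrt(2.0 * dt / tau)
    noise = rng.standard_normal((T, M)) * amp
    if spec.family == "uniform":
        w = prior.half_width
        for t in range(T):
            s = s + noise[t]
            # reflect at the walls: triangle-wave fold back into [-w, w]
            r = np.mod(s + w, 4.0 * w)
            s = np.where(r <= 2.0 * w, r - w, 3.0 * w - r)
            out[t] = s
    elif spec.family == "laplace":
        # drift -g(s)/tau with the tanh-smoothed score, hoisted for speed
        k = (dt / tau) / prior.laplace_scale
        gm = prior.gamma
        tanh = np.tanh
        for t in range(T):
            s = s - k * tanh(gm * s) + noise[t]
            out[t] = s
    else:
        step = dt / tau
        g = prior.g
        for t in range(T):
            s = s - step * g(s) + noise[t]
            out[t] = s
    return out


def sample(spec: SourceSpec, T: int, seed) -> np.ndarray:
    """Dispatch on the temporal mode."""
    if spec.temporal == "iid":
        return sample_iid(spec, T, seed)
    return simulate_langevin(spec, T, seed)


@dataclass(frozen=True)
class MixingModel:
    """Linear mixing x = A s with an N x M gain matrix A."""

    A: np.ndarray
    kind: str = "explicit"

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        object.__setattr__(self, "A", A)

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.A.shape[1]

    def inverse(self) -> np.ndarray:
        if self.N != self.M:
            raise ValueError("inverse requires a square mixing matrix")
        return np.linalg.inv(self.A)


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def make_mixing(
    kind: str,
    theta: float | None = None,
    N: int | None = None,
    A: np.ndarray | None = None,
    seed=None,
    cond_max: float = 100.0,
    angles: np.ndarray | None = None,
) -> MixingModel:
    """Construct a mixing matrix.

    kinds
    -----
    ``rotation``          2x2 rotation by ``theta``.
    ``square_random``     N x N i.i.d. standard-normal entries, resampled
                          until the condition number is below ``cond_max``.
    ``stacked_rotation``  N x 2 stack of 2x2 rotation blocks (N even); block
                          angles are ``angles`` if given, else evenly spread
                          over [0, pi).
    ``explicit``          the user matrix, preserved bit-exactly (validated
                          invertible when square).
    """
    if kind == "rotation":
        if theta is None:
            raise ValueError("rotation kind requires theta")
        return MixingModel(A=rotation_matrix(theta), kind=kind)
    if kind == "square_random":
        if N is None:
            raise ValueError("square_random kind requires N")
        rng = _rng(seed)
        for _ in range(1000):
            cand = rng.standard_normal((N, N))
            if np.linalg.cond(cand) < cond_max:
                # normalize overall gain (||A||_F = sqrt(N)); the mixture is
                # the same problem up to scale, but keeps the learning
                # timescale of W comparable across draws
                cand *= math.sqrt(N) / np.linalg.norm(cand)
                return MixingModel(A=cand, kind=kind)
        raise ArithmeticError("square_random: no well-conditioned matrix found")
    if kind == "stacked_rotation":
        if N is None or N % 2:
            raise ValueError("stacked_rotation kind requires even N")
        n_blocks = N // 2
        if angles is None:
            angles = np.arange(n_blocks) * math.pi / n_blocks
        blocks = [rotation_matrix(a) for a in np.asarray(angles, dtype=float)]
        return MixingModel(A=np.vstack(blocks), kind=kind)
    if kind == "explicit":
        if A is None:
            raise ValueError("explicit kind requires A")
        A = np.asarray(A, dtype=float)
        if A.shape[0] == A.shape[1]:
            if abs(np.linalg.det(A)) < 1e-12:
                raise ValueError("explicit square mixing matrix is singular")
        return MixingModel(A=A, kind=kind)
    raise ValueError(f"unknown mixing kind {kind!r}")


def mix(model: MixingModel, s: np.ndarray) -> np.ndarray:
    """Row-wise linear mixture x = A s for a T x M source matrix."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[1] != model.M:
        raise ValueError(f"source matrix has {s.shape} columns, expected M={model.M}")
    return s @ model.A.T


# -- plain-text signal IO ----------------------------------------------------

def write_signals(path, X: np.ndarray, names: list[str] | None = None, delimiter: str = "\t") -> None:
    """Write a samples x channels matrix as delimited text with a header row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"ch{i}" for i in range(X.shape[1])]
    np.savetxt(path, X, delimiter=delimiter, header=delimiter.join(names), comments="")


def read_signals(path, delimiter: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a delimited numeric table with a one-line header; returns (data, names)."""
    with open(path) as fh:
        header = fh.readline().strip()
    for d in ([delimiter] if delimiter else ["\t", ","]):
        if d in header:
            names = [h.strip() for h in header.split(d)]
            data = np.loadtxt(path, delimiter=d, skiprows=1, ndmin=2)
            return data, names
    # single-column fallback
    return np.loadtxt(path, skiprows=1, ndmin=2), [header]
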