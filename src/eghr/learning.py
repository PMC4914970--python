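"""The error-gated Hebbian rule (EGHR) and the shared training loop.

A linear network ``u = W x`` receives mixtures ``x = A s`` of independent
sources.  The EGHR changes each synapse by a plain Hebbian product
``g(u_i) x_j`` multiplied by a *global* scalar gate ``E0 - E(u)``, where
``E(u) = -sum_i log p0(u_i)`` is the surprise of the current output under
the assumed source prior and ``E0`` is a constant:

    tau_W dW/dt = < (E0 - E(u)) g(u) x^T >

This is exact gradient descent on ``L = <(E(u) - E0)^2 / 2>``: the rule
reduces fluctuations of the surprise around ``E0``, which drives the
outputs toward independence while the constant ``E0 > -N log p0(0)``
keeps W away from the trivial zero solution.  With ``E0 = N <z> + 1`` the
unmixing matrix ``W = A^-1`` (and its row permutations/sign flips) is an
equilibrium.

The training loop is rule-agnostic: every rule (EGHR and the five
comparison rules in :mod:`eghr.rules`) exposes the same stepper interface
and produces the same :class:`ExperimentTrace`, so all experiments run
identically across rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .priors import Prior, default_E0
from .sources import (MixingModel, SourceSpec, _draw_marginal, sample_iid,
                      simulate_langevin)

__all__ = [
    "LearnerState",
    "ExperimentTrace",
    "Schedule",
    "DivergenceError",
    "eghr_update",
    "cost_L",
    "train",
    "EGHR",
]

W_DIVERGENCE_LIMIT = 1e6


class DivergenceError(RuntimeError):
    """Raised when W leaves the finite range; carries the step index and the
    partial trace collected so far."""

    def __init__(self, step: int, trace: "ExperimentTrace | None" = None):
        super().__init__(f"weight matrix diverged at update step {step}")
        self.step = step
        self.trace = trace


@dataclass
class LearnerState:
    """Synaptic matrix plus the learning schedule of a single learner.

    ``dt_update`` is the sparse-sampling interval between updates (the rule
    only looks at the signal every dt_update source steps); each update
    integrates the learning ODE by one source-resolution step ``dt``, so
    the per-update learning rate is ``dt / tau_W``.
    """

    W: np.ndarray
    tau_W: float = 1e3
    dt_update: float = 100.0
    dt: float = 1.0
    step: int = 0

    def __post_init__(self) -> None:
        self.W = np.array(self.W, dtype=float)

    @property
    def eta(self) -> float:
        """Per-update learning rate dt / tau_W (0 when frozen)."""
        if math.isinf(self.tau_W):
            return 0.0
        return self.dt / self.tau_W


@dataclass
class ExperimentTrace:
    """Time-indexed record of a training run."""

    steps: list[int] = field(default_factory=list)
    Ws: list[np.ndarray] = field(default_factory=list)
    costs: list[float] = field(default_factory=list)
    mis: list[float] = field(default_factory=list)
    Ks: list[np.ndarray] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def append(self, step, W, cost=np.nan, mi=np.nan, K=None) -> None:
        if self.steps and step <= self.steps[-1]:
            raise ValueError("checkpoint steps must be strictly increasing")
        self.steps.append(int(step))
        self.Ws.append(np.array(W))
        self.costs.append(float(cost))
        self.mis.append(float(mi))
        if K is not None:
            self.Ks.append(np.array(K))

    @property
    def final_W(self) -> np.ndarray:
        return self.Ws[-1]

    def averaged_W(self, frac: float = 0.25) -> np.ndarray:
        """W averaged over the trailing ``frac`` of checkpoints.

        The online rules fluctuate around a solution in the stationary
        regime; evaluating the time-averaged W (rather than one endpoint
        snapshot) mirrors pooling the final outputs over many steps and
        suppresses the stationary jitter.
        """
        lo = self.steps[-1] * (1.0 - frac)
        Ws = [w for s, w in zip(self.steps, self.Ws) if s >= lo]
        return np.mean(Ws, axis=0)

    def to_table(self) -> np.ndarray:
        """(step, cost, MI, vec(W)) rows for delimited-text export."""
        n = len(self.steps)
        wflat = np.array([w.ravel() for w in self.Ws])
        return np.column_stack([np.array(self.steps, float), self.costs, self.mis, wflat.reshape(n, -1)])

    def save(self, path, delimiter: str = "\t") -> None:
        tab = self.to_table()
        nW = tab.shape[1] - 3
        names = ["step", "cost_L", "mutual_info"] + [f"W{i}" for i in range(nW)]
        np.savetxt(path, tab, delimiter=delimiter, header=delimiter.join(names), comments="")


@dataclass(frozen=True)
class Schedule:
    """Training schedule in source-time units (defaults follow the reference
    simulations: 2e6 source steps at resolution dt = 1, the signal sparsely
    sampled every dt_update = 100 steps, learning time constant 1e3).

    Each update integrates the learning ODE by one source-resolution step,
    i.e. the per-update learning rate is dt / tau_W; dt_update sets only how
    often the signal is looked at.
    """

    T: int = 2_000_000
    dt_update: float = 100.0
    tau_W: float = 1e3
    dt: float = 1.0
    batch: int = 1
    checkpoint_every: int = 200  # in update steps
    eval_samples: int = 2000     # held-out samples for cost/MI checkpoints

    @property
    def n_updates(self) -> int:
        return int(self.T // self.dt_update)

    @property
    def eta(self) -> float:
        return 0.0 if math.isinf(self.tau_W) else self.dt / self.tau_W


# -- EGHR proper -------------------------------------------------------------

def _surprise_rows(prior: Prior, U: np.ndarray) -> np.ndarray:
    return prior.z(U).sum(axis=1)


def eghr_update(
    state: LearnerState, x_batch: np.ndarray, prior: Prior, E0: float
) -> LearnerState:
    """One EGHR step on a B x N' input batch (B = 1 is the online rule).

    dW = eta * mean_b[(E0 - E(u_b)) g(u_b) x_b^T],  u_b = W x_b.
    """
    X = np.atleast_2d(np.asarray(x_batch, dtype=float))
    U = X @ state.W.T
    if not np.all(np.isfinite(U)):
        raise DivergenceError(state.step)
    gate = E0 - _surprise_rows(prior, U)           # (B,)
    G = prior.g(U)                                 # (B, N)
    dW = (G * gate[:, None]).T @ X / X.shape[0]
    state.W = state.W + state.eta * dW
    state.step += 1
    if not np.all(np.isfinite(state.W)) or np.max(np.abs(state.W)) > W_DIVERGENCE_LIMIT:
        raise DivergenceError(state.step)
    return state


def cost_L(W: np.ndarray, x_samples: np.ndarray, prior: Prior, E0: float) -> float:
    """Sample mean of (E(Wx) - E0)^2 / 2."""
    X = np.atleast_2d(np.asarray(x_samples, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    E = _surprise_rows(prior, X @ np.asarray(W).T)
    return float(np.mean((E - E0) ** 2) / 2.0)


# -- rule stepper interface ---------------------------------------------------

class Rule:
    """Uniform stepper interface shared by all learning rules.

    ``dt_update`` is the interval (in source steps) between weight updates;
    rules with fast auxiliary dynamics use a small value.  ``update``
    consumes the current input sample(s) and returns nothing (mutates W and
    any auxiliary state in place via the ``state`` object it owns).
    """

    name = "rule"
    default_dt_update = 100.0
    default_tau_W = 1e3

    def __init__(self, prior: Prior, E0: float | None = None):
        self.prior = prior
        self.E0 = E0

    def prepare(self, N: int, Nin: int, schedule: Schedule) -> None:
        """Resolve per-run constants (e.g. the default E0 needs N)."""
        if self.E0 is None:
            self.E0 = default_E0(self.prior, N)

    def init_aux(self, N: int):
        return None

    def update(self, W: np.ndarray, aux, X: np.ndarray, eta: float) -> np.ndarray:
        raise NotImplementedError


class EGHR(Rule):
    """Error-gated Hebbian rule: dW = eta <(E0 - E(u)) g(u) x^T>."""

    name = "eghr"

    def update(self, W, aux, X, eta):
        U = X @ W.T
        gate = self.E0 - _surprise_rows(self.prior, U)
        G = self.prior.g(U)
        return W + eta * (G * gate[:, None]).T @ X / X.shape[0]


# -- training loop ------------------------------------------------------------

def _source_array(spec_or_array, T: int, seed) -> np.ndarray:
    if isinstance(spec_or_array, np.ndarray):
        return spec_or_array
    spec: SourceSpec = spec_or_array
    if spec.temporal == "iid":
        return sample_iid(spec, T, seed)
    return simulate_langevin(spec, T, seed)


def train(
    rule: Rule,
    source,
    mixing: MixingModel,
    schedule: Schedule | None = None,
    W0: np.ndarray | None = None,
    seed=0,
    record_K: bool = True,
    compute_mi: bool = False,
) -> ExperimentTrace:
    """Run one learning experiment and return its trace.

    ``source`` is a :class:`SourceSpec` (samples are generated with ``seed``)
    or a precomputed T x M source array at source resolution dt = 1.
    Checkpoints record W, the empirical cost L on a held-out buffer and,
    optionally, the pairwise mutual information of the outputs.
    """
    from .metrics import mutual_information_histogram  # local import, cycle-free

    sch = schedule or Schedule()
    A = mixing.A
    N_in, M = A.shape
    N_out = N_in  # square network over inputs; undercomplete handled via A
    W = 1.5 * np.eye(N_out, N_in) if W0 is None else np.array(W0, dtype=float)
    if W.shape != (N_out, N_in):
        raise ValueError(f"W0 shape {W.shape} incompatible with mixing {A.shape}")

    stride = max(int(sch.dt_update), 1)
    n_upd = sch.n_updates
    # Source samples at the update instants.  iid runs draw only what each
    # update consumes (the sampled instant, or the batch window); correlated
    # runs materialize the full path.
    if isinstance(source, np.ndarray):
        S_full = np.asarray(source, dtype=float)
        S_upd = S_full[stride - 1 :: stride][:n_upd]
    elif source.temporal == "iid":
        if sch.batch == 1:
            S_upd = sample_iid(source, n_upd, seed)
        else:
            S_upd = None  # drawn lazily per update block below
        S_full = None
    else:
        S_full = _source_array(source, sch.T, seed)
        S_upd = S_full[stride - 1 :: stride][:n_upd]
    eval_seed = np.random.SeedSequence([0xE6A1, abs(hash(seed)) % 2**31]).generate_state(1)[0]
    if isinstance(source, np.ndarray):
        S_eval = S_full[: sch.eval_samples]
    else:
        S_eval = sample_iid(
            SourceSpec(
                family=source.family, alpha=source.alpha, beta=source.beta,
                variance=source.variance, M=source.M,
            ),
            sch.eval_samples,
            eval_seed,
        )
    X_eval = S_eval @ A.T

    rule.prepare(N_out, N_in, sch)
    aux = rule.init_aux(N_out)
    eta = sch.eta
    trace = ExperimentTrace(meta={"rule": rule.name, "seed": seed, "schedule": sch})

    def checkpoint(k: int) -> None:
        cost = cost_L(W, X_eval, rule.prior, rule.E0)
        mi = np.nan
        if compute_mi:
            mi = mutual_information_histogram(X_eval @ W.T)
        trace.append(k, W, cost=cost, mi=mi, K=(W @ A if record_K else None))

    iid_rng = np.random.default_rng(np.random.SeedSequence([0x51D, abs(hash(seed)) % 2**31]))
    if S_full is None and S_upd is None:
        iid_spec = source

    checkpoint(0)
    try:
        for k in range(n_upd):
            if sch.batch > 1:
                if S_full is not None:
                    lo = max(0, (k + 1) * stride - sch.batch)
                    Sb = S_full[lo : (k + 1) * stride]
                else:
                    Sb = np.column_stack(
                        [_draw_marginal(iid_spec, iid_rng, sch.batch) for _ in range(M)]
                    )
                X = Sb @ A.T
            else:
                X = S_upd[k : k + 1] @ A.T
            W = rule.update(W, aux, X, eta)
            if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > W_DIVERGENCE_LIMIT:
                raise DivergenceError(k + 1, trace)
            if (k + 1) % sch.checkpoint_every == 0:
                checkpoint(k + 1)
    except DivergenceError as err:
        err.trace = trace
        raise
    if trace.steps[-1] != n_upd:
        checkpoint(n_upd)
    return trace


def init_W_unit_circle_K(A: np.ndarray, seed=0) -> np.ndarray:
    """Initial W placing every row of K = W A on the unit circle at a random
    angle (the undercomplete-experiment initialization for 2 sources)."""
    A = np.asarray(A, dtype=float)
    N, M = A.shape
    if M != 2:
        raise ValueError("unit-circle K initialization requires M = 2 sources")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=N)
    K0 = np.column_stack([np.cos(phi), np.sin(phi)])
    return K0 @ np.linalg.pinv(A)
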