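"""Evaluation and theory-checking analyses.

* Velocity maps on the rotation manifold W = (W11, W12; -W12, W11): the
  expected weight change of a rule, computed by quadrature over the source
  density, at each point of a grid in (W11, W12); fixed points are located
  and classified from the numerically differentiated field.
* A plug-in histogram estimator of the mutual information between output
  channels, with a shuffled-control floor.
* Recovery diagnostics based on K = W A: per-row alignment with signed
  coordinate axes (the ICA success criterion, also for the undercomplete
  case where K is tall) and an interference index.
* A condition grid running every rule over mixing/source/temporal
  conditions with multiple seeds and starts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .learning import DivergenceError, Schedule, train
from .priors import Prior, default_E0
from .sources import MixingModel, SourceSpec, make_mixing, rotation_matrix

__all__ = [
    "VelocityMap",
    "RecoveryReport",
    "velocity_map",
    "classify_fixed_point",
    "mutual_information_histogram",
    "recovery_report",
    "condition_grid",
    "manifold_velocity",
]

QUADRATURE_DS = 0.1
QUADRATURE_RANGE = 20.0
GRID_LO, GRID_HI, GRID_STEP = -1.5, 1.5, 0.05


def _source_grid(prior: Prior, ds: float = QUADRATURE_DS, lim: float = QUADRATURE_RANGE):
    """2-D tensor grid of source values and normalized density weights."""
    s = np.arange(-lim, lim + ds / 2, ds)
    logp = -prior.z(s)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    S1, S2 = np.meshgrid(s, s, indexing="ij")
    S = np.column_stack([S1.ravel(), S2.ravel()])
    wts = np.outer(p, p).ravel()
    return S, wts


def _expected_update(rule_name: str, W: np.ndarray, A: np.ndarray, prior: Prior,
                     E0: float, S: np.ndarray, wts: np.ndarray) -> np.ndarray:
    """Expectation of a rule's W-update by quadrature over the source density."""
    U = S @ (W @ A).T
    G = prior.g(U)
    if rule_name == "eghr":
        X = S @ A.T
        gate = (E0 - prior.z(U).sum(axis=1)) * wts
        return (G * gate[:, None]).T @ X
    Gw = G * wts[:, None]
    if rule_name == "amari":
        return (np.eye(2) - Gw.T @ U) @ W
    if rule_name == "bell_sejnowski":
        X = S @ A.T
        return np.linalg.inv(W).T - Gw.T @ X
    if rule_name == "cichocki":
        return np.eye(2) - Gw.T @ U
    raise ValueError(f"no quadrature form for rule {rule_name!r}")


def _averaged_update(rule, W: np.ndarray, A: np.ndarray, spec: SourceSpec,
                     T_avg: int, seed) -> np.ndarray:
    """Long-run averaged update of a dynamical rule (Linsker/Foldiak) with W
    frozen; the auxiliary state evolves while update directions are averaged."""
    from .sources import simulate_langevin

    sch = Schedule(T=T_avg, dt_update=rule.default_dt_update, tau_W=1.0)
    rule.prepare(W.shape[0], W.shape[1], sch)
    aux = rule.init_aux(W.shape[0])
    S = simulate_langevin(spec, T_avg, seed)
    stride = max(int(rule.default_dt_update), 1)
    S_upd = S[stride - 1 :: stride]
    burn = len(S_upd) // 5
    acc = np.zeros_like(W)
    n = 0
    for k, s_t in enumerate(S_upd):
        x = A @ s_t
        W_new = rule.update(W, aux, x[None, :], 1.0)
        if k >= burn:
            acc += W_new - W
            n += 1
    return acc / max(n, 1)


def manifold_velocity(rule_name: str, W11: float, W12: float, A: np.ndarray,
                      prior: Prior, E0: float, S: np.ndarray, wts: np.ndarray) -> np.ndarray:
    """(dW11, dW12): expected update projected onto the rotation manifold."""
    W = np.array([[W11, W12], [-W12, W11]])
    dW = _expected_update(rule_name, W, A, prior, E0, S, wts)
    return np.array([(dW[0, 0] + dW[1, 1]) / 2.0, (dW[0, 1] - dW[1, 0]) / 2.0])


@dataclass
class VelocityMap:
    """Velocity field of a rule on the rotation-parameterized weight manifold."""

    axes: np.ndarray               # grid coordinates (shared by W11 and W12)
    velocity: np.ndarray           # (n, n, 2); [i, j] = field at (W11=axes[i], W12=axes[j])
    fixed_points: list = field(default_factory=list)  # (location(2,), classification)
    rule: str = ""

    def stable_points(self) -> list[np.ndarray]:
        return [loc for loc, c in self.fixed_points if c == "stable"]

    def unstable_points(self) -> list[np.ndarray]:
        return [loc for loc, c in self.fixed_points if c == "unstable"]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=2)

    def save(self, path, delimiter: str = "\t") -> None:
        n = len(self.axes)
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        tab = np.column_stack([
            self.axes[ii.ravel()], self.axes[jj.ravel()],
            self.velocity[..., 0].ravel(), self.velocity[..., 1].ravel(),
        ])
        np.savetxt(path, tab, delimiter=delimiter,
                   header=delimiter.join(["W11", "W12", "dW11", "dW12"]), comments="")


def classify_fixed_point(field_fn, location, h: float = 0.02, cond_tol: float = 1e-8) -> str:
    """Classify a fixed point from the finite-difference Jacobian of the field.

    Both eigenvalue real parts negative -> stable; both positive ->
    unstable; mixed signs -> saddle; Jacobian below conditioning tolerance
    -> marginal.  The default stencil half-width ``h`` spans several
    quadrature-grid ripples of the field so the macroscopic Jacobian is
    recovered.
    """
    x, y = float(location[0]), float(location[1])
    J = np.empty((2, 2))
    J[:, 0] = (field_fn(x + h, y) - field_fn(x - h, y)) / (2 * h)
    J[:, 1] = (field_fn(x, y + h) - field_fn(x, y - h)) / (2 * h)
    eig = np.linalg.eigvals(J)
    scale = np.max(np.abs(eig))
    if scale < cond_tol:
        return "marginal"
    re = np.real(eig)
    if np.all(re < -cond_tol * scale):
        return "stable"
    if np.all(re > cond_tol * scale):
        return "unstable"
    return "saddle"


def _refine_fixed_point(field_fn, x0, radius: float = 0.12):
    """Refine a fixed-point candidate by minimizing the squared field norm.

    Derivative-free minimization is used because the quadrature field
    carries smooth ripples (the kink lines of the integrand sweep across
    the fixed source grid as W varies) that defeat Newton iteration; the
    minimizer settles within the ripple amplitude of the true zero.
    """
    from scipy.optimize import minimize

    x0 = np.array(x0, dtype=float)
    obj = lambda x: float(np.sum(field_fn(x[0], x[1]) ** 2))
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-14, "maxiter": 200})
    x = res.x
    if np.linalg.norm(x - x0) > radius:  # wandered off the candidate cell
        return x0
    return x


def velocity_map(
    rule_name: str,
    prior: Prior,
    mixing: MixingModel,
    E0: float | None = None,
    grid_step: float = GRID_STEP,
    ds: float = QUADRATURE_DS,
    fp_tol_factor: float = 0.02,
    source_spec: SourceSpec | None = None,
    T_avg: int = 200_000,
    seed: int = 0,
) -> VelocityMap:
    """Velocity map of a rule for a 2x2 rotation mixing matrix.

    The expected update is computed by quadrature over p0 for the rules
    whose expectation is directly computable (EGHR, Amari, Bell-Sejnowski,
    Cichocki) and by long-run averaging of the full dynamical stepper for
    Linsker/Foldiak.  Fixed points are candidate local minima of the field
    magnitude, refined by derivative-free minimization and accepted when
    the refined field norm is below ``fp_tol_factor`` times the grid-median
    norm, then classified by the sign pattern of the numerical Jacobian.
    The default acceptance factor reflects the O(ds^2) bias floor of the
    fixed-grid quadrature over an integrand with moving kink lines.
    """
    A = mixing.A
    if A.shape != (2, 2) or not np.allclose(A.T @ A, (A[0, 0] ** 2 + A[1, 0] ** 2) * np.eye(2), atol=1e-10):
        raise ValueError("velocity_map requires a (possibly scaled) 2x2 rotation mixing matrix")
    if E0 is None:
        E0 = default_E0(prior, 2)

    if rule_name in ("eghr", "amari", "bell_sejnowski", "cichocki"):
        S, wts = _source_grid(prior, ds=ds)
        field_fn = lambda a, b: manifold_velocity(rule_name, a, b, A, prior, E0, S, wts)
    elif rule_name in ("linsker", "foldiak"):
        from .rules import make_rule

        if source_spec is None:
            source_spec = SourceSpec(family=prior.family, variance=prior.variance,
                                     temporal="langevin", tau_s=50.0, dt=1.0)

        def field_fn(a, b, _cache={}):
            key = (round(a, 9), round(b, 9))
            if key not in _cache:
                rule = make_rule(rule_name, prior)
                W = np.array([[a, b], [-b, a]])
                dW = _averaged_update(rule, W, A, source_spec, T_avg, seed)
                _cache[key] = np.array([(dW[0, 0] + dW[1, 1]) / 2, (dW[0, 1] - dW[1, 0]) / 2])
            return _cache[key]
    else:
        raise ValueError(f"unknown rule {rule_name!r}")

    axes = np.arange(GRID_LO, GRID_HI - 1e-12, grid_step)
    n = len(axes)
    V = np.empty((n, n, 2))
    for i, a in enumerate(axes):
        for j, b in enumerate(axes):
            V[i, j] = field_fn(a, b)

    mag = np.linalg.norm(V, axis=2)
    med = np.median(mag)
    # candidate cells: strict local minima of the field magnitude
    fps: list[tuple[np.ndarray, str]] = []
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            window = mag[i - 1 : i + 2, j - 1 : j + 2]
            if mag[i, j] == window.min() and mag[i, j] < 0.5 * med:
                x = _refine_fixed_point(field_fn, (axes[i], axes[j]))
                if np.linalg.norm(field_fn(*x)) >= fp_tol_factor * med:
                    continue
                if any(np.linalg.norm(x - loc) < grid_step for loc, _ in fps):
                    continue
                fps.append((x, classify_fixed_point(field_fn, x)))
    return VelocityMap(axes=axes, velocity=V, fixed_points=fps, rule=rule_name)


# -- mutual information --------------------------------------------------------

def _plugin_mi(u1: np.ndarray, u2: np.ndarray, bins: int) -> float:
    lo1, hi1 = np.percentile(u1, [0.5, 99.5])
    lo2, hi2 = np.percentile(u2, [0.5, 99.5])
    H, _, _ = np.histogram2d(u1, u2, bins=bins, range=[[lo1, hi1], [lo2, hi2]])
    p = H / H.sum()
    p1 = p.sum(axis=1, keepdims=True)
    p2 = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(p1) - np.log(p2))
    return float(np.nansum(terms))


def mutual_information_histogram(
    u_samples: np.ndarray, bins: int = 30, shuffle_control: bool = False, seed: int = 0
) -> float:
    """Plug-in histogram estimate (nats) of the mutual information between
    output channels; the mean over channel pairs when there are more than 2.

    ``shuffle_control=True`` instead returns the estimator floor obtained by
    permuting each second channel (destroying dependence while keeping the
    marginals), useful as a bias reference for the plug-in estimate.
    """
    U = np.atleast_2d(np.asarray(u_samples, dtype=float))
    T, C = U.shape
    if C < 2:
        raise ValueError("need at least two channels")
    rng = np.random.default_rng(seed)
    vals = []
    for i, j in itertools.combinations(range(C), 2):
        u2 = rng.permutation(U[:, j]) if shuffle_control else U[:, j]
        vals.append(_plugin_mi(U[:, i], u2, bins))
    return float(np.mean(vals))


# -- recovery diagnostics ------------------------------------------------------

@dataclass
class RecoveryReport:
    """Axis-alignment diagnostics of the source-to-output matrix K = W A."""

    K: np.ndarray
    angles_deg: np.ndarray        # per-row angle to the nearest signed axis
    gains: np.ndarray             # per-row norm
    axes_idx: np.ndarray          # per-row nearest axis index (argmax |K_ij|)
    interference: np.ndarray      # per-row off-axis energy fraction, in [0, 1]
    aligned: np.ndarray           # per-row boolean at the requested tolerance
    angle_tol_deg: float

    @property
    def aligned_count(self) -> int:
        return int(np.sum(self.aligned))

    @property
    def sources_covered(self) -> int:
        """Number of distinct sources having at least one aligned row."""
        return len(set(self.axes_idx[self.aligned].tolist()))

    @property
    def max_interference(self) -> float:
        return float(np.max(self.interference))


def recovery_report(W: np.ndarray, A: np.ndarray, angle_tol_deg: float = 5.0) -> RecoveryReport:
    """Per-row alignment of K = W A with the signed coordinate axes."""
    K = np.asarray(W, dtype=float) @ np.asarray(A, dtype=float)
    norms = np.linalg.norm(K, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    frac = np.abs(K) / safe[:, None]
    axes_idx = np.argmax(np.abs(K), axis=1)
    cosang = np.clip(frac[np.arange(K.shape[0]), axes_idx], -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    angles[norms == 0] = 90.0  # zero rows are unaligned by convention
    interference = 1.0 - cosang**2
    interference[norms == 0] = 1.0
    aligned = (angles < angle_tol_deg) & (norms > 0)
    return RecoveryReport(
        K=K, angles_deg=angles, gains=norms, axes_idx=axes_idx,
        interference=interference, aligned=aligned, angle_tol_deg=angle_tol_deg,
    )


def match_rows_to_sources(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal row->source assignment (for square K): returns (perm, signs)
    maximizing the matched absolute gains via the Hungarian algorithm."""
    cost = -np.abs(K)
    rows, cols = linear_sum_assignment(cost)
    signs = np.sign(K[rows, cols])
    return cols, signs


# -- condition grid ------------------------------------------------------------

_STARTS = {
    "identity+": lambda N: 1.5 * np.eye(N),
    "identity-": lambda N: -1.5 * np.eye(N),
    "small+": lambda N: 0.8 * np.eye(N),
}


def condition_grid(
    rule_names,
    conditions,
    n_seeds: int = 5,
    starts=("identity+", "identity-", "small+"),
    schedule: Schedule | None = None,
    angle_tol_deg: float = 5.0,
    success_threshold: float = 1.0,
):
    """Success-fraction table of rules x conditions.

    ``conditions`` is an iterable of dicts with keys ``mixing`` (one of
    rotation / non_rotation / undercomplete), ``family`` (laplace/uniform)
    and ``temporal`` (iid/langevin).  Success of one run = every K row
    axis-aligned at tolerance and every source covered by some aligned row.
    Returns a pandas DataFrame with one row per (rule, condition) cell.
    """
    import pandas as pd

    from .rules import make_rule

    rows = []
    for rule_name, cond in itertools.product(rule_names, conditions):
        mixing = _condition_mixing(cond)
        spec = SourceSpec(
            family=cond.get("family", "laplace"),
            temporal=cond.get("temporal", "iid"),
            tau_s=cond.get("tau_s", 50.0),
            M=mixing.M,
        )
        prior = spec.prior
        sch = schedule or Schedule()
        n_ok = n_run = 0
        for seed, start in itertools.product(range(n_seeds), starts):
            W0 = _STARTS[start](mixing.N)
            rule = make_rule(rule_name, prior)
            n_run += 1
            try:
                tr = train(rule, spec, mixing, schedule=sch, W0=W0, seed=seed)
            except DivergenceError:
                continue
            rep = recovery_report(tr.averaged_W(), mixing.A, angle_tol_deg)
            if rep.aligned_count == mixing.N and rep.sources_covered == mixing.M:
                n_ok += 1
        rows.append({
            "rule": rule_name, **cond, "n_runs": n_run, "n_success": n_ok,
            "success_fraction": n_ok / n_run if n_run else np.nan,
            "tick": n_ok >= success_threshold * n_run,
        })
    return pd.DataFrame(rows)


def _condition_mixing(cond) -> MixingModel:
    kind = cond.get("mixing", "rotation")
    if kind == "rotation":
        return make_mixing("rotation", theta=cond.get("theta", math.pi / 6))
    if kind == "non_rotation":
        return make_mixing("explicit", A=np.array([[1.0, 0.5], [0.5, 1.0]]))
    if kind == "undercomplete":
        return make_mixing("stacked_rotation", N=cond.get("N", 8))
    raise ValueError(f"unknown mixing condition {kind!r}")
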