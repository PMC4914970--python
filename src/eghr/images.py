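"""End-to-end blind source separation on synthetic images.

Mirrors the natural-image demonstration: several grayscale source images
are superposed pixel-wise through a random invertible mixing matrix, the
error-gated rule is trained on pixels sampled one at a time from the mixed
stack, and the learned W is applied to reconstruct the sources (up to
permutation, sign, and scale).

The sources here are generated textures (oriented gratings, square waves)
whose pixel histograms are sub-Gaussian — negative excess kurtosis, like
the natural photographs they stand in for — plus one Gaussian white-noise
channel; a uniform prior is therefore the matched choice for training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .priors import Prior, default_E0

__all__ = ["ImageStack", "generate_synthetic_images", "run_image_bss", "BssMatchReport"]


@dataclass
class ImageStack:
    """List of equal-shape zero-mean 2-D intensity arrays (one per channel)."""

    images: list

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("all images must share one shape")

    @property
    def n(self) -> int:
        return len(self.images)

    @property
    def shape(self):
        return self.images[0].shape

    def as_matrix(self) -> np.ndarray:
        """pixels x channels matrix."""
        return np.column_stack([im.ravel() for im in self.images])

    @classmethod
    def from_matrix(cls, X: np.ndarray, shape) -> "ImageStack":
        return cls([X[:, i].reshape(shape) for i in range(X.shape[1])])


def _bounded_quantile_map(gamma: float = 10.0):
    """Quantile transform onto the soft-walled uniform intensity law.

    Returns a function mapping ranks in (0, 1) to intensities distributed
    as the smoothed uniform density exp(-z)/Z (zero mean, unit variance up
    to smoothing corrections) — the bounded histogram natural photographs
    approximate and the one the uniform-prior learner assumes.
    """
    from .priors import Prior

    p = Prior(family="uniform", gamma=gamma)
    grid = np.linspace(-5.0, 5.0, 20001)
    pdf = np.exp(-p.z(grid))
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    return lambda ranks: np.interp(ranks, cdf, grid)


def _oriented_texture(shape, freq, angle, bandwidth, rng, qmap) -> np.ndarray:
    """Oriented band-pass-filtered white noise, histogram-equalized to a
    bounded (sub-Gaussian) intensity law.

    Each channel is built from its own independent noise field, so pixel
    values of distinct channels are mutually independent (deterministic
    gratings would not be: their joint pixel histogram does not
    factorize).  The rank-based equalization keeps the oriented spatial
    structure while pinning the marginal.
    """
    from scipy.stats import rankdata

    h, w = shape
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None] * h
    fx = np.fft.fftfreq(w)[None, :] * w
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    radial = np.exp(-((r - freq) ** 2) / (2 * bandwidth**2))
    dtheta = np.angle(np.exp(1j * 2 * (theta - angle))) / 2  # pi-periodic distance
    angular = np.exp(-(dtheta**2) / (2 * 0.4**2))
    f = np.real(np.fft.ifft2(np.fft.fft2(noise) * radial * angular))
    ranks = rankdata(f.ravel()) / (f.size + 1)
    return qmap(ranks).reshape(shape)


def generate_synthetic_images(n_images: int, shape=(64, 64), seed=0) -> ImageStack:
    """Textured source images plus one white-noise channel.

    Each textured channel is an oriented band-pass noise texture with a
    randomly drawn peak frequency, orientation and bandwidth, histogram-
    equalized to a bounded intensity law, so its pixel histogram is
    sub-Gaussian (negative excess kurtosis); the final channel is spatially
    white noise with the same bounded histogram.  All channels are
    standardized to zero mean and unit variance, and distinct channels are
    independent by construction.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    qmap = _bounded_quantile_map()
    images = []
    for i in range(n_images - 1):
        freq = rng.uniform(4.0, 10.0)
        angle = i * math.pi / max(n_images - 1, 1) + rng.uniform(-0.2, 0.2)
        bandwidth = rng.uniform(1.5, 3.0)
        images.append(_oriented_texture(shape, freq, angle, bandwidth, rng, qmap))
    # white-noise channel: spatially uncorrelated, bounded intensity histogram
    noise = rng.standard_normal(shape)
    ranks = rankdata(noise.ravel()) / (noise.size + 1)
    images.append(qmap(ranks).reshape(shape))
    out = []
    for im in images:
        im = im - im.mean()
        out.append(im / im.std())
    return ImageStack(out)


@dataclass
class BssMatchReport:
    """Best-match assignment between true sources and network outputs."""

    permutation: np.ndarray       # output index assigned to each source
    correlations: np.ndarray      # |corr| of each source with its match
    W: np.ndarray

    @property
    def min_correlation(self) -> float:
        return float(np.min(self.correlations))


def _match_outputs(S: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = S.shape[1]
    C = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = abs(np.corrcoef(S[:, i], U[:, j])[0, 1])
    rows, cols = linear_sum_assignment(-C)
    return cols, C[rows, cols]


def run_image_bss(
    stack: ImageStack,
    A: np.ndarray,
    prior: Prior | None = None,
    n_steps: int = 2_000_000,
    tau_W: float = 2e4,
    seed: int = 0,
    W0: np.ndarray | None = None,
    sampling: str = "random",
) -> tuple[ImageStack, BssMatchReport]:
    """Train the error-gated rule on a mixed pixel stream and reconstruct.

    Pixels of the mixed images are standardized per channel, presented one
    at a time (``sampling='random'`` with replacement, or ``'raster'`` scan
    order cycled), and the online rule is applied at every presentation
    with learning rate 1/tau_W.  Returns the unmixed image stack (outputs
    permuted/sign-corrected to match the sources) and a match report with
    per-source absolute correlations.
    """
    A = np.asarray(A, dtype=float)
    n = stack.n
    if A.shape != (n, n):
        raise ValueError(f"mixing matrix {A.shape} does not match {n} images")
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("mixing matrix is singular")
    if prior is None:
        prior = Prior(family="uniform")
    S = stack.as_matrix()
    X = S @ A.T
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    rng = np.random.default_rng(seed)
    P = X.shape[0]
    if sampling == "random":
        idx = rng.integers(0, P, size=n_steps)
    elif sampling == "raster":
        idx = np.resize(np.arange(P), n_steps)
    else:
        raise ValueError("sampling must be 'random' or 'raster'")

    E0 = default_E0(prior, n)
    W = np.eye(n) if W0 is None else np.array(W0, dtype=float)
    z, g = prior.z, prior.g
    # present pixels in small blocks: one block applies the averaged update
    # with a step of block_size/tau_W, first-order equivalent to block_size
    # online presentations but vectorized
    block = max(1, min(20, n_steps))
    eta = block / tau_W
    W_acc = np.zeros_like(W)
    n_acc = 0
    tail_start = int(0.75 * (n_steps // block))
    for k in range(n_steps // block):
        Xb = X[idx[k * block : (k + 1) * block]]
        U = Xb @ W.T
        gate = E0 - prior.z(U).sum(axis=1)
        G = prior.g(U)
        W += eta * (G * gate[:, None]).T @ Xb / Xb.shape[0]
        if not np.all(np.isfinite(W)):
            from .learning import DivergenceError

            raise DivergenceError(k)
        if k >= tail_start:
            W_acc += W
            n_acc += 1
    W = W_acc / max(n_acc, 1)  # tail-averaged weights (suppresses jitter)

    U = X @ W.T
    perm, corrs = _match_outputs(S, U)
    # permute, sign-correct and rescale outputs to match the sources
    out = []
    for i in range(n):
        u = U[:, perm[i]]
        sgn = np.sign(np.corrcoef(S[:, i], u)[0, 1]) or 1.0
        u = sgn * u
        u = (u - u.mean()) / u.std()
        out.append(u.reshape(stack.shape))
    return ImageStack(out), BssMatchReport(permutation=perm, correlations=corrs, W=W)
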