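"""Synthetic data generators for the linear and PS-based study conditions.

Two families of generators are provided.  The *linear* family draws
multivariate normal scores with a target covariance, optionally
discretized to b-point ordinal scales through a Gaussian copula whose
intermediate correlations are adjusted so the ordinal scores reproduce the
target Pearson correlations (the behaviour of GenOrd-style ordinal
samplers).  The *PS* family replaces each normal score by a draw whose
only retained information is the side of the column mean the score fell
on, so any two transformed columns are related purely through the
probability of superiority -- the orthant probability asin(rho)/pi + 0.5
of the generating correlation -- while their Pearson correlation is
attenuated.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .ps_core import sign_pattern

__all__ = [
    "PSGenSpec",
    "ScaleSpec",
    "generate_linear_continuous",
    "discretize_to_scale",
    "ordinal_intermediate_corr",
    "ps_transform_continuous",
    "ps_transform_binary",
    "ps_transform_ordinal",
    "blomqvist_pairs",
    "generate_condition",
]

#: Half-width of the uniform magnitude distribution in the continuous PS
#: transform: sqrt(12)/2, chosen so the transformed scores have SD 1.
UNIFORM_HALF_WIDTH = math.sqrt(12.0) / 2.0

ORDINAL_POINTS = (2, 3, 5, 7)


@dataclass(frozen=True)
class PSGenSpec:
    """Parameters of the bivariate PS (Blomqvist-type) generating process."""

    gamma: float          # population probability of superiority
    c: float = UNIFORM_HALF_WIDTH   # uniform limit for |y|
    mu_x: float = 0.0
    mu_y: float = 0.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.c <= 0:
            raise ValueError("c must be positive")


@dataclass(frozen=True)
class ScaleSpec:
    """One measurement-scale condition: relation x scale of measurement."""

    relation: str            # "linear" or "ps"
    kind: str                # "continuous" or "ordinal"
    points: int | None = None

    def __post_init__(self):
        if self.relation not in ("linear", "ps"):
            raise ValueError("relation must be 'linear' or 'ps'")
        if self.kind == "ordinal":
            if self.points not in ORDINAL_POINTS:
                raise ValueError(f"ordinal points must be one of {ORDINAL_POINTS}")
        elif self.kind == "continuous":
            if self.points is not None:
                raise ValueError("continuous scale takes no points")
        else:
            raise ValueError("kind must be 'continuous' or 'ordinal'")

    @property
    def label(self) -> str:
        pts = "cont" if self.points is None else f"{self.points}pt"
        return f"{self.relation}-{pts}"


def all_scales() -> list[ScaleSpec]:
    """The ten measurement-scale conditions (5 linear + 5 PS)."""
    out = []
    for relation in ("linear", "ps"):
        out.append(ScaleSpec(relation, "continuous"))
        out.extend(ScaleSpec(relation, "ordinal", b) for b in ORDINAL_POINTS)
    return out


def generate_linear_continuous(sigma, n: int, seed) -> np.ndarray:
    """Draw ``n`` rows from a zero-mean multivariate normal with covariance
    ``sigma``; reproducible given ``seed`` (an int or a Generator)."""
    sigma = np.asarray(sigma, dtype=float)
    if n < 1:
        raise ValueError("n must be positive")
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma must be positive-definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, sigma.shape[0]))
    return z @ chol.T


def discretize_to_scale(x, b: int) -> np.ndarray:
    """Cut each column at standard-normal quantiles into ``b`` equal-probability
    categories coded 1..b.  Monotone: a larger score never maps lower."""
    if b not in ORDINAL_POINTS:
        raise ValueError(f"b must be one of {ORDINAL_POINTS}")
    x = np.asarray(x, dtype=float)
    cuts = stats.norm.ppf(np.arange(1, b) / b)
    return (np.searchsorted(cuts, x.ravel()).reshape(x.shape) + 1).astype(np.int64)


def _discretized_corr(rho: float, b: int) -> float:
    """Pearson correlation between two b-category equal-probability
    discretizations of a bivariate normal pair with correlation ``rho``."""
    cuts = stats.norm.ppf(np.arange(1, b) / b)
    # joint CDF on the grid of finite thresholds
    bvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]])
    grid = np.array([[bvn.cdf([u, v]) for v in cuts] for u in cuts])
    full = np.zeros((b + 1, b + 1))
    full[1:b, 1:b] = grid
    full[b, 1:b] = stats.norm.cdf(cuts)
    full[1:b, b] = stats.norm.cdf(cuts)
    full[b, b] = 1.0
    cells = np.diff(np.diff(full, axis=0), axis=1)     # P(category i, j)
    scores = np.arange(1, b + 1, dtype=float)
    exy = scores @ cells @ scores
    mu = (b + 1) / 2.0
    var = (b * b - 1) / 12.0
    return (exy - mu * mu) / var


@lru_cache(maxsize=256)
def ordinal_intermediate_corr(target: float, b: int) -> float:
    """Latent normal correlation whose b-point discretization has Pearson
    correlation ``target`` (the GenOrd/ordsample compensation step)."""
    if target == 0.0:
        return 0.0
    lo, hi = (0.0, 0.9995) if target > 0 else (-0.9995, 0.0)
    f = lambda r: _discretized_corr(r, b) - target
    if f(hi) < 0 if target > 0 else f(lo) > 0:
        raise ValueError(f"target correlation {target} unreachable at b={b}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def _adjusted_sigma(sigma: np.ndarray, b: int) -> np.ndarray:
    """Elementwise intermediate-correlation adjustment of a correlation
    matrix, clipped back to positive-definiteness if needed."""
    p = sigma.shape[0]
    out = np.eye(p)
    for j in range(p):
        for k in range(j + 1, p):
            out[j, k] = out[k, j] = ordinal_intermediate_corr(
                round(float(sigma[j, k]), 10), b)
    w = np.linalg.eigvalsh(out)
    if w[0] < 1e-8:
        ww, v = np.linalg.eigh(out)
        out = (v * np.maximum(ww, 1e-8)) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
    return out


def ps_transform_continuous(x, rng) -> np.ndarray:
    """Continuous PS transform: each score becomes a uniform draw on
    (0, sqrt(12)/2) when above its column mean, on (-sqrt(12)/2, 0)
    otherwise, so only the side of the mean is retained and the marginal
    SD is 1 in expectation."""
    x = np.asarray(x, dtype=float)
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant column")
    rng = np.random.default_rng(rng)
    above = x > x.mean(axis=0)
    mag = rng.uniform(0.0, UNIFORM_HALF_WIDTH, size=x.shape)
    return np.where(above, mag, -mag)


def ps_transform_binary(x) -> np.ndarray:
    """Binary PS transform: indicator of exceeding the column mean."""
    x = np.asarray(x, dtype=float)
    return (x > x.mean(axis=0)).astype(np.int64)


def ps_transform_ordinal(x, b: int, rng) -> np.ndarray:
    """Ordinal PS transform to a b-point centered scale (b odd).

    The cutoff c = b/2 + 0.01 splits the b integer categories
    {-floor(c), ..., floor(c)} into a lower and an upper side: scores
    above their column mean draw uniformly from {0, ..., floor(c)} and
    scores at or below it from {-floor(c), ..., -1}.  The two sides are
    disjoint, so the transform preserves exactly which side of its mean
    every score lies on (the column mean of the transformed scores always
    falls between -1 and 0), and the probability of superiority between
    any two columns is untouched.
    """
    if b % 2 == 0:
        raise ValueError("even b is the binary transform; use ps_transform_binary")
    if b < 3:
        raise ValueError("b must be >= 3 and odd")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(rng)
    m = int(b / 2 + 0.01)
    above = x > x.mean(axis=0)
    upper = rng.integers(0, m + 1, size=x.shape)
    lower = rng.integers(-m, 0, size=x.shape)
    return np.where(above, upper, lower).astype(np.int64)


def blomqvist_pairs(spec: PSGenSpec, x_dist: str = "normal") -> np.ndarray:
    """Bivariate generator with a prescribed population PS ``gamma``.

    x is drawn from ``x_dist``; y falls on the same side of its mean as x
    with probability gamma (uniform magnitudes up to ``c``), on the
    opposite side otherwise, and exactly at the mean when x is at its
    mean.  Returns an (n, 2) array.
    """
    rng = np.random.default_rng(spec.seed)
    if x_dist == "normal":
        x = spec.mu_x + rng.standard_normal(spec.n)
    elif x_dist == "uniform":
        x = spec.mu_x + rng.uniform(-spec.c, spec.c, spec.n)
    elif x_dist == "lognormal":
        x = spec.mu_x + rng.lognormal(size=spec.n)
    else:
        raise ValueError(f"unknown x distribution {x_dist!r}")
    tau = rng.uniform(size=spec.n)
    mag = rng.uniform(0.0, spec.c, size=spec.n)
    above_x = x > spec.mu_x
    concordant = tau <= spec.gamma
    y_above = above_x == concordant     # same side iff tau <= gamma
    y = spec.mu_y + np.where(y_above, mag, -mag)
    y[x == spec.mu_x] = spec.mu_y
    return np.column_stack([x, y])


def generate_condition(sigma, scale: ScaleSpec, n: int, seed) -> np.ndarray:
    """Generate one study dataset for a measurement-scale condition.

    linear/continuous -> MVN; linear/ordinal -> copula-adjusted MVN cut at
    equal-probability thresholds; ps/continuous, ps/2-point, ps/ordinal ->
    MVN followed by the corresponding side-of-mean transform.
    """
    sigma = np.asarray(sigma, dtype=float)
    rng = np.random.default_rng(seed)
    if scale.relation == "linear":
        if scale.kind == "continuous":
            return generate_linear_continuous(sigma, n, rng)
        latent = generate_linear_continuous(_adjusted_sigma(sigma, scale.points),
                                            n, rng)
        return discretize_to_scale(latent, scale.points)
    x = generate_linear_continuous(sigma, n, rng)
    if scale.kind == "continuous":
        return ps_transform_continuous(x, rng)
    if scale.points == 2:
        return ps_transform_binary(x)
    return ps_transform_ordinal(x, scale.points, rng)
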