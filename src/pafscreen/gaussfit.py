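"""Gaussian P-wave fitting by the hybrid Taguchi-genetic algorithm (HTGA).

A delineated, baseline-subtracted P-wave of D points is modelled as

    y(i) = A * exp(-((i - C) / W)**2),   i = 1..D (1-based),

and the sum of squared errors between the segment and y is minimised over
(A, C, W).  The optimiser is a generational genetic algorithm whose
crossover is the Taguchi method: for each mating pair, candidate children
are the rows of a two-level L4(2^3) orthogonal array over the three factors
(A, C, W) — level 1 taking the gene from parent 1, level 2 from parent 2.
Each row's fitting error is converted to a signal-to-noise ratio
eta = -10*log10(SSE + eps), and the child takes, for every factor, the level
with the larger mean SNR across the array rows.  Selection is binary
tournament, mutation is per-gene Gaussian perturbation clipped to bounds,
and elitism re-injects the incumbent best each generation, so the reported
best SSE is non-increasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "GaussianParams",
    "PWaveSegment",
    "HTGAConfig",
    "gaussian_eval",
    "fit_sse",
    "taguchi_crossover",
    "htga_fit",
    "default_bounds",
]

#: Guard against log10(0) at perfect fits.
SNR_EPS = 1e-12

#: L4(2^3) orthogonal array (1-indexed levels) for three two-level factors.
L4 = np.array(
    [
        [1, 1, 1],
        [1, 2, 2],
        [2, 1, 2],
        [2, 2, 1],
    ]
)


@dataclass
class GaussianParams:
    """Gaussian parameters in segment sample-index coordinates (i = 1..D)."""

    A: float
    C: float
    W: float

    def __post_init__(self):
        if not (self.W > 0):
            raise ValueError(f"Gaussian width W must be positive, got {self.W}")
        if not np.isfinite(self.A):
            raise ValueError("amplitude A must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.C, self.W], dtype=float)


@dataclass
class PWaveSegment:
    """A baseline-subtracted P-wave of D >= 4 finite samples."""

    values: np.ndarray
    D: int = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 4:
            raise ValueError("P-wave segment needs at least 4 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("P-wave segment must be finite")
        self.D = int(self.values.size)


@dataclass
class HTGAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    bounds: tuple[tuple[float, float], ...] | None = None  # ((A), (C), (W)) or None
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4 or self.population_size % 2:
            raise ConfigurationError("population_size must be even and >= 4")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if self.bounds is not None:
            if len(self.bounds) != 3:
                raise ConfigurationError("bounds must give (low, high) for A, C, W")
            for lo, hi in self.bounds:
                if not (lo < hi):
                    raise ConfigurationError(f"invalid bounds ({lo}, {hi}): low < high required")


def default_bounds(segment: PWaveSegment) -> tuple[tuple[float, float], ...]:
    """Search box enclosing plausible P morphology for this segment."""
    amax = float(np.max(np.abs(segment.values)))
    if amax == 0:
        amax = 1.0
    return ((0.0, 2.0 * amax), (1.0, float(segment.D)), (0.5, float(segment.D)))


def gaussian_eval(params: GaussianParams, i) -> np.ndarray | float:
    """Evaluate A*exp(-((i-C)/W)^2) at scalar or array i."""
    i = np.asarray(i, dtype=float)
    out = params.A * np.exp(-(((i - params.C) / params.W) ** 2))
    return float(out) if out.ndim == 0 else out


def fit_sse(params: GaussianParams, segment: PWaveSegment) -> float:
    """Sum of squared errors of the Gaussian against the segment (i = 1..D)."""
    i = np.arange(1, segment.D + 1, dtype=float)
    resid = segment.values - gaussian_eval(params, i)
    return float(np.dot(resid, resid))


def _sse_batch(pop: np.ndarray, values: np.ndarray) -> np.ndarray:
    """SSE of each (A, C, W) row of ``pop`` against ``values`` (i = 1..D)."""
    i = np.arange(1, values.size + 1, dtype=float)
    A = pop[:, 0:1]
    C = pop[:, 1:2]
    W = pop[:, 2:3]
    y = A * np.exp(-(((i[None, :] - C) / W) ** 2))
    resid = values[None, :] - y
    return np.einsum("ij,ij->i", resid, resid)


def _taguchi_children(p1: np.ndarray, p2: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Vectorised Taguchi crossover for n mating pairs.

    p1, p2: (n, 3) parent gene matrices.  Returns the (n, 3) children.
    """
    n = p1.shape[0]
    # candidate rows of the L4 array: (n, 4, 3)
    take2 = (L4 == 2)[None, :, :]  # (1, 4, 3)
    cand = np.where(take2, p2[:, None, :], p1[:, None, :])
    sse = _sse_batch(cand.reshape(-1, 3), values).reshape(n, 4)
    eta = -10.0 * np.log10(sse + SNR_EPS)
    child = np.empty_like(p1)
    for f in range(3):
        lvl1 = L4[:, f] == 1
        m1 = eta[:, lvl1].mean(axis=1)
        m2 = eta[:, ~lvl1].mean(axis=1)
        child[:, f] = np.where(m1 >= m2, p1[:, f], p2[:, f])
    return child


def taguchi_crossover(
    parent1: GaussianParams, parent2: GaussianParams, segment: PWaveSegment
) -> GaussianParams:
    """SNR-guided Taguchi crossover of two parents over one segment.

    Ties in mean SNR keep parent 1's gene.
    """
    child = _taguchi_children(
        parent1.as_array()[None, :], parent2.as_array()[None, :], segment.values
    )[0]
    return GaussianParams(A=float(child[0]), C=float(child[1]), W=float(child[2]))


def htga_fit(
    segment: PWaveSegment, config: HTGAConfig | None = None, with_history: bool = False
):
    """Fit (A, C, W) to a P-wave segment by the HTGA.

    Returns ``(GaussianParams, sse)`` — or ``(params, sse, history)`` with the
    best-ever SSE after each generation when ``with_history`` is true.
    Deterministic under a fixed ``config.seed``.
    """
    if config is None:
        config = HTGAConfig()
    bounds = config.bounds if config.bounds is not None else default_bounds(segment)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.any(lo >= hi):
        raise ConfigurationError("bounds require low < high for every parameter")
    # width must stay positive regardless of user bounds
    lo[2] = max(lo[2], 1e-6)

    rng = np.random.default_rng(config.seed)
    n = config.population_size
    values = segment.values
    pop = rng.uniform(lo, hi, size=(n, 3))
    sse = _sse_batch(pop, values)
    best_idx = int(np.argmin(sse))
    best = pop[best_idx].copy()
    best_sse = float(sse[best_idx])
    history = [best_sse]

    mut_sd = 0.1 * (hi - lo)
    for _ in range(config.generations):
        # binary tournament selection of two parent pools
        cand = rng.integers(0, n, size=(2, n, 2))
        pick = np.where(sse[cand[..., 0]] <= sse[cand[..., 1]], cand[..., 0], cand[..., 1])
        p1, p2 = pop[pick[0]], pop[pick[1]]
        do_cx = rng.random(n) < config.crossover_rate
        children = p1.copy()
        if np.any(do_cx):
            children[do_cx] = _taguchi_children(p1[do_cx], p2[do_cx], values)
        # per-gene Gaussian perturbation mutation, clipped to bounds
        mut_mask = rng.random((n, 3)) < config.mutation_rate
        noise = rng.normal(0.0, 1.0, size=(n, 3)) * mut_sd
        children = np.clip(np.where(mut_mask, children + noise, children), lo, hi)
        child_sse = _sse_batch(children, values)
        # elitism: re-inject incumbent best over the worst child
        worst = int(np.argmax(child_sse))
        children[worst] = best
        child_sse[worst] = best_sse
        pop, sse = children, child_sse
        gen_best = int(np.argmin(sse))
        if sse[gen_best] < best_sse:
            best_sse = float(sse[gen_best])
            best = pop[gen_best].copy()
        history.append(best_sse)

    params = GaussianParams(A=float(best[0]), C=float(best[1]), W=float(best[2]))
    if with_history:
        return params, best_sse, history
    return params, best_sse
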