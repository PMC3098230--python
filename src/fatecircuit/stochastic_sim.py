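"""Stochastic simulation of the circuit and attractor-landscape estimation.

The noisy circuit adds independent additive Gaussian noise of standard
deviation sigma to each coordinate of the generic system and is integrated by
the Euler-Maruyama scheme,

    x_{n+1} = x_n + f_x(x_n, y_n)*dt + sigma*sqrt(dt)*xi_n,

with each coordinate clamped at zero from below after every step, since the
variables are protein concentrations.  The stationary occupancy of long
trajectories on the (x, y) plane visualizes the attractor landscape: its
local maxima ("modes") are the noisy attractors, and in the degenerate b = c
regime the occupancy spreads along the steady-state manifold with x and y
inversely related — the model's picture of a heterogeneous progenitor
population.

At the default noise level the committed basins do not exchange trajectories
on any feasible timescale, so the landscape of a multistable regime is
estimated from an ensemble of trajectories started across the state space
(a population of cells), pooling their post-burn-in samples
(:func:`attractor_landscape`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .circuit_dynamics import GenericParams
from .degenerate_manifold import detect_degeneracy, manifold_y_of_x, x_max

__all__ = [
    "SDEConfig",
    "DensityGrid",
    "simulate",
    "integrate_euler",
    "stationary_density",
    "count_modes",
    "manifold_residence",
    "attractor_landscape",
]

#: divergence guard: the admissible region is O(1), anything beyond this is a
#: numerically exploded trajectory
_DIVERGENCE_BOUND = 1e3


@dataclass(frozen=True)
class SDEConfig:
    """Configuration of an Euler-Maruyama run.

    sigma is the noise standard deviation (per sqrt(time)); the trajectory
    length is T = n_steps*dt; the leading ``burn_in_fraction`` of samples is
    discarded before any stationary statistic.
    """

    sigma: float = 0.05
    dt: float = 0.01
    n_steps: int = 1_000_000
    burn_in_fraction: float = 0.1
    seed: int = 0
    initial_state: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if min(self.initial_state) < 0:
            raise ValueError("initial state must be nonnegative")

    @property
    def T(self) -> float:
        return self.n_steps * self.dt


@dataclass(frozen=True)
class DensityGrid:
    """Normalized 2-D stationary occupancy with detected modes."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    prob: np.ndarray  # shape (n_bins_x, n_bins_y), sums to 1
    modes: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def _drift_closure(p: GenericParams):
    a, f = p.a, p.f
    bx, cx, dx = p.bx, p.cx, p.dx
    by, cy, dy = p.by, p.cy, p.dy

    def drift(x: float, y: float) -> tuple[float, float]:
        fx = a * x / ((1.0 + bx * x) * (1.0 + cx * y)) - dx * x
        fy = f * y / ((1.0 + by * y) * (1.0 + cy * x)) - dy * y
        return fx, fy

    return drift


def simulate(p: GenericParams, cfg: SDEConfig) -> np.ndarray:
    """Euler-Maruyama trajectory of shape (n_steps + 1, 2).

    Reproducible for a given seed; with sigma = 0 the arithmetic matches
    :func:`integrate_euler` bitwise.  Raises if the state exceeds the
    divergence bound (dt too large for the parameters).
    """
    drift = _drift_closure(p)
    x, y = float(cfg.initial_state[0]), float(cfg.initial_state[1])
    dt = cfg.dt
    xs = [x]
    ys = [y]
    if cfg.sigma > 0.0:
        rng = np.random.default_rng(cfg.seed)
        amp = cfg.sigma * math.sqrt(dt)
        nx = rng.standard_normal(cfg.n_steps).tolist()
        ny = rng.standard_normal(cfg.n_steps).tolist()
        for i in range(cfg.n_steps):
            fx, fy = drift(x, y)
            x = x + fx * dt + amp * nx[i]
            y = y + fy * dt + amp * ny[i]
            if x < 0.0:
                x = 0.0
            if y < 0.0:
                y = 0.0
            if x > _DIVERGENCE_BOUND or y > _DIVERGENCE_BOUND:
                raise RuntimeError(
                    f"trajectory diverged at step {i} (state ({x:.3g}, {y:.3g})); "
                    "reduce dt or check parameters"
                )
            xs.append(x)
            ys.append(y)
    else:
        for i in range(cfg.n_steps):
            fx, fy = drift(x, y)
            x = x + fx * dt
            y = y + fy * dt
            if x < 0.0:
                x = 0.0
            if y < 0.0:
                y = 0.0
            if x > _DIVERGENCE_BOUND or y > _DIVERGENCE_BOUND:
                raise RuntimeError(
                    f"trajectory diverged at step {i} (state ({x:.3g}, {y:.3g})); "
                    "reduce dt or check parameters"
                )
            xs.append(x)
            ys.append(y)
    return np.column_stack([xs, ys])


def integrate_euler(
    p: GenericParams, initial: tuple[float, float], dt: float, n_steps: int
) -> np.ndarray:
    """Deterministic fixed-step Euler integration (the sigma = 0 limit)."""
    cfg = SDEConfig(sigma=0.0, dt=dt, n_steps=n_steps, initial_state=initial)
    return simulate(p, cfg)


def _post_burn_in(trajectory: np.ndarray, burn_in_fraction: float) -> np.ndarray:
    n = trajectory.shape[0]
    start = int(burn_in_fraction * n)
    samples = trajectory[start:]
    if samples.size == 0:
        raise ValueError("no samples remain after burn-in")
    return samples


def stationary_density(
    trajectory: np.ndarray,
    n_bins: int = 100,
    burn_in_fraction: float = 0.1,
    upper: float | None = None,
    smooth: bool = True,
) -> DensityGrid:
    """Normalized 2-D occupancy histogram of post-burn-in samples.

    The grid spans [0, upper]^2 where ``upper`` defaults to 1.2x the largest
    observed coordinate; occupancies are optionally smoothed with a Gaussian
    kernel of one bin width and renormalized to sum to 1.
    """
    samples = _post_burn_in(np.asarray(trajectory, dtype=float), burn_in_fraction)
    if upper is None:
        upper = 1.2 * max(float(samples.max()), 1e-6)
    edges = np.linspace(0.0, upper, n_bins + 1)
    hist, xe, ye = np.histogram2d(samples[:, 0], samples[:, 1], bins=[edges, edges])
    if smooth:
        hist = ndimage.gaussian_filter(hist, sigma=1.0, mode="constant")
    total = hist.sum()
    if total == 0:
        raise ValueError("all samples fell outside the grid")
    return DensityGrid(x_edges=xe, y_edges=ye, prob=hist / total)


def count_modes(
    grid: DensityGrid, rel_threshold: float = 0.1, min_separation: float = 0.5
) -> list[tuple[float, float, float]]:
    """Local maxima of the (smoothed) density — the noisy attractors.

    A bin is a mode candidate when it is >= all 8 neighbors and its height is
    at least ``rel_threshold`` times the global maximum; candidates closer
    than ``min_separation`` in state units are merged keeping the higher.
    Returns (x, y, height) triples sorted by descending height.
    """
    prob = grid.prob
    footprint_max = ndimage.maximum_filter(prob, size=3, mode="constant")
    peak_mask = (prob >= footprint_max) & (prob >= rel_threshold * prob.max()) & (prob > 0)
    xi, yi = np.nonzero(peak_mask)
    cands = sorted(
        (
            (float(grid.x_centers[i]), float(grid.y_centers[j]), float(prob[i, j]))
            for i, j in zip(xi, yi)
        ),
        key=lambda t: -t[2],
    )
    modes: list[tuple[float, float, float]] = []
    for cx, cy, h in cands:
        if all(math.hypot(cx - mx, cy - my) >= min_separation for mx, my, _ in modes):
            modes.append((cx, cy, h))
    return modes


def manifold_residence(
    trajectory: np.ndarray,
    p: GenericParams,
    dist_tol: float = 0.3,
    burn_in_fraction: float = 0.1,
    n_proj: int = 4001,
) -> float:
    """Fraction of post-burn-in samples within ``dist_tol`` of the b = c manifold.

    The distance of each sample to the manifold is obtained by projecting onto
    its x-parameterization: the manifold is discretized at ``n_proj`` points
    (spacing far below ``dist_tol``) and the nearest vertex distance is taken,
    which realizes the 1-D minimization to grid accuracy.
    """
    from scipy.spatial import cKDTree

    if not detect_degeneracy(p, tol=1e-9):
        raise ValueError("manifold residence requires degenerate parameters (b = c, a = f)")
    samples = _post_burn_in(np.asarray(trajectory, dtype=float), burn_in_fraction)
    xm = x_max(p)
    mx = np.linspace(0.0, xm, n_proj)
    my = np.array([manifold_y_of_x(float(v), p) for v in mx])
    tree = cKDTree(np.column_stack([mx, my]))
    dmin, _ = tree.query(samples, k=1)
    return float(np.mean(dmin <= dist_tol))


def attractor_landscape(
    p: GenericParams,
    cfg: SDEConfig,
    n_traj: int = 10,
    n_bins: int = 100,
    upper: float | None = None,
) -> tuple[DensityGrid, np.ndarray]:
    """Attractor landscape from an ensemble of trajectories (a cell population).

    The configured total step count is split across ``n_traj`` trajectories
    whose initial states are drawn uniformly over [0, 1.2*x_hi]^2 (x_hi the
    largest committed-state coordinate); post-burn-in samples are pooled and
    histogrammed.  At low noise, single trajectories never cross between
    committed basins, so pooling over a scattered ensemble is what samples
    the full landscape.  Returns (density grid with modes attached, pooled
    samples).  Reproducible for a given cfg.seed.
    """
    if n_traj <= 0:
        raise ValueError("n_traj must be positive")
    rng = np.random.default_rng(cfg.seed)
    x_hi = max((p.a / p.dx - 1.0) / p.bx, (p.f / p.dy - 1.0) / p.by)
    box = 1.2 * x_hi
    steps_per = max(1, cfg.n_steps // n_traj)
    pooled = []
    for k in range(n_traj):
        start = rng.uniform(0.0, box, size=2)
        sub = replace(
            cfg,
            n_steps=steps_per,
            seed=int(rng.integers(0, 2**31 - 1)),
            initial_state=(float(start[0]), float(start[1])),
        )
        traj = simulate(p, sub)
        pooled.append(_post_burn_in(traj, cfg.burn_in_fraction))
    samples = np.vstack(pooled)
    if upper is None:
        upper = 1.2 * max(float(samples.max()), 1e-6)
    grid = stationary_density(samples, n_bins=n_bins, burn_in_fraction=0.0, upper=upper)
    modes = count_modes(grid)
    return DensityGrid(grid.x_edges, grid.y_edges, grid.prob, tuple(modes)), samples
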