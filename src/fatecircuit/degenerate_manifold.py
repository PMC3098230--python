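"""The degenerate critical case b = c: a continuum of steady states.

When cross-repression exactly balances self-saturation (b = c, with symmetric
production a = f), the interior fixed-point equations collapse to the single
condition

    (1 + b*x)(1 + b*y) = a/d,

so every point of the curve y(x) = ((a/d)/(1+b*x) - 1)/b for x in
[0, x_max], x_max = (a-d)/(b*d), is a steady state.  The Jacobian on this
manifold is rank-deficient: one eigenvalue is exactly zero (no force along
the manifold) and the other,

    lambda(x) = -d*b*( x/(1+b*x) + y/(1+b*y) ),

is negative — the manifold attracts transversally but is indifferent
longitudinally.  lambda has an interior minimum at the diagonal point
x* = (sqrt(a/d) - 1)/b; under noise this is the most strongly attracting
neighborhood, the model's picture of the indeterminate progenitor state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .circuit_dynamics import GenericParams

__all__ = [
    "ManifoldPoint",
    "detect_degeneracy",
    "x_max",
    "manifold_y_of_x",
    "manifold_eigenvalues",
    "lambda_min",
    "sample_manifold",
]


@dataclass(frozen=True)
class ManifoldPoint:
    """A steady state on the b = c continuum with its linearization.

    ``mu`` is the degenerate (zero) eigenvalue; ``mu_raw`` retains the raw
    eigensolver value for diagnostics.  ``lam`` is the attracting transversal
    eigenvalue, <= 0 everywhere on the manifold.
    """

    x: float
    y: float
    lam: float
    mu: float
    mu_raw: float = 0.0


def detect_degeneracy(p: GenericParams, tol: float = 1e-9) -> bool:
    """True iff the parameters are on the degenerate locus b = c with a = f
    (relative tolerance ``tol``)."""
    return (
        abs(p.bx - p.cx) <= tol * max(p.bx, p.cx)
        and abs(p.by - p.cy) <= tol * max(p.by, p.cy)
        and abs(p.a - p.f) <= tol * max(p.a, p.f)
        and abs(p.dx - p.dy) <= tol * max(p.dx, p.dy)
    )


def _require_degenerate(p: GenericParams) -> None:
    if not detect_degeneracy(p, tol=1e-12):
        raise ValueError(
            "degenerate-manifold analysis requires b = c and a = f "
            f"(got b={p.b}, c={p.c}, a={p.a}, f={p.f})"
        )
    if not p.a > p.d:
        raise ValueError("positivity requires a > d")


def x_max(p: GenericParams) -> float:
    """Right endpoint of the manifold, (a - d)/(b*d) — the committed-state
    coordinate, reached where y = 0."""
    _require_degenerate(p)
    return (p.a - p.d) / (p.b * p.d)


def manifold_y_of_x(x: float, p: GenericParams) -> float:
    """The manifold curve: y solving (1 + b*x)(1 + b*y) = a/d.

    Defined for 0 <= x <= x_max; the endpoints satisfy y(0) = x_max and
    y(x_max) = 0 exactly.
    """
    _require_degenerate(p)
    xm = (p.a - p.d) / (p.b * p.d)
    if not (0.0 <= x <= xm * (1.0 + 1e-12)):
        raise ValueError(f"x={x} outside the manifold interval [0, {xm}]")
    return ((p.a / p.d) / (1.0 + p.b * x) - 1.0) / p.b


def manifold_eigenvalues(x: float, p: GenericParams) -> tuple[float, float]:
    """Jacobian eigenvalues (lambda, mu) at the manifold point over ``x``.

    mu = 0 exactly (the Jacobian is rank-deficient on the continuum);
    lambda = -d*b*(x/(1+b*x) + y/(1+b*y)) < 0 on the open interval.
    """
    y = manifold_y_of_x(x, p)
    lam = -p.d * p.b * (x / (1.0 + p.b * x) + y / (1.0 + p.b * y))
    return lam, 0.0


def lambda_min(p: GenericParams) -> tuple[float, float]:
    """Minimizer (x*, lambda*) of the transversal eigenvalue over the manifold.

    Located by bounded scalar minimization; for symmetric parameters the
    minimum lies on the diagonal at x* = (sqrt(a/d) - 1)/b, where the
    attraction onto the manifold is strongest.
    """
    xm = x_max(p)
    res = optimize.minimize_scalar(
        lambda x: manifold_eigenvalues(x, p)[0],
        bounds=(0.0, xm),
        method="bounded",
        options={"xatol": 1e-10},
    )
    x_star = float(res.x)
    # polish with the closed-form diagonal point when it is consistent
    x_diag = (math.sqrt(p.a / p.d) - 1.0) / p.b
    if 0.0 <= x_diag <= xm and manifold_eigenvalues(x_diag, p)[0] <= res.fun + 1e-12:
        x_star = x_diag
    return x_star, manifold_eigenvalues(x_star, p)[0]


def sample_manifold(p: GenericParams, n_points: int = 200) -> list[ManifoldPoint]:
    """Uniform-in-x sample of the manifold with eigenvalues at every point."""
    from .circuit_dynamics import jacobian

    xm = x_max(p)
    pts = []
    for x in np.linspace(0.0, xm, n_points):
        y = manifold_y_of_x(float(x), p)
        lam, mu = manifold_eigenvalues(float(x), p)
        eig = np.sort(np.real(np.linalg.eigvals(jacobian((float(x), y), p))))
        mu_raw = float(eig[1])  # the near-zero one; lam is eig[0] <= 0
        pts.append(ManifoldPoint(x=float(x), y=y, lam=lam, mu=mu, mu_raw=mu_raw))
    return pts


def manifold_frame(p: GenericParams, n_points: int = 200) -> pd.DataFrame:
    """The sampled manifold as a table with columns x, y, lambda, mu."""
    pts = sample_manifold(p, n_points)
    return pd.DataFrame(
        {
            "x": [q.x for q in pts],
            "y": [q.y for q in pts],
            "lambda": [q.lam for q in pts],
            "mu": [q.mu for q in pts],
        }
    )
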