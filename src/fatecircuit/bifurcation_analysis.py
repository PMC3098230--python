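"""Sweep of the bifurcation parameter q = c/b and location of the critical point.

Increasing the cross-repression-to-self-saturation ratio q carries the circuit
from a single stable indeterminate state (x = y, the progenitor) to two stable
committed states in which one gene dominates.  The exchange of stability
happens where the eigenvalue of the interior diagonal state transverse to the
diagonal,

    e_perp(q) = d*s*(c - b) / ((1 + b*s)(1 + c*s)),   c = q*b,

changes sign — exactly at q = 1 for a symmetric-production circuit.  The sweep
varies c at fixed b, which keeps the committed-state branches literally
constant across q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit_dynamics import (
    GenericParams,
    SteadyStateSet,
    check_positivity,
    steady_states,
)

__all__ = ["BifurcationDiagram", "sweep", "critical_q", "transversal_eigenvalue"]


@dataclass(frozen=True)
class BifurcationDiagram:
    """Steady-state branches over a grid of the bifurcation parameter."""

    q_grid: tuple[float, ...]
    branches: tuple[SteadyStateSet, ...]
    critical_q: float | None = None
    base_params: GenericParams | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (q, steady state)."""
        rows = []
        for q, sset in zip(self.q_grid, self.branches):
            for s in sset:
                rows.append(
                    {
                        "q": q,
                        "label": s.label,
                        "x": s.x,
                        "y": s.y,
                        "lambda": s.eigenvalues[0],
                        "mu": s.eigenvalues[1],
                        "stability": s.stability,
                    }
                )
        return pd.DataFrame(rows, columns=["q", "label", "x", "y", "lambda", "mu", "stability"])

    def n_stable(self) -> list[int]:
        return [len(s.stable) for s in self.branches]


def _match_branches(prev: SteadyStateSet, curr: SteadyStateSet) -> None:
    """Assert label continuity between adjacent grid points: each state's
    nearest neighbor at the previous q must carry the same label.  The
    interior branch and its degenerate point at q = 1 are one family."""
    interior = {"symmetric", "manifold_point"}

    def family(label: str) -> str:
        return "interior" if label in interior else label

    for s in curr:
        if not prev.states:
            return
        nearest = min(prev, key=lambda t: max(abs(t.x - s.x), abs(t.y - s.y)))
        if family(nearest.label) != family(s.label):
            raise RuntimeError(
                f"branch label swap between adjacent q points: {s.label} vs {nearest.label}"
            )


def sweep(p_base: GenericParams, q_values=None, refine_critical: bool = True) -> BifurcationDiagram:
    """Enumerate and classify steady states across a grid of q = c/b.

    For each q the cross-repression is set to c = q*b and all steady states
    are enumerated and classified.  Grid points where positivity fails are
    recorded with their ``lost_states`` flags; the sweep continues.  The
    default grid is 101 log-spaced values in [0.2, 5]; the critical point is
    refined by bisection, never read off the grid.
    """
    if q_values is None:
        q_values = np.logspace(np.log10(0.2), np.log10(5.0), 101)
    q_values = [float(q) for q in q_values]
    if any(q <= 0 for q in q_values) or sorted(q_values) != q_values:
        raise ValueError("q_values must be positive and sorted ascending")
    if not check_positivity(p_base):
        raise ValueError("base parameters violate positivity (need a > d and f > d)")

    branches = []
    prev = None
    for q in q_values:
        sset = steady_states(p_base.with_q(q))
        if prev is not None:
            _match_branches(prev, sset)
        branches.append(sset)
        prev = sset

    crit = critical_q(p_base) if (refine_critical and p_base.a == p_base.f) else None
    return BifurcationDiagram(
        q_grid=tuple(q_values),
        branches=tuple(branches),
        critical_q=crit,
        base_params=p_base,
    )


def transversal_eigenvalue(q: float, p_base: GenericParams) -> float:
    """Eigenvalue of the interior diagonal state along (1, -1), as a function
    of q at fixed b: d*s*(c-b)/((1+b*s)(1+c*s)) with (1+b*s)(1+c*s) = a/d."""
    p = p_base.with_q(q)
    sset = steady_states(p)
    try:
        s = sset.by_label("symmetric" if not sset.has_continuum else "manifold_point")
    except KeyError:
        raise RuntimeError(f"no interior diagonal state at q={q}")
    x = s.x
    return p.d * x * (p.c - p.b) / ((1.0 + p.b * x) * (1.0 + p.c * x))


def critical_q(
    p_base: GenericParams, tol: float = 1e-6, bracket: tuple[float, float] = (0.1, 10.0)
) -> float:
    """Locate the stability exchange of the diagonal state by bisection.

    Bisects the sign of the transversal eigenvalue over ``bracket`` until the
    bracket width is at most ``tol``; returns the bracket midpoint.  Requires
    symmetric production (a = f) so the diagonal ansatz applies.
    """
    if p_base.a != p_base.f:
        raise ValueError("critical_q requires symmetric production (a = f)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = bracket
    flo = transversal_eigenvalue(lo, p_base)
    fhi = transversal_eigenvalue(hi, p_base)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise RuntimeError(
            f"no sign change of the transversal eigenvalue in bracket {bracket}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = transversal_eigenvalue(mid, p_base)
        if fm == 0.0:
            return mid
        if np.sign(fm) == np.sign(flo):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)
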