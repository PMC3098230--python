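"""Generic planar dynamical system of the fate-decision circuit.

The coarse-grained circuit of two self-activating, mutually repressing genes is

    dx/dt = a*x / ((1 + b_x*x)(1 + c_x*y)) - d_x*x
    dy/dt = f*y / ((1 + b_y*y)(1 + c_y*x)) - d_y*y

with production scales ``a``, ``f``, self-saturation ``b``, cross-repression
``c`` and degradation ``d``.  The symmetric case (b_x = b_y, c_x = c_y,
d_x = d_y) is the standard analysis setting; its dimensionless bifurcation
parameter is q = c/b.  The asymmetric (gene-specific) coefficients are carried
everywhere; symmetry is a constrained view, not a separate code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GenericParams",
    "SteadyState",
    "SteadyStateSet",
    "rhs",
    "jacobian",
    "steady_states",
    "check_positivity",
    "classify",
]

#: coordinates closer than this (max norm) are considered the same fixed point
_DEDUP_TOL = 1e-8
#: residual level below which a point counts as a steady state
_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class GenericParams:
    """Parameters of the generic two-gene system.

    ``a``/``f`` are the production scales of gene 1 (x) and gene 2 (y),
    ``b`` the self-saturation coefficient, ``c`` the cross-repression
    coefficient and ``d`` the degradation rate, all strictly positive.
    Gene-2 overrides ``b_y``/``c_y``/``d_y`` may be given for an asymmetric
    circuit; when ``None`` they inherit ``b``/``c``/``d`` (symmetric system).
    The bifurcation parameter ``q = c/b`` is derived, never stored.
    """

    a: float = 1.0
    f: float = 1.0
    b: float = 0.5
    c: float = 0.5
    d: float = 0.5
    b_y: float | None = None
    c_y: float | None = None
    d_y: float | None = None

    def __post_init__(self) -> None:
        for name in ("a", "f", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {v!r}")
        for name in ("b_y", "c_y", "d_y"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {v!r}")

    # gene-specific views -------------------------------------------------
    @property
    def bx(self) -> float:
        return self.b

    @property
    def cx(self) -> float:
        return self.c

    @property
    def dx(self) -> float:
        return self.d

    @property
    def by(self) -> float:
        return self.b if self.b_y is None else self.b_y

    @property
    def cy(self) -> float:
        return self.c if self.c_y is None else self.c_y

    @property
    def dy(self) -> float:
        return self.d if self.d_y is None else self.d_y

    @property
    def q(self) -> float:
        """Bifurcation parameter c/b of gene 1."""
        return self.c / self.b

    @property
    def is_symmetric(self) -> bool:
        """True when both genes share coefficients and production scales."""
        return (
            self.a == self.f
            and self.bx == self.by
            and self.cx == self.cy
            and self.dx == self.dy
        )

    def with_q(self, q: float) -> "GenericParams":
        """Return a copy with the cross-repression set to ``c = q*b`` (both genes)."""
        if q <= 0:
            raise ValueError("q must be strictly positive")
        c_y = None if self.c_y is None else q * self.by
        return replace(self, c=q * self.b, c_y=c_y)


@dataclass(frozen=True)
class SteadyState:
    """A fixed point with its linearization.

    ``stability`` is one of ``stable``, ``saddle``, ``unstable``,
    ``degenerate`` (an eigenvalue within tolerance of zero); ``label`` names
    the branch: ``trivial`` (0,0), ``asym_x``/``asym_y`` (single-gene-high),
    ``symmetric`` (interior, x = y for a symmetric circuit) or
    ``manifold_point`` (on the b = c continuum).
    """

    coords: tuple[float, float]
    eigenvalues: tuple[float, float]
    stability: str
    label: str

    @property
    def x(self) -> float:
        return self.coords[0]

    @property
    def y(self) -> float:
        return self.coords[1]


@dataclass(frozen=True)
class SteadyStateSet(Sequence):
    """Isolated steady states, plus a flag for a degenerate interior continuum.

    Behaves as a sequence of :class:`SteadyState`.  When ``has_continuum`` is
    True (b = c, a = f) the interior fixed points form a one-dimensional
    manifold; the single listed interior state is its diagonal representative
    and :mod:`fatecircuit.degenerate_manifold` parameterizes the rest.
    """

    states: tuple[SteadyState, ...]
    has_continuum: bool = False
    lost_states: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]

    def __iter__(self) -> Iterator[SteadyState]:
        return iter(self.states)

    @property
    def stable(self) -> tuple[SteadyState, ...]:
        return tuple(s for s in self.states if s.stability == "stable")

    def by_label(self, label: str) -> SteadyState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)


def _check_state(x: float, y: float) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"concentrations must be nonnegative, got ({x}, {y})")


def rhs(state: tuple[float, float], p: GenericParams) -> tuple[float, float]:
    """Time derivatives (dx/dt, dy/dt) of the generic system."""
    x, y = state
    _check_state(x, y)
    fx = p.a * x / ((1.0 + p.bx * x) * (1.0 + p.cx * y)) - p.dx * x
    fy = p.f * y / ((1.0 + p.by * y) * (1.0 + p.cy * x)) - p.dy * y
    return fx, fy


def jacobian(state: tuple[float, float], p: GenericParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`rhs` at ``state``."""
    x, y = state
    _check_state(x, y)
    ux, vx = 1.0 + p.bx * x, 1.0 + p.cx * y
    uy, vy = 1.0 + p.by * y, 1.0 + p.cy * x
    j11 = p.a / (ux * ux * vx) - p.dx
    j12 = -p.a * p.cx * x / (ux * vx * vx)
    j21 = -p.f * p.cy * y / (uy * vy * vy)
    j22 = p.f / (uy * uy * vy) - p.dy
    return np.array([[j11, j12], [j21, j22]])


def check_positivity(p: GenericParams) -> bool:
    """True iff production exceeds degradation for both genes (a > d and f > d).

    This is the condition under which the nontrivial steady states have
    strictly positive coordinates, as concentrations require.
    """
    return p.a > p.dx and p.f > p.dy


def classify(
    coords: tuple[float, float], p: GenericParams, zero_tol: float | None = None
) -> SteadyState:
    """Classify a fixed point by the eigenvalues of the analytic Jacobian.

    ``zero_tol`` defaults to ``1e-9 * max(|lambda|, |mu|, d)`` — a scale-aware
    threshold needed to recognize the exactly-zero eigenvalue on the b = c
    manifold.  Raises if ``coords`` is not a steady state (residual > 1e-8).
    """
    fx, fy = rhs(coords, p)
    if max(abs(fx), abs(fy)) > _RESIDUAL_TOL:
        raise ValueError(
            f"point {coords} is not a steady state (residual {max(abs(fx), abs(fy)):.2e})"
        )
    eig = np.linalg.eigvals(jacobian(coords, p))
    re = np.sort(np.real(eig))[::-1]
    lam, mu = float(re[0]), float(re[1])
    if zero_tol is None:
        zero_tol = 1e-9 * max(abs(lam), abs(mu), p.d)
    if abs(lam) <= zero_tol or abs(mu) <= zero_tol:
        stability = "degenerate"
    elif lam < 0.0:
        stability = "stable"
    elif mu > 0.0:
        stability = "unstable"
    else:
        stability = "saddle"
    return SteadyState(
        coords=(float(coords[0]), float(coords[1])),
        eigenvalues=(lam, mu),
        stability=stability,
        label=_guess_label(coords, p),
    )


def _guess_label(coords: tuple[float, float], p: GenericParams) -> str:
    x, y = coords
    if x <= _DEDUP_TOL and y <= _DEDUP_TOL:
        return "trivial"
    if y <= _DEDUP_TOL:
        return "asym_x"
    if x <= _DEDUP_TOL:
        return "asym_y"
    if _is_degenerate(p):
        return "manifold_point"
    return "symmetric"


def _is_degenerate(p: GenericParams, tol: float = 1e-12) -> bool:
    return (
        abs(p.bx - p.cx) <= tol * max(p.bx, p.cx)
        and abs(p.by - p.cy) <= tol * max(p.by, p.cy)
        and abs(p.a - p.f) <= tol * max(p.a, p.f)
    )


def _polish(guess: tuple[float, float], p: GenericParams) -> tuple[float, float] | None:
    """Refine a fixed-point guess with a Newton-type root finder; snap tiny
    negative coordinates to zero (concentrations)."""

    def fun(z):
        x, y = max(z[0], 0.0), max(z[1], 0.0)
        return rhs((x, y), p)

    sol = optimize.root(fun, np.asarray(guess, dtype=float), method="hybr", tol=1e-12)
    x, y = sol.x
    if -_DEDUP_TOL < x < 0:
        x = 0.0
    if -_DEDUP_TOL < y < 0:
        y = 0.0
    if x < 0 or y < 0:
        return None
    if max(abs(v) for v in rhs((x, y), p)) > _RESIDUAL_TOL:
        return None
    return float(x), float(y)


def _interior_symmetric_root(p: GenericParams) -> float | None:
    """Positive root s of (1 + b*s)(1 + c*s) = a/d for the diagonal state."""
    bb, cc = p.bx, p.cx
    rho = p.a / p.dx - 1.0
    disc = (bb + cc) ** 2 + 4.0 * bb * cc * rho
    if disc < 0:
        return None
    s = (-(bb + cc) + math.sqrt(disc)) / (2.0 * bb * cc)
    return s if s > 0 else None


def steady_states(p: GenericParams, zero_tol: float | None = None) -> SteadyStateSet:
    """Enumerate and classify all steady states of the generic system.

    For a symmetric-production system (a = f) away from degeneracy the four
    states are returned in closed form and polished by root-finding: the
    trivial state (0,0), the two single-gene-high states ((a-d)/(b*d), 0) and
    (0, (f-d)/(b*d)), and the interior diagonal state (s, s) with
    (1+b*s)(1+c*s) = a/d.  For a != f the interior branch is located by
    multi-start 2-D root finding on a 5x5 grid.  At b = c with a = f the
    interior fixed points form a continuum: the set carries
    ``has_continuum=True`` and lists the diagonal representative as a
    ``manifold_point``.  Positivity violations are reported via
    ``lost_states`` rather than raised.
    """
    lost: list[str] = []
    candidates: list[tuple[tuple[float, float], str]] = [((0.0, 0.0), "trivial")]

    if p.a > p.dx:
        candidates.append((((p.a - p.dx) / (p.bx * p.dx), 0.0), "asym_x"))
    else:
        lost.append("asym_x")
    if p.f > p.dy:
        candidates.append(((0.0, (p.f - p.dy) / (p.by * p.dy)), "asym_y"))
    else:
        lost.append("asym_y")

    degenerate = _is_degenerate(p)
    interior_label = "manifold_point" if degenerate else "symmetric"
    interior: list[tuple[float, float]] = []
    if p.is_symmetric or (p.a == p.f and p.b_y is None and p.c_y is None and p.d_y is None):
        s = _interior_symmetric_root(p)
        if s is not None:
            interior.append((s, s))
        else:
            lost.append("symmetric")
    else:
        # a != f (or gene-specific coefficients): x = y no longer an ansatz;
        # multi-start search over the positivity box.
        xm = max((p.a / p.dx - 1.0) / p.bx, (p.f / p.dy - 1.0) / p.by, 1.0)
        grid = np.linspace(0.05 * xm, xm, 5)
        for gx in grid:
            for gy in grid:
                pol = _polish((gx, gy), p)
                if pol is None or pol[0] <= _DEDUP_TOL or pol[1] <= _DEDUP_TOL:
                    continue
                if all(
                    max(abs(pol[0] - q0[0]), abs(pol[1] - q0[1])) > _DEDUP_TOL
                    for q0 in interior
                ):
                    interior.append(pol)
        if not interior:
            lost.append("symmetric")
    candidates.extend((pt, interior_label) for pt in interior)

    states: list[SteadyState] = []
    for guess, label in candidates:
        pol = guess if label == "trivial" else _polish(guess, p)
        if pol is None:
            lost.append(label)
            continue
        if any(
            max(abs(pol[0] - s.x), abs(pol[1] - s.y)) <= _DEDUP_TOL for s in states
        ):
            continue
        ss = classify(pol, p, zero_tol=zero_tol)
        states.append(SteadyState(ss.coords, ss.eigenvalues, ss.stability, label))

    return SteadyStateSet(
        states=tuple(states), has_continuum=degenerate, lost_states=tuple(lost)
    )
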