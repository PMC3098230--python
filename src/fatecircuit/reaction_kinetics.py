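"""Elementary reaction schemes of the circuit and their rapid-equilibrium reduction.

Two chemistries produce the same coarse-grained dynamics:

* **Model 1** — self-activation and cross-repression act independently on each
  promoter: the activator X binds its own promoter with equilibrium constant
  K_x (production alpha_x from the bound complex), while the repressor Y binds
  the promoter — free or activator-occupied — with the same constant K_yx.
  Independent binding makes the promoter partition function factorize,
  (1 + K_x[X])(1 + K_yx[Y]), so the reduced rate is

      d[X]/dt = alpha_x*x_tot*K_x*[X] / ((1 + K_x[X])(1 + K_yx[Y])) - delta_x*[X]

  whose expanded denominator carries the cross term K_x*K_yx*[X][Y] — an
  effective heterodimer without any assumed protein-protein cooperativity.

* **Model 2** — the repressor binds the free promoter with K_yx but the
  activator-occupied complex with its own constant K_xxy, forming a ternary
  promoter-X-Y complex in situ.  The partition function is then
  1 + K_x[X] + K_yx[Y] + K_x*K_xxy*[X][Y]; it factorizes back to Model 1
  exactly when K_xxy = K_yx (no cooperativity between X and Y on the promoter).

Binding/release rate pairs are realized as (rate_scale*K, rate_scale) so each
equilibrium constant is exact and a single ``rate_scale`` controls the
timescale separation that justifies the reduction.  The full mass-action
network doubles as a brute-force oracle for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from .circuit_dynamics import GenericParams

__all__ = [
    "Model1Params",
    "Model2Params",
    "Model2Reduction",
    "FullNetworkParams",
    "SPECIES",
    "effective_activation_rate",
    "reduce_model1",
    "reduce_model2",
    "reduced_rate_model2",
    "full_network_rhs",
    "make_initial_state",
    "equilibrated_state",
    "integrate_full_network",
    "full_network_steady_state",
    "to_sbml",
]


def _require_positive(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ValueError(f"kinetic parameter {f.name!r} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class Model1Params:
    """Kinetic constants of the independent-binding scheme.

    alpha_*: production rate from the activator-bound promoter; delta_*:
    first-order protein degradation; K_x/K_y: self-binding equilibrium
    constants; K_yx/K_xy: cross-binding constants of the repressor to the
    opposite promoter; x_tot/y_tot: total promoter concentrations.  All
    strictly positive; each K is the ratio of a binding to a release rate.
    """

    alpha_x: float
    alpha_y: float
    delta_x: float
    delta_y: float
    K_x: float
    K_y: float
    K_yx: float
    K_xy: float
    x_tot: float
    y_tot: float

    def __post_init__(self) -> None:
        _require_positive(self)


@dataclass(frozen=True)
class Model2Params:
    """Model 1 constants plus ternary-complex cross-binding constants.

    K_xxy / K_yyx: equilibrium constants for the repressor binding the
    already activator-occupied promoter (Y to xX, X to yY).
    """

    alpha_x: float
    alpha_y: float
    delta_x: float
    delta_y: float
    K_x: float
    K_y: float
    K_yx: float
    K_xy: float
    x_tot: float
    y_tot: float
    K_xxy: float
    K_yyx: float

    def __post_init__(self) -> None:
        _require_positive(self)


def model1_as_model2(p: Model1Params) -> Model2Params:
    """Model 1's elementary realization: repressor affinity independent of
    activator occupancy, i.e. Model 2 with K_xxy = K_yx and K_yyx = K_xy."""
    return Model2Params(
        alpha_x=p.alpha_x, alpha_y=p.alpha_y, delta_x=p.delta_x, delta_y=p.delta_y,
        K_x=p.K_x, K_y=p.K_y, K_yx=p.K_yx, K_xy=p.K_xy,
        x_tot=p.x_tot, y_tot=p.y_tot, K_xxy=p.K_yx, K_yyx=p.K_xy,
    )


@dataclass(frozen=True)
class FullNetworkParams:
    """A kinetic parameter set plus the binding/release timescale.

    ``rate_scale`` multiplies every binding AND release rate, leaving all
    equilibrium constants fixed; large values enforce the rapid-equilibrium
    regime in which the reduced model becomes exact.
    """

    kinetics: Model1Params | Model2Params
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.rate_scale) and self.rate_scale > 0):
            raise ValueError("rate_scale must be strictly positive")

    @property
    def elementary(self) -> Model2Params:
        """The scheme in elementary (promoter-state) form."""
        if isinstance(self.kinetics, Model2Params):
            return self.kinetics
        return model1_as_model2(self.kinetics)


#: species order of the full-network state vector
SPECIES = ("x", "xX", "xY", "xXY", "y", "yY", "yX", "yYX", "X", "Y")
_IDX = {name: i for i, name in enumerate(SPECIES)}


def effective_activation_rate(K: float, alpha: float, conc: float) -> float:
    """Per-promoter production rate under self-activation alone.

    Eliminating the fast self-binding equilibrium gives the saturating
    rate alpha*K*conc / (1 + K*conc): zero without protein, half-maximal at
    conc = 1/K, bounded by alpha.
    """
    if K <= 0 or alpha <= 0:
        raise ValueError("K and alpha must be strictly positive")
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    return alpha * K * conc / (1.0 + K * conc)


def reduce_model1(p: Model1Params) -> GenericParams:
    """Map the independent-binding scheme onto the generic system.

    Rapid equilibrium of promoter binding plus promoter conservation yields
    d[X]/dt = a*[X]/((1+b*[X])(1+c*[Y])) - d*[X] with a = alpha_x*x_tot*K_x,
    b = K_x, c = K_yx, d = delta_x (mirrored for Y).
    """
    return GenericParams(
        a=p.alpha_x * p.x_tot * p.K_x,
        f=p.alpha_y * p.y_tot * p.K_y,
        b=p.K_x,
        c=p.K_yx,
        d=p.delta_x,
        b_y=p.K_y,
        c_y=p.K_xy,
        d_y=p.delta_y,
    )


class _DenomCoeffs(NamedTuple):
    const: float
    X: float
    Y: float
    XY: float


@dataclass(frozen=True)
class Model2Reduction:
    """Reduced form of the ternary-complex scheme.

    ``denom_x``/``denom_y`` are the promoter partition-function coefficients
    (1, [X], [Y], [X][Y] terms).  ``factorizes`` is True when both partition
    functions split as (1+K_self*[activator])(1+K_cross*[repressor]) — exactly
    the no-cooperativity condition K_xxy = K_yx and K_yyx = K_xy — in which
    case ``generic`` holds the same mapping as :func:`reduce_model1`.
    """

    denom_x: _DenomCoeffs
    denom_y: _DenomCoeffs
    factorizes: bool
    generic: GenericParams | None


def reduce_model2(p: Model2Params, rel_tol: float = 1e-12) -> Model2Reduction:
    """Reduce the ternary-complex scheme; report whether it factorizes.

    The reduced rate is
    d[X]/dt = alpha_x*x_tot*K_x*[X] / (1 + K_x[X] + K_yx[Y] + K_x*K_xxy[X][Y])
              - delta_x*[X].
    Factorization back to the Model 1 form requires K_xxy = K_yx (and the
    mirror) within ``rel_tol`` relative tolerance; near-misses are reported
    as non-factorizing, never silently factorized.
    """
    denom_x = _DenomCoeffs(1.0, p.K_x, p.K_yx, p.K_x * p.K_xxy)
    denom_y = _DenomCoeffs(1.0, p.K_y, p.K_xy, p.K_y * p.K_yyx)
    fac_x = abs(p.K_xxy - p.K_yx) <= rel_tol * max(p.K_xxy, p.K_yx)
    fac_y = abs(p.K_yyx - p.K_xy) <= rel_tol * max(p.K_yyx, p.K_xy)
    factorizes = fac_x and fac_y
    generic = None
    if factorizes:
        generic = GenericParams(
            a=p.alpha_x * p.x_tot * p.K_x,
            f=p.alpha_y * p.y_tot * p.K_y,
            b=p.K_x,
            c=p.K_yx,
            d=p.delta_x,
            b_y=p.K_y,
            c_y=p.K_xy,
            d_y=p.delta_y,
        )
    return Model2Reduction(denom_x, denom_y, factorizes, generic)


def reduced_rate_model2(p: Model2Params, X: float, Y: float) -> tuple[float, float]:
    """Evaluate the reduced Model 2 rates (d[X]/dt, d[Y]/dt) at (X, Y)."""
    if X < 0 or Y < 0:
        raise ValueError("concentrations must be nonnegative")
    zx = 1.0 + p.K_x * X + p.K_yx * Y + p.K_x * p.K_xxy * X * Y
    zy = 1.0 + p.K_y * Y + p.K_xy * X + p.K_y * p.K_yyx * X * Y
    dX = p.alpha_x * p.x_tot * p.K_x * X / zx - p.delta_x * X
    dY = p.alpha_y * p.y_tot * p.K_y * Y / zy - p.delta_y * Y
    return dX, dY


def symbolic_denominator(model: str, p: Model1Params | Model2Params):
    """Expanded promoter partition function of the X gene as a sympy Poly in
    symbols X, Y — used to inspect the [X][Y] cross term."""
    X, Y = sympy.symbols("X Y", nonnegative=True)
    if model == "model1":
        expr = sympy.expand((1 + p.K_x * X) * (1 + p.K_yx * Y))
    elif model == "model2":
        expr = 1 + p.K_x * X + p.K_yx * Y + p.K_x * p.K_xxy * X * Y
    else:
        raise ValueError("model must be 'model1' or 'model2'")
    return sympy.Poly(expr, X, Y)


# ---------------------------------------------------------------------------
# full mass-action network (brute-force oracle for the reduction)
# ---------------------------------------------------------------------------

def _check_nonnegative(state: np.ndarray) -> None:
    if np.any(np.asarray(state) < 0):
        raise ValueError("species concentrations must be nonnegative")


def full_network_rhs(state: np.ndarray, p: FullNetworkParams) -> np.ndarray:
    """Mass-action time derivatives of every elementary species.

    Reactions per X-locus (K_xxy = K_yx for a Model 1 parameter set):
    x + X <-> xX (K_x), x + Y <-> xY (K_yx), xX + Y <-> xXY (K_xxy),
    xX -> xX + X (alpha_x), X -> 0 (delta_x); mirrored for the y-locus.
    Each binding/release pair runs at (rate_scale*K, rate_scale).
    Promoter totals are conserved exactly: the promoter-species derivatives
    of each gene sum to zero.
    """
    _check_nonnegative(state)
    k = p.elementary
    r = p.rate_scale
    x, xX, xY, xXY, y, yY, yX, yYX, X, Y = state

    v1 = r * (k.K_x * x * X - xX)
    v2 = r * (k.K_yx * x * Y - xY)
    v3 = r * (k.K_xxy * xX * Y - xXY)
    w1 = r * (k.K_y * y * Y - yY)
    w2 = r * (k.K_xy * y * X - yX)
    w3 = r * (k.K_yyx * yY * X - yYX)

    return np.array([
        -v1 - v2,                                   # x
        v1 - v3,                                    # xX
        v2,                                         # xY
        v3,                                         # xXY
        -w1 - w2,                                   # y
        w1 - w3,                                    # yY
        w2,                                         # yX
        w3,                                         # yYX
        k.alpha_x * xX - k.delta_x * X - v1 - w2 - w3,   # X
        k.alpha_y * yY - k.delta_y * Y - v2 - v3 - w1,   # Y
    ])


def make_initial_state(
    p: FullNetworkParams, X: float = 0.0, Y: float = 0.0
) -> np.ndarray:
    """State with all promoter free and the given free-protein levels."""
    k = p.elementary
    s = np.zeros(len(SPECIES))
    s[_IDX["x"]] = k.x_tot
    s[_IDX["y"]] = k.y_tot
    s[_IDX["X"]] = X
    s[_IDX["Y"]] = Y
    return s


def equilibrated_state(p: FullNetworkParams, X: float, Y: float) -> np.ndarray:
    """State with promoter occupancies at their rapid-equilibrium values for
    fixed free-protein levels (X, Y)."""
    k = p.elementary
    zx = 1.0 + k.K_x * X + k.K_yx * Y + k.K_x * k.K_xxy * X * Y
    zy = 1.0 + k.K_y * Y + k.K_xy * X + k.K_y * k.K_yyx * X * Y
    s = np.zeros(len(SPECIES))
    s[_IDX["x"]] = k.x_tot / zx
    s[_IDX["xX"]] = k.x_tot * k.K_x * X / zx
    s[_IDX["xY"]] = k.x_tot * k.K_yx * Y / zx
    s[_IDX["xXY"]] = k.x_tot * k.K_x * k.K_xxy * X * Y / zx
    s[_IDX["y"]] = k.y_tot / zy
    s[_IDX["yY"]] = k.y_tot * k.K_y * Y / zy
    s[_IDX["yX"]] = k.y_tot * k.K_xy * X / zy
    s[_IDX["yYX"]] = k.y_tot * k.K_y * k.K_yyx * X * Y / zy
    s[_IDX["X"]] = X
    s[_IDX["Y"]] = Y
    return s


def integrate_full_network(
    p: FullNetworkParams,
    initial: np.ndarray,
    t_end: float,
    n_out: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the stiff mass-action network with an implicit/adaptive solver.

    Returns the scipy OdeResult (``.t`` shape (n_out,), ``.y`` shape
    (10, n_out)).  rate_scale up to 1e3 makes the system stiff; LSODA switches
    to BDF automatically.  Raises with solver diagnostics on failure.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    _check_nonnegative(initial)
    sol = solve_ivp(
        lambda t, s: full_network_rhs(np.maximum(s, 0.0), p),
        (0.0, t_end),
        np.asarray(initial, dtype=float),
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_out),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"full-network integration failed: {sol.message}")
    return sol


def full_network_steady_state(
    p: FullNetworkParams,
    initial: np.ndarray | None = None,
    t_end: float = 500.0,
    tol: float = 1e-10,
) -> np.ndarray:
    """Integrate to convergence and return the terminal state.

    Convergence is declared when the max |derivative| of the free proteins
    drops below ``tol``; otherwise integration continues in doublings of
    ``t_end`` (up to 8x) before raising.
    """
    state = make_initial_state(p, X=0.1, Y=0.1) if initial is None else initial
    t = t_end
    for _ in range(4):
        sol = integrate_full_network(p, state, t, n_out=2)
        state = np.maximum(sol.y[:, -1], 0.0)
        deriv = full_network_rhs(state, p)
        if max(abs(deriv[_IDX["X"]]), abs(deriv[_IDX["Y"]])) < tol:
            return state
        t *= 2.0
    raise RuntimeError("full network did not reach steady state within time budget")


# ---------------------------------------------------------------------------
# SBML export (writer only)
# ---------------------------------------------------------------------------

def to_sbml(p: FullNetworkParams, model_id: str = "fate_circuit") -> str:
    """Serialize the elementary network as an SBML Level 3 Version 2 document.

    A minimal writer: species, parameters, and mass-action reactions with
    MathML kinetic laws.  Export only; no SBML import is provided.
    """
    import xml.etree.ElementTree as ET

    k = p.elementary
    SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
    MATH_NS = "http://www.w3.org/1998/Math/MathML"
    ET.register_namespace("", SBML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", attrib={"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{SBML_NS}}}model", attrib={"id": model_id})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps, f"{{{SBML_NS}}}compartment",
        attrib={"id": "cell", "size": "1", "constant": "true"},
    )
    sp_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    init = {name: 0.0 for name in SPECIES}
    init["x"], init["y"] = k.x_tot, k.y_tot
    for name in SPECIES:
        ET.SubElement(
            sp_list, f"{{{SBML_NS}}}species",
            attrib={
                "id": name, "compartment": "cell",
                "initialConcentration": repr(init[name]),
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false", "constant": "false",
            },
        )
    par_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    params = {
        "kon_x": p.rate_scale * k.K_x, "koff": p.rate_scale,
        "kon_yx": p.rate_scale * k.K_yx, "kon_xxy": p.rate_scale * k.K_xxy,
        "kon_y": p.rate_scale * k.K_y, "kon_xy": p.rate_scale * k.K_xy,
        "kon_yyx": p.rate_scale * k.K_yyx,
        "alpha_x": k.alpha_x, "alpha_y": k.alpha_y,
        "delta_x": k.delta_x, "delta_y": k.delta_y,
    }
    for pid, val in params.items():
        ET.SubElement(
            par_list, f"{{{SBML_NS}}}parameter",
            attrib={"id": pid, "value": repr(val), "constant": "true"},
        )

    def mass_action_math(rate_const: str, species: list[str]) -> ET.Element:
        math = ET.Element(f"{{{MATH_NS}}}math")
        times = ET.SubElement(math, f"{{{MATH_NS}}}apply")
        ET.SubElement(times, f"{{{MATH_NS}}}times")
        for ci_name in [rate_const, *species]:
            ci = ET.SubElement(times, f"{{{MATH_NS}}}ci")
            ci.text = ci_name
        return math

    reactions = [
        ("bind_xX", ["x", "X"], ["xX"], "kon_x"),
        ("release_xX", ["xX"], ["x", "X"], "koff"),
        ("bind_xY", ["x", "Y"], ["xY"], "kon_yx"),
        ("release_xY", ["xY"], ["x", "Y"], "koff"),
        ("bind_xXY", ["xX", "Y"], ["xXY"], "kon_xxy"),
        ("release_xXY", ["xXY"], ["xX", "Y"], "koff"),
        ("produce_X", ["xX"], ["xX", "X"], "alpha_x"),
        ("degrade_X", ["X"], [], "delta_x"),
        ("bind_yY", ["y", "Y"], ["yY"], "kon_y"),
        ("release_yY", ["yY"], ["y", "Y"], "koff"),
        ("bind_yX", ["y", "X"], ["yX"], "kon_xy"),
        ("release_yX", ["yX"], ["y", "X"], "koff"),
        ("bind_yYX", ["yY", "X"], ["yYX"], "kon_yyx"),
        ("release_yYX", ["yYX"], ["yY", "X"], "koff"),
        ("produce_Y", ["yY"], ["yY", "Y"], "alpha_y"),
        ("degrade_Y", ["Y"], [], "delta_y"),
    ]
    rx_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rid, reactants, products, rate_const in reactions:
        rx = ET.SubElement(
            rx_list, f"{{{SBML_NS}}}reaction",
            attrib={"id": rid, "reversible": "false"},
        )
        if reactants:
            lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for s in reactants:
                ET.SubElement(
                    lor, f"{{{SBML_NS}}}speciesReference",
                    attrib={"species": s, "stoichiometry": "1", "constant": "true"},
                )
        if products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for s in products:
                ET.SubElement(
                    lop, f"{{{SBML_NS}}}speciesReference",
                    attrib={"species": s, "stoichiometry": "1", "constant": "true"},
                )
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        kl.append(mass_action_math(rate_const, reactants))

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
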