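"""Hill-function ODE models of motif circuits and their assemblies.

Every node X has a linear removal term and saturating regulation:

    dX/dt = beta_X * G_X(regulators) - alpha_X * X

where a positive regulator Y contributes an increasing Hill term
``Y^n / (k^n + Y^n)`` and a negative regulator a decreasing one
``k^n / (k^n + Y^n)``.  Multi-input nodes combine their regulators with
an AND gate (product of Hill terms) by default, or an OR gate
(``1 - prod(1 - h_i)``).  A node may instead be declared an external
input driven by a prescribed function of time (e.g. a step), in which
case it is not integrated.

Named fixture circuits cover the classic motif panels: positive
self-loop (SL), toggle switch (TMFL), Lock-ON (LMFL) and oscillator
(OMFL) mutual feedback pairs, coherent/incoherent type-1 feedforward
loops (C1FFL / I1FFL), their self-loop combinations, shared-edge
three-node loop pairs, double mutual feedback pairs, and mutually
interacting FFLs.  Fixture parameters are tuned to place each circuit in
its characteristic dynamical regime and are documented in the registry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

__all__ = [
    "hill",
    "SignedEdge",
    "CircuitModel",
    "Trajectory",
    "FixedPoint",
    "build_model",
    "named_circuit",
    "NAMED_CIRCUITS",
    "simulate",
    "find_fixed_points",
    "classify_dynamics",
    "synchronization_metrics",
    "parse_circuit_spec",
]

DEFAULT_K = 0.5
DEFAULT_N = 2.0
DEFAULT_BETA = 1.0
DEFAULT_ALPHA = 1.0


def hill(x: float, k: float, n: float, sign: str = "+") -> float:
    """Saturating regulatory response with half-effect ``k``, cooperativity
    ``n``: activation ``x^n/(k^n+x^n)`` or repression ``k^n/(k^n+x^n)``.

    The two branches are complementary: ``hill(x,k,n,'+') +
    hill(x,k,n,'-') == 1``.
    """
    if x < 0:
        raise ValueError("regulator level must be nonnegative")
    if k <= 0:
        raise ValueError("half-effect level k must be positive")
    if n < 1:
        raise ValueError("cooperativity n must be >= 1")
    xn = x**n
    kn = k**n
    act = xn / (kn + xn)
    return act if sign == "+" else 1.0 - act


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: str  # "+" or "-"
    k: float = DEFAULT_K
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError(f"edge sign must be '+' or '-', got {self.sign!r}")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def step_input(level: float, t_on: float = 0.0, basal: float = 0.0):
    """External input that steps from ``basal`` to ``level`` at ``t_on``."""

    def f(t: float) -> float:
        return level if t >= t_on else basal

    return f


@dataclass
class CircuitModel:
    """A signed, parameterized regulatory circuit compiled to an ODE.

    ``variables`` are the dynamical nodes (integrated); nodes in
    ``external_inputs`` are prescribed functions of time.
    """

    nodes: tuple[str, ...]
    edges: tuple[SignedEdge, ...]
    external_inputs: dict[str, Callable[[float], float]] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    gate: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = set(self.nodes)
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")
        for name in self.external_inputs:
            if name not in names:
                raise ValueError(f"external input {name!r} is not a declared node")
        for d in (self.beta, self.alpha):
            for name, val in d.items():
                if name not in names:
                    raise ValueError(f"parameter for unknown node {name!r}")
                if val <= 0:
                    raise ValueError(f"beta/alpha must be positive (node {name!r})")
        for name, g in self.gate.items():
            if g not in ("AND", "OR"):
                raise ValueError(f"gate must be AND or OR, got {g!r}")
        object.__setattr__(
            self,
            "variables",
            tuple(n for n in self.nodes if n not in self.external_inputs),
        )

    variables: tuple[str, ...] = field(init=False)

    def beta_of(self, node: str) -> float:
        return self.beta.get(node, DEFAULT_BETA)

    def alpha_of(self, node: str) -> float:
        return self.alpha.get(node, DEFAULT_ALPHA)

    def gate_of(self, node: str) -> str:
        return self.gate.get(node, "AND")

    def rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Compile the right-hand side dX/dt = beta*G(regulators) - alpha*X."""
        var_index = {v: i for i, v in enumerate(self.variables)}
        incoming: dict[str, list[SignedEdge]] = {v: [] for v in self.variables}
        for e in self.edges:
            if e.target in incoming:
                incoming[e.target].append(e)

        def f(t: float, y: np.ndarray) -> np.ndarray:
            levels = {}
            for v, i in var_index.items():
                levels[v] = max(float(y[i]), 0.0)
            for name, fn in self.external_inputs.items():
                levels[name] = max(float(fn(t)), 0.0)
            dy = np.empty(len(self.variables))
            for v, i in var_index.items():
                regs = incoming[v]
                if regs:
                    terms = [hill(levels[e.source], e.k, e.n, e.sign) for e in regs]
                    if self.gate_of(v) == "AND":
                        g = math.prod(terms)
                    else:
                        g = 1.0 - math.prod(1.0 - h for h in terms)
                else:
                    g = 0.0
                dy[i] = self.beta_of(v) * g - self.alpha_of(v) * float(y[i])
            return dy

        return f


def build_model(spec: Mapping) -> CircuitModel:
    """Build a CircuitModel from a plain mapping.

    Keys: ``nodes`` (list), ``edges`` (list of (source, target, sign) or
    (source, target, sign, k, n)), optional ``external`` (node ->
    constant level or (level, t_on) step), ``beta``/``alpha`` (node ->
    value), ``gate`` (node -> "AND"/"OR").
    """
    edges = []
    for item in spec.get("edges", []):
        if len(item) == 3:
            u, v, s = item
            edges.append(SignedEdge(u, v, s))
        elif len(item) == 5:
            u, v, s, k, n = item
            edges.append(SignedEdge(u, v, s, float(k), float(n)))
        else:
            raise ValueError(f"edge spec must have 3 or 5 fields: {item!r}")
    external: dict[str, Callable[[float], float]] = {}
    for name, val in spec.get("external", {}).items():
        if callable(val):
            external[name] = val
        elif isinstance(val, (tuple, list)):
            external[name] = step_input(float(val[0]), float(val[1]))
        else:
            external[name] = step_input(float(val))
    return CircuitModel(
        nodes=tuple(spec["nodes"]),
        edges=tuple(edges),
        external_inputs=external,
        beta={k: float(v) for k, v in spec.get("beta", {}).items()},
        alpha={k: float(v) for k, v in spec.get("alpha", {}).items()},
        gate=dict(spec.get("gate", {})),
    )


def parse_circuit_spec(text: str) -> CircuitModel:
    """Parse the plain-text circuit format.

    Line types (comments with ``#``)::

        nodes X Y Z
        edge X Y + [k n]
        external X <level> [t_on]
        param Y beta 2.0
        param Y alpha 1.0
        gate Z AND
    """
    spec: dict = {"nodes": [], "edges": [], "external": {}, "beta": {}, "alpha": {}, "gate": {}}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kind = tok[0].lower()
        try:
            if kind == "nodes":
                spec["nodes"].extend(tok[1:])
            elif kind == "edge":
                if len(tok) == 4:
                    spec["edges"].append((tok[1], tok[2], tok[3]))
                else:
                    spec["edges"].append(
                        (tok[1], tok[2], tok[3], float(tok[4]), float(tok[5]))
                    )
            elif kind == "external":
                t_on = float(tok[3]) if len(tok) > 3 else 0.0
                spec["external"][tok[1]] = (float(tok[2]), t_on)
            elif kind == "param":
                if tok[2] not in ("beta", "alpha"):
                    raise ValueError("param must set beta or alpha")
                spec[tok[2]][tok[1]] = float(tok[3])
            elif kind == "gate":
                spec["gate"][tok[1]] = tok[2].upper()
            else:
                raise ValueError(f"unknown directive {kind!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"circuit spec line {lineno}: {exc}") from exc
    return build_model(spec)


# ---------------------------------------------------------------------------
# named fixture circuits
#
# beta defaults to 1 but feedback fixtures use beta = 2: with k = 0.5 and
# n = 2 the symmetric mutual-feedback fixed point is exactly marginal at
# beta = 1, so beta = 2 places the switches safely in their bistable
# regime.  Oscillator assemblies use steeper Hill terms (n = 4) because a
# three-stage negative loop needs loop gain above the secant bound to
# sustain oscillations.


def _mutual(sign_xy: str, sign_yx: str, beta: float = 2.0) -> dict:
    return {
        "nodes": ["X", "Y"],
        "edges": [("X", "Y", sign_xy), ("Y", "X", sign_yx)],
        "beta": {"X": beta, "Y": beta},
    }


def _with_self_loops(spec: dict, nodes: Iterable[str], k: float = 0.3) -> dict:
    # self-loop half-effect 0.3 (not the default 0.5): at k = 0.5 the
    # self-activation gain exactly cancels linear removal at the interior
    # fixed point, leaving it marginal; a lower k keeps it hyperbolic
    out = {k2: (v.copy() if hasattr(v, "copy") else v) for k2, v in spec.items()}
    out["edges"] = list(spec["edges"]) + [(n, n, "+", k, DEFAULT_N) for n in nodes]
    return out


def _ffl(y_sign: str, beta: float = 2.0, x_level: float = 1.0) -> dict:
    return {
        "nodes": ["X", "Y", "Z"],
        "edges": [("X", "Y", "+"), ("X", "Z", "+"), ("Y", "Z", y_sign)],
        "external": {"X": x_level},
        "beta": {"Y": beta, "Z": beta},
        "gate": {"Z": "AND"},
    }


def _registry() -> dict[str, dict]:
    reg: dict[str, dict] = {}
    reg["SL"] = {"nodes": ["X"], "edges": [("X", "X", "+")], "beta": {"X": 2.0}}
    reg["TMFL"] = _mutual("-", "-")
    reg["LMFL"] = _mutual("+", "+")
    # oscillator pair: Y (activator) activates X (repressor), X represses
    # Y.  Cooperativity 4 (not the default 2) so the spiral's frequency
    # clearly exceeds its decay rate and the ring-down is visible.
    reg["OMFL"] = {
        "nodes": ["X", "Y"],
        "edges": [("Y", "X", "+", 0.5, 4.0), ("X", "Y", "-", 0.5, 4.0)],
        "beta": {"X": 2.0, "Y": 2.0},
    }
    reg["TMFL+SL"] = _with_self_loops(reg["TMFL"], ["X", "Y"])
    reg["LMFL+SL"] = _with_self_loops(reg["LMFL"], ["X", "Y"])
    reg["OMFL+SL"] = _with_self_loops(reg["OMFL"], ["X", "Y"])
    reg["C1FFL"] = _ffl("+")
    reg["I1FFL"] = _ffl("-")
    # self-loop on the FFL intermediate; the X->Z edge is sensitized
    # (k = 0.05) so that a weak input still drives the output once the
    # repressor has died away
    reg["C1FFL+SLY"] = {
        "nodes": ["X", "Y", "Z"],
        "edges": [
            ("X", "Y", "+"),
            ("Y", "Y", "+"),
            ("X", "Z", "+"),
            ("Y", "Z", "+"),
        ],
        "external": {"X": 0.5},
        "beta": {"Y": 4.0, "Z": 2.0},
        "gate": {"Y": "AND", "Z": "AND"},
    }
    reg["I1FFL+SLY"] = {
        "nodes": ["X", "Y", "Z"],
        "edges": [
            ("X", "Y", "+"),
            ("Y", "Y", "+"),
            ("X", "Z", "+", 0.05, 2.0),
            ("Y", "Z", "-"),
        ],
        "external": {"X": 0.5},
        "beta": {"Y": 4.0, "Z": 2.0},
        "gate": {"Y": "AND", "Z": "AND"},
    }
    # two three-node loops sharing the X->Y edge (electronic-circuit
    # pattern): loop {X,Y,Z} carries the single negative edge and
    # oscillates; loop {X,Y,W} is all-positive.  The W->X half-effect is
    # high (k = 4) so the all-positive loop reads the oscillation without
    # flooding X's production and quenching the negative loop; X combines
    # its two activators with an OR gate.
    reg["3LOOP-PAIR"] = {
        "nodes": ["X", "Y", "Z", "W"],
        "edges": [
            ("X", "Y", "+", 0.5, 4.0),
            ("Y", "Z", "-", 0.5, 4.0),
            ("Z", "X", "+", 0.5, 4.0),
            ("Y", "W", "+", 0.5, 4.0),
            ("W", "X", "+", 4.0, 4.0),
        ],
        "beta": {"X": 2.0, "Y": 2.0, "Z": 2.0, "W": 2.0},
        "gate": {"X": "OR"},
    }
    reg["3LOOP-NEG"] = {  # the oscillating loop alone
        "nodes": ["X", "Y", "Z"],
        "edges": [
            ("X", "Y", "+", 0.5, 4.0),
            ("Y", "Z", "-", 0.5, 4.0),
            ("Z", "X", "+", 0.5, 4.0),
        ],
        "beta": {"X": 2.0, "Y": 2.0, "Z": 2.0},
    }
    reg["3LOOP-POS"] = {  # the all-positive loop alone
        "nodes": ["X", "Y", "W"],
        "edges": [
            ("X", "Y", "+", 0.5, 4.0),
            ("Y", "W", "+", 0.5, 4.0),
            ("W", "X", "+", 0.5, 4.0),
        ],
        "beta": {"X": 2.0, "Y": 2.0, "W": 2.0},
    }
    # double mutual feedback (neuronal pattern): X<->Y, Y<->Z mutual,
    # X represses Z; two copies share the X -| Z edge.  At these
    # parameters the single circuit only rings down (damped), while the
    # pair sustains oscillations that Y and W share in phase: with X
    # combining its activators by OR, the second motif's W adds exactly
    # the drive the single circuit lacks.
    _dmf_edges = [
        ("X", "Y", "+", 0.32, 4.0),
        ("Y", "X", "+", 0.86, 4.0),
        ("Y", "Z", "+", 0.25, 4.0),
        ("Z", "Y", "+", 0.93, 4.0),
        ("X", "Z", "-", 0.93, 4.0),
    ]
    reg["DMF-NEG"] = {
        "nodes": ["X", "Y", "Z"],
        "edges": list(_dmf_edges),
        "beta": {"X": 2.5, "Y": 3.4, "Z": 4.7},
        "alpha": {"X": 1.0, "Y": 0.2, "Z": 0.5},
        "gate": {"X": "OR", "Y": "AND", "Z": "AND"},
    }
    reg["DMF-PAIR"] = {
        "nodes": ["X", "Y", "Z", "W"],
        "edges": list(_dmf_edges)
        + [
            ("X", "W", "+", 0.32, 4.0),
            ("W", "X", "+", 0.86, 4.0),
            ("W", "Z", "+", 0.25, 4.0),
            ("Z", "W", "+", 0.93, 4.0),
        ],
        "beta": {"X": 2.5, "Y": 3.4, "Z": 4.7, "W": 3.4},
        "alpha": {"X": 1.0, "Y": 0.2, "Z": 0.5, "W": 0.2},
        "gate": {"X": "OR", "Y": "AND", "Z": "AND", "W": "AND"},
    }
    # mutually interacting FFLs: the coherent FFL's output C activates
    # the incoherent FFL's input D, whose output F represses A.  The
    # heterogeneous k/beta/alpha values place the long negative loop
    # A->C->D->F-|A in its oscillatory regime (no single FFL can
    # oscillate: each alone has a triangular Jacobian).
    reg["FFL-PAIR"] = {
        "nodes": ["A", "B", "C", "D", "E", "F"],
        "edges": [
            ("A", "B", "+", 0.41, 4.0),
            ("A", "C", "+", 0.36, 4.0),
            ("B", "C", "+", 0.33, 4.0),
            ("D", "E", "+", 0.74, 4.0),
            ("D", "F", "+", 0.47, 4.0),
            ("E", "F", "-", 0.67, 4.0),
            ("C", "D", "+", 0.57, 4.0),
            ("F", "A", "-", 0.43, 4.0),
        ],
        "beta": {"A": 4.69, "B": 4.94, "C": 2.59, "D": 3.23, "E": 1.84, "F": 5.93},
        "alpha": {"A": 2.0, "B": 1.0, "C": 2.0, "D": 1.0, "E": 1.0, "F": 1.0},
        "gate": {"C": "AND", "F": "AND"},
    }
    # each FFL of the pair alone, same parameters, input frozen at 1
    reg["FFL-PAIR-C1"] = {
        "nodes": ["A", "B", "C"],
        "edges": [
            ("A", "B", "+", 0.41, 4.0),
            ("A", "C", "+", 0.36, 4.0),
            ("B", "C", "+", 0.33, 4.0),
        ],
        "external": {"A": 1.0},
        "beta": {"B": 4.94, "C": 2.59},
        "alpha": {"B": 1.0, "C": 2.0},
        "gate": {"C": "AND"},
    }
    reg["FFL-PAIR-I1"] = {
        "nodes": ["D", "E", "F"],
        "edges": [
            ("D", "E", "+", 0.74, 4.0),
            ("D", "F", "+", 0.47, 4.0),
            ("E", "F", "-", 0.67, 4.0),
        ],
        "external": {"D": 1.0},
        "beta": {"E": 1.84, "F": 5.93},
        "alpha": {"E": 1.0, "F": 1.0},
        "gate": {"F": "AND"},
    }
    return reg


NAMED_CIRCUITS: dict[str, dict] = _registry()


def named_circuit(name: str, **overrides) -> CircuitModel:
    """Instantiate a named fixture circuit, optionally overriding spec keys
    (``external``, ``beta``, ``alpha``, ``gate``)."""
    try:
        spec = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in NAMED_CIRCUITS[name].items()}
    except KeyError:
        raise KeyError(f"unknown circuit {name!r}; known: {sorted(NAMED_CIRCUITS)}") from None
    for key, val in overrides.items():
        if key in ("beta", "alpha", "gate", "external"):
            merged = dict(spec.get(key, {}))
            merged.update(val)
            spec[key] = merged
        else:
            spec[key] = val
    return build_model(spec)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # variables x time
    variables: tuple[str, ...]
    solver: str = "LSODA"

    def series(self, variable: str) -> np.ndarray:
        return self.y[self.variables.index(variable)]


def simulate(
    model: CircuitModel,
    x0: Mapping[str, float] | Sequence[float],
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 2000,
) -> Trajectory:
    """Integrate the circuit from a nonnegative initial state.

    Uses LSODA (stiff-capable).  States are clipped at zero if the solver
    undershoots; an undershoot beyond ``100 * atol`` raises a warning.
    """
    if isinstance(x0, Mapping):
        y0 = np.array([float(x0.get(v, 0.0)) for v in model.variables])
    else:
        y0 = np.asarray(x0, dtype=float)
        if y0.shape != (len(model.variables),):
            raise ValueError(
                f"initial state must have {len(model.variables)} entries "
                f"for variables {model.variables}"
            )
    if (y0 < 0).any():
        raise ValueError("initial state must be nonnegative")
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        model.rhs(),
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = sol.y
    if (y < -100 * atol).any():
        warnings.warn("solver undershoot below zero beyond tolerance; clipping")
    return Trajectory(t=sol.t, y=np.clip(y, 0.0, None), variables=model.variables)


# ---------------------------------------------------------------------------
# fixed points and stability


@dataclass
class FixedPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # stable-node | stable-spiral | saddle | unstable | marginal

    @property
    def stable(self) -> bool:
        return self.classification in ("stable-node", "stable-spiral")


def _numeric_jacobian(f, y: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    d = len(y)
    jac = np.empty((d, d))
    for j in range(d):
        dy = np.zeros(d)
        dy[j] = eps
        hi = f(0.0, y + dy)
        lo = f(0.0, np.clip(y - dy, 0.0, None))
        denom = (y + dy)[j] - max(y[j] - eps, 0.0)
        jac[:, j] = (hi - lo) / denom
    return jac


def classify_eigenvalues(eigenvalues: np.ndarray, tol: float = 1e-7) -> str:
    re = eigenvalues.real
    im = eigenvalues.imag
    if np.any(np.abs(re) < tol):
        return "marginal"
    if np.all(re < 0):
        return "stable-spiral" if np.any(np.abs(im) > tol) else "stable-node"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points(
    model: CircuitModel,
    grid: Sequence[float] | None = None,
    freeze_time: float = 1e9,
    rhs_tol: float = 1e-9,
    dedup_tol: float = 1e-6,
) -> list[FixedPoint]:
    """Locate fixed points by multi-start root solving on a grid.

    External inputs are frozen at their level at ``freeze_time``.  Roots
    with any negative component are discarded (levels are
    concentrations); duplicates within ``dedup_tol`` are merged, and each
    root carries its Jacobian eigenvalues and stability classification.
    """
    f0 = model.rhs()

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return f0(freeze_time, y)

    d = len(model.variables)
    if grid is None:
        scale = max(
            model.beta_of(v) / model.alpha_of(v) for v in model.variables
        )
        grid = [0.0, 0.05 * scale, 0.25 * scale, 0.5 * scale, scale]
    starts = np.array(np.meshgrid(*([list(grid)] * d))).reshape(d, -1).T
    found: list[FixedPoint] = []
    for start in starts:
        sol = root(lambda y: f(0.0, y), start, method="hybr", tol=1e-12)
        y = sol.x
        if not sol.success or np.any(y < -dedup_tol):
            continue
        y = np.clip(y, 0.0, None)
        if np.linalg.norm(f(0.0, y)) > rhs_tol:
            continue
        if any(np.linalg.norm(y - fp.state) < dedup_tol for fp in found):
            continue
        jac = _numeric_jacobian(f, y)
        eig = np.linalg.eigvals(jac)
        found.append(
            FixedPoint(state=y, eigenvalues=eig, classification=classify_eigenvalues(eig))
        )
    if not found:
        warnings.warn("no fixed points converged from any start")
    found.sort(key=lambda fp: tuple(fp.state))
    return found


# ---------------------------------------------------------------------------
# trajectory classification


def classify_dynamics(
    traj: Trajectory,
    variable: str,
    transient_fraction: float = 0.3,
    sustained_ratio: float = 0.9,
    min_relative_amplitude: float = 0.01,
) -> str:
    """Label a variable's time course.

    Returns one of ``monotone-converge``, ``pulse``,
    ``damped-oscillation``, ``sustained-oscillation`` or
    ``inconclusive``.  A pulse is a single interior maximum whose final
    level falls below half the peak.  Oscillation calls ignore the first
    30% of the trajectory as transient; sustained vs damped is decided by
    the trend of successive peak-to-trough amplitudes.
    """
    x = traj.series(variable)
    t = traj.t
    if len(t) < 10:
        return "inconclusive"
    rng = float(x.max() - x.min())
    if rng < 1e-12:
        return "monotone-converge"
    prominence = max(0.02 * rng, 1e-9)
    peaks, _ = find_peaks(x, prominence=prominence)
    troughs, _ = find_peaks(-x, prominence=prominence)
    i0 = int(np.searchsorted(t, transient_fraction * t[-1]))
    post_peaks = peaks[peaks >= i0]
    post_troughs = troughs[troughs >= i0]
    scale = max(abs(float(x[i0:].mean())), rng)
    if len(post_peaks) >= 2 and len(post_troughs) >= 1:
        # peak-to-trough amplitudes over the post-transient window
        amps = []
        for p in post_peaks:
            later_troughs = post_troughs[post_troughs > p]
            if later_troughs.size:
                amps.append(float(x[p] - x[later_troughs[0]]))
        if len(amps) >= 2 and amps[0] > min_relative_amplitude * scale:
            ratio = amps[-1] / amps[0]
            return (
                "sustained-oscillation"
                if ratio >= sustained_ratio
                else "damped-oscillation"
            )
        if len(amps) >= 1:
            return "damped-oscillation"
    if len(peaks) >= 2:
        return "damped-oscillation"
    if len(peaks) == 1:
        if x[-1] < 0.5 * x[peaks[0]]:
            return "pulse"
        return "monotone-converge"
    return "monotone-converge"


def synchronization_metrics(
    traj: Trajectory,
    var_a: str,
    var_b: str,
    transient_fraction: float = 0.3,
) -> tuple[str, float | None]:
    """Phase relation between two oscillating variables.

    Returns ``(relation, lag)`` where relation is ``in-phase``
    (|lag|/T < 0.1), ``anti-phase`` (|lag/T - 0.5| < 0.1 up to sign) or
    ``none`` (either variable not oscillatory, or intermediate phase).
    The lag is the cross-correlation peak offset of variable b relative
    to variable a, in time units.
    """
    for v in (var_a, var_b):
        if classify_dynamics(traj, v, transient_fraction) not in (
            "sustained-oscillation",
            "damped-oscillation",
        ):
            return "none", None
    t = traj.t
    i0 = int(np.searchsorted(t, transient_fraction * t[-1]))
    a = traj.series(var_a)[i0:]
    b = traj.series(var_b)[i0:]
    dt = float(np.median(np.diff(t[i0:])))
    # period from peak spacing of variable a
    prom = 0.02 * float(a.max() - a.min())
    peaks, _ = find_peaks(a, prominence=max(prom, 1e-12))
    if len(peaks) < 2:
        return "none", None
    period = float(np.median(np.diff(peaks))) * dt
    a0 = a - a.mean()
    b0 = b - b.mean()
    corr = np.correlate(b0, a0, mode="full")
    lags = (np.arange(corr.size) - (len(a0) - 1)) * dt
    window = np.abs(lags) <= period * 0.75
    best = int(np.argmax(corr[window]))
    lag = float(lags[window][best])
    phase = abs(lag) / period
    if phase < 0.1 or phase > 0.9:
        return "in-phase", lag
    if abs(phase - 0.5) < 0.1:
        return "anti-phase", lag
    return "none", lag
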