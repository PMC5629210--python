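"""Bistable junctional RhoA-myosin signaling network with SRGAP1 forcing.

The zonula adherens maintains a zone of active RhoA through a
mechanochemical feedback network: RhoA activates ROCK1, ROCK1 drives
non-muscle myosin IIA (NMIIA) accumulation, and cortically anchored NMIIA
in turn stabilizes junctional ROCK1. Anchored ROCK1 suppresses Rnd3,
which would otherwise recruit the RhoA antagonist p190B RhoGAP. The
double-negative loop (ROCK1 -| Rnd3 -> p190B -| RhoA) combined with the
ROCK1/NMIIA positive loop makes the network bistable: a state with RhoA
stably active (Rnd3/p190B suppressed) coexists with a relatively
inactive state (Rnd3/p190B high). SRGAP1 is a second RhoA GAP that sits
orthogonal to this feedback: it represses RhoA directly but is not
itself regulated by the network, so it is modeled as an exogenous,
externally forced concentration.

Species amounts are dimensionless junctional abundances; proteins
localized at the junctional cortex are treated as active. Each node
follows

    dX_i/dt = basal_i + sum_stim w*h(X_j) - X_i * (removal_i + sum_rep w*h(X_j))

with saturating Hill interactions h(x) = x^n / (K^n + x^n): stimulators
add to production, repressors add to first-order removal. SRGAP1 obeys
its forcing schedule exactly (constant until ``t_ramp``, then rising
linearly at ``slope`` per time unit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .errors import IntegrationFailure, ValidationError

STIMULATION = "stimulation"
REPRESSION = "repression"

DEFAULT_NODES = ("RhoA", "ROCK1", "NMIIA", "Rnd3", "p190B", "SRGAP1")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # STIMULATION or REPRESSION

    def __post_init__(self):
        if self.sign not in (STIMULATION, REPRESSION):
            raise ValidationError(f"edge sign must be stimulation/repression, got {self.sign!r}")


@dataclass(frozen=True)
class NetworkTopology:
    """Ordered node set and signed interaction edges."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node names")
        seen = set()
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValidationError(f"edge {e.source}->{e.target} references undeclared node")
            key = (e.source, e.target)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)

    def in_edges(self, node: str) -> list[Edge]:
        return [e for e in self.edges if e.target == node]


@dataclass(frozen=True)
class EdgeParams:
    """Saturating-interaction parameters of one edge."""

    weight: float       # maximal interaction strength (dimensionless)
    threshold: float    # Hill half-saturation constant K
    hill: float         # Hill coefficient n

    def __post_init__(self):
        if not (self.weight > 0 and self.threshold > 0 and self.hill > 0):
            raise ValidationError("edge weight, threshold and Hill coefficient must be > 0")


@dataclass(frozen=True)
class RampSchedule:
    """SRGAP1 forcing: constant until ``t_start``, then linear increase."""

    t_start: float = 200.0
    slope: float = 0.0075  # concentration per model time unit

    def __post_init__(self):
        if self.t_start < 0:
            raise ValidationError("ramp start time must be >= 0")

    def level(self, t, initial: float = 0.0):
        """Forced SRGAP1 level at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        return initial + self.slope * np.clip(t - self.t_start, 0.0, None)


@dataclass(frozen=True)
class NetworkParameters:
    basal: Mapping[str, float]
    removal: Mapping[str, float]
    edge_params: Mapping[tuple[str, str], EdgeParams]
    forcing: RampSchedule = field(default_factory=RampSchedule)
    exogenous: str = "SRGAP1"

    def validate_against(self, topology: NetworkTopology) -> None:
        dynamic = [n for n in topology.nodes if n != self.exogenous]
        for n in dynamic:
            if n not in self.basal or n not in self.removal:
                raise ValidationError(f"node {n!r} lacks basal/removal parameters")
            if self.basal[n] < 0:
                raise ValidationError(f"basal rate of {n!r} must be >= 0")
            if self.removal[n] <= 0:
                raise ValidationError(f"removal rate of {n!r} must be > 0")
        for e in topology.edges:
            if (e.source, e.target) not in self.edge_params:
                raise ValidationError(f"edge {e.source}->{e.target} lacks parameters")


@dataclass
class Trajectory:
    """Time courses of all nodes plus the applied SRGAP1 forcing."""

    times: np.ndarray                    # strictly increasing
    values: pd.DataFrame                 # one column per node, one row per time
    forcing: RampSchedule | None = None
    srgap1_initial: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("trajectory time grid must be strictly increasing")
        if len(self.values) != len(self.times):
            raise ValidationError("one concentration row per time point required")

    def __getitem__(self, node: str) -> np.ndarray:
        return self.values[node].to_numpy()

    def final_state(self) -> dict[str, float]:
        return self.values.iloc[-1].to_dict()

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, node, value) table."""
        df = self.values.copy()
        df.insert(0, "time", self.times)
        return df.melt(id_vars="time", var_name="node", value_name="value")


@dataclass
class FixedPoint:
    state: dict[str, float]
    rhs_norm: float
    eigenvalues: np.ndarray
    stable: bool
    n_basin_hits: int = 1


@dataclass
class RegimeReport:
    """Classification of a ramp trajectory into the two response regimes."""

    labels: np.ndarray            # per time point: "active-tuned" / "switched-inactive"
    switch_time: float | None
    switch_srgap1: float | None   # SRGAP1 level at the switch, if any
    active_ref: float
    inactive_ref: float

    def __post_init__(self):
        if not self.active_ref > self.inactive_ref:
            raise ValidationError("active reference level must exceed inactive reference")
        if self.switch_srgap1 is not None and not self.switch_srgap1 > 0:
            raise ValidationError("switch SRGAP1 level must be > 0 when present")


ACTIVE_TUNED = "active-tuned"
SWITCHED_INACTIVE = "switched-inactive"


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

def build_default_model() -> tuple[NetworkTopology, NetworkParameters]:
    """Six-node default network with a bistable SRGAP1-free core.

    The default parameter set is pinned; under it the SRGAP1-free
    subnetwork has exactly two stable fixed points (RhoA-active and
    RhoA-inactive), the all-ones initial condition lies in the active
    basin, and a slow SRGAP1 ramp first tunes RhoA down within the
    active state and then switches the network to the inactive state.
    """
    topology = NetworkTopology(
        nodes=DEFAULT_NODES,
        edges=(
            Edge("RhoA", "ROCK1", STIMULATION),
            Edge("ROCK1", "NMIIA", STIMULATION),
            Edge("NMIIA", "ROCK1", STIMULATION),   # cortical anchoring feedback
            Edge("ROCK1", "Rnd3", REPRESSION),
            Edge("Rnd3", "p190B", STIMULATION),
            Edge("p190B", "RhoA", REPRESSION),
            Edge("SRGAP1", "RhoA", REPRESSION),    # orthogonal antagonist
        ),
    )
    parameters = NetworkParameters(
        basal={"RhoA": 1.0, "ROCK1": 0.02, "NMIIA": 0.02, "Rnd3": 1.0, "p190B": 0.05},
        removal={"RhoA": 1.0, "ROCK1": 1.0, "NMIIA": 1.0, "Rnd3": 1.0, "p190B": 1.0},
        edge_params={
            ("RhoA", "ROCK1"): EdgeParams(1.0, 0.5, 4),
            ("ROCK1", "NMIIA"): EdgeParams(1.0, 0.7, 4),
            ("NMIIA", "ROCK1"): EdgeParams(1.0, 0.7, 4),
            ("ROCK1", "Rnd3"): EdgeParams(9.0, 0.7, 4),
            ("Rnd3", "p190B"): EdgeParams(2.0, 0.5, 4),
            ("p190B", "RhoA"): EdgeParams(5.0, 0.5, 4),
            ("SRGAP1", "RhoA"): EdgeParams(3.0, 1.5, 2),
        },
        forcing=RampSchedule(t_start=200.0, slope=0.0075),
    )
    parameters.validate_against(topology)
    return topology, parameters


def default_initial_state() -> dict[str, float]:
    """All junctional concentrations one, SRGAP1 zero."""
    return {n: (0.0 if n == "SRGAP1" else 1.0) for n in DEFAULT_NODES}


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _hill(x: np.ndarray, K: float, n: float) -> np.ndarray:
    x = np.maximum(x, 0.0)
    xn = x ** n
    return xn / (K ** n + xn)


def make_rhs(topology, parameters, srgap1_of_t):
    """Vector field over the dynamic (non-exogenous) nodes.

    ``srgap1_of_t`` maps model time to the forced SRGAP1 level.
    """
    parameters.validate_against(topology)
    exo = parameters.exogenous
    dynamic = [n for n in topology.nodes if n != exo]
    idx = {n: i for i, n in enumerate(dynamic)}
    basal = np.array([parameters.basal[n] for n in dynamic])
    removal = np.array([parameters.removal[n] for n in dynamic])
    stim, rep = [], []  # (target_idx, source_name, w, K, n)
    for e in topology.edges:
        if e.target == exo:
            continue
        p = parameters.edge_params[(e.source, e.target)]
        entry = (idx[e.target], e.source, p.weight, p.threshold, p.hill)
        (stim if e.sign == STIMULATION else rep).append(entry)

    def rhs(t, y):
        level = {n: y[i] for n, i in idx.items()}
        level[exo] = srgap1_of_t(t)
        prod = basal.copy()
        rem = removal.copy()
        for j, src, w, K, n in stim:
            prod[j] += w * _hill(level[src], K, n)
        for j, src, w, K, n in rep:
            rem[j] += w * _hill(level[src], K, n)
        return prod - y * rem

    return rhs, dynamic


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    topology: NetworkTopology,
    parameters: NetworkParameters,
    initial_state: Mapping[str, float],
    t_end: float,
    output_grid: Sequence[float] | None = None,
    *,
    apply_forcing: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Deterministically integrate the network from ``initial_state``.

    SRGAP1 follows its forcing schedule exactly (it is substituted as an
    explicit function of time, not integrated). With
    ``apply_forcing=False`` SRGAP1 stays frozen at its initial value.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    missing = [n for n in topology.nodes if n not in initial_state]
    if missing:
        raise ValidationError(f"initial_state missing node(s): {missing}")
    exo = parameters.exogenous
    s0 = float(initial_state[exo])
    sched = parameters.forcing
    if apply_forcing:
        srgap1_of_t = lambda t: float(sched.level(t, s0))
    else:
        srgap1_of_t = lambda t: s0

    rhs, dynamic = make_rhs(topology, parameters, srgap1_of_t)
    y0 = np.array([float(initial_state[n]) for n in dynamic])
    if np.any(y0 < 0) or s0 < 0:
        raise ValidationError("initial concentrations must be >= 0")

    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, 601)
    t_eval = np.asarray(output_grid, dtype=float)

    # integrate in segments split at the ramp kink so the stiff solver
    # never steps across the non-smooth point
    breaks = [0.0, t_end]
    if apply_forcing and 0.0 < sched.t_start < t_end:
        breaks = [0.0, sched.t_start, t_end]
    times_out, ys_out = [], []
    y = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        seg_eval = np.unique(np.concatenate([[a], seg_eval, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=seg_eval)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            t_fail = sol.t[-1] if sol.t.size else a
            raise IntegrationFailure(
                f"integration failed near t = {t_fail:.6g}", time=float(t_fail))
        times_out.append(sol.t)
        ys_out.append(sol.y)
        y = sol.y[:, -1]

    t_all = np.concatenate(times_out)
    y_all = np.concatenate(ys_out, axis=1)
    # deduplicate segment joins and restrict to the requested grid
    keep = np.isin(t_all, t_eval)
    t_all, y_all = t_all[keep], y_all[:, keep]
    t_all, uniq = np.unique(t_all, return_index=True)
    y_all = y_all[:, uniq]

    values = pd.DataFrame({n: np.clip(y_all[i], 0.0, None) for i, n in enumerate(dynamic)})
    values[exo] = srgap1_of_t(0.0) if not apply_forcing else sched.level(t_all, s0)
    values = values[list(topology.nodes)]
    return Trajectory(times=t_all, values=values,
                      forcing=sched if apply_forcing else None, srgap1_initial=s0)


def steady_state(
    topology,
    parameters,
    initial_state,
    *,
    srgap1: float | None = None,
    tol: float = 1e-9,
    t_max: float = 1e5,
) -> tuple[dict[str, float], bool]:
    """Integrate with frozen SRGAP1 until ``||dX/dt|| < tol`` or ``t_max``.

    Returns the final state and a convergence flag.
    """
    state = dict(initial_state)
    if srgap1 is not None:
        state[parameters.exogenous] = srgap1
    rhs, dynamic = make_rhs(topology, parameters,
                            lambda t, s=state[parameters.exogenous]: s)
    t, chunk = 0.0, 500.0
    y = np.array([float(state[n]) for n in dynamic])
    while t < t_max:
        sol = solve_ivp(rhs, (0, chunk), y, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationFailure(f"equilibration failed near t = {t:.6g}", time=t)
        y = sol.y[:, -1]
        t += chunk
        if np.linalg.norm(rhs(0.0, y)) < tol:
            break
    out = {n: float(v) for n, v in zip(dynamic, y)}
    out[parameters.exogenous] = float(state[parameters.exogenous])
    converged = bool(np.linalg.norm(rhs(0.0, y)) < tol)
    return out, converged


# ---------------------------------------------------------------------------
# fixed-point analysis
# ---------------------------------------------------------------------------

def _jacobian(rhs, y, eps=1e-7):
    y = np.asarray(y, dtype=float)
    f0 = np.asarray(rhs(0.0, y))
    J = np.empty((y.size, y.size))
    for j in range(y.size):
        dy = y.copy()
        step = eps * max(1.0, abs(y[j]))
        dy[j] += step
        J[:, j] = (np.asarray(rhs(0.0, dy)) - f0) / step
    return J


def bistability_scan(
    topology: NetworkTopology,
    parameters: NetworkParameters,
    init_grid: Iterable[Mapping[str, float]] | None = None,
    *,
    srgap1: float = 0.0,
    cluster_tol: float = 1e-4,
    fp_tol: float = 1e-8,
) -> list[FixedPoint]:
    """Locate distinct stable fixed points with SRGAP1 frozen.

    Integrates to equilibrium from each start point, clusters the
    endpoints by proximity (tolerance ``cluster_tol`` in state space),
    polishes each cluster representative and verifies it is a genuine
    stable fixed point (``||RHS|| < fp_tol``, all Jacobian eigenvalue
    real parts negative). Results are sorted by descending RhoA.
    """
    exo = parameters.exogenous
    dynamic = [n for n in topology.nodes if n != exo]
    if init_grid is None:
        # low/high per node: 2^5 corners of the state box
        levels = [0.05, 2.0]
        init_grid = []
        for bits in range(2 ** len(dynamic)):
            state = {n: levels[(bits >> i) & 1] for i, n in enumerate(dynamic)}
            state[exo] = srgap1
            init_grid.append(state)

    endpoints, weights = [], []
    for start in init_grid:
        try:
            st, ok = steady_state(topology, parameters, start, srgap1=srgap1)
        except IntegrationFailure:
            continue  # flagged start point, not fatal
        if not ok:
            continue
        endpoints.append(np.array([st[n] for n in dynamic]))
        weights.append(1)

    clusters: list[tuple[np.ndarray, int]] = []
    for y in endpoints:
        for i, (c, k) in enumerate(clusters):
            if np.linalg.norm(y - c) < max(cluster_tol, 1e-6 * np.linalg.norm(c)):
                clusters[i] = ((c * k + y) / (k + 1), k + 1)
                break
        else:
            clusters.append((y, 1))

    rhs, _ = make_rhs(topology, parameters, lambda t: srgap1)
    out = []
    for c, k in clusters:
        norm = float(np.linalg.norm(rhs(0.0, c)))
        if norm >= fp_tol:
            continue
        J = _jacobian(rhs, c)
        eig = np.linalg.eigvals(J)
        state = {n: float(v) for n, v in zip(dynamic, c)}
        state[exo] = srgap1
        out.append(FixedPoint(state=state, rhs_norm=norm, eigenvalues=eig,
                              stable=bool(np.all(eig.real < 0)), n_basin_hits=k))
    out.sort(key=lambda fp: -fp.state["RhoA"])
    return out


# ---------------------------------------------------------------------------
# regimes and the ramp experiment
# ---------------------------------------------------------------------------

def classify_regime(
    trajectory: Trajectory,
    active_ref: float,
    inactive_ref: float,
    switch_fraction: float = 0.5,
) -> RegimeReport:
    """Label each time point as active-tuned or switched-inactive.

    A point is switched once RhoA has fallen below
    ``inactive_ref + switch_fraction * (active_ref - inactive_ref)`` and
    never recrosses that threshold upward.
    """
    if not active_ref > inactive_ref:
        raise ValidationError("active_ref must exceed inactive_ref")
    if not 0.0 < switch_fraction < 1.0:
        raise ValidationError("switch_fraction must lie in (0, 1)")
    rhoa = trajectory["RhoA"]
    threshold = inactive_ref + switch_fraction * (active_ref - inactive_ref)
    below = rhoa < threshold
    # switched from the first index after the last upward recrossing
    switched = np.zeros(len(rhoa), dtype=bool)
    if below[-1]:
        i = len(rhoa)
        while i > 0 and below[i - 1]:
            i -= 1
        switched[i:] = True
    labels = np.where(switched, SWITCHED_INACTIVE, ACTIVE_TUNED)
    switch_time = switch_srgap1 = None
    if switched.any():
        j = int(np.argmax(switched))
        switch_time = float(trajectory.times[j])
        level = float(trajectory["SRGAP1"][j])
        # a trajectory already switched at zero forcing has no
        # SRGAP1-attributable switch level
        switch_srgap1 = level if level > 0 else None
    return RegimeReport(labels=labels, switch_time=switch_time,
                        switch_srgap1=switch_srgap1,
                        active_ref=active_ref, inactive_ref=inactive_ref)


def srgap1_ramp_experiment(
    topology: NetworkTopology,
    parameters: NetworkParameters,
    *,
    t_end: float = 1200.0,
    output_grid: Sequence[float] | None = None,
    switch_fraction: float = 0.5,
    rtol: float = 1e-8,
) -> tuple[Trajectory, RegimeReport]:
    """Run the linear-SRGAP1-ramp protocol and classify the response.

    All junctional concentrations start at one and SRGAP1 at zero; the
    network equilibrates onto the active state during the pre-ramp
    window (the ramp default starts at t = 200, well after the ~100
    time units the network needs to settle), then SRGAP1 rises linearly.
    Branch reference levels come from a bistability scan at SRGAP1 = 0.
    """
    init = {n: (0.0 if n == parameters.exogenous else 1.0) for n in topology.nodes}
    traj = simulate(topology, parameters, init, t_end,
                    output_grid=output_grid, rtol=rtol)
    fps = [fp for fp in bistability_scan(topology, parameters) if fp.stable]
    if len(fps) < 2:
        raise ValidationError(
            "ramp classification requires a bistable SRGAP1-free network")
    active_ref = fps[0].state["RhoA"]
    inactive_ref = fps[-1].state["RhoA"]
    report = classify_regime(traj, active_ref, inactive_ref, switch_fraction)
    return traj, report


def frozen_srgap1_switch_level(
    topology,
    parameters,
    *,
    s_max: float = 4.0,
    tol: float = 1e-3,
) -> float:
    """Bisect for the SRGAP1 level where the active branch disappears.

    Starting each equilibration from the SRGAP1-free active state, the
    network stays on the active branch for frozen SRGAP1 just below the
    returned level and collapses to the inactive branch just above it.
    """
    fps = [fp for fp in bistability_scan(topology, parameters) if fp.stable]
    if len(fps) < 2:
        raise ValidationError("switch-level search requires bistability at SRGAP1 = 0")
    active = fps[0].state
    inactive_rhoa = fps[-1].state["RhoA"]
    mid = lambda: inactive_rhoa + 0.5 * (active["RhoA"] - inactive_rhoa)

    def on_active_branch(s):
        st, _ = steady_state(topology, parameters, active, srgap1=s)
        return st["RhoA"] > mid()

    lo, hi = 0.0, s_max
    if on_active_branch(hi):
        raise ValidationError(f"active branch persists up to SRGAP1 = {s_max}")
    while hi - lo > tol:
        m = 0.5 * (lo + hi)
        if on_active_branch(m):
            lo = m
        else:
            hi = m
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------

def model_to_config(topology: NetworkTopology, parameters: NetworkParameters) -> dict:
    return {
        "nodes": list(topology.nodes),
        "exogenous": parameters.exogenous,
        "edges": [
            {
                "source": e.source, "target": e.target, "sign": e.sign,
                "weight": parameters.edge_params[(e.source, e.target)].weight,
                "threshold": parameters.edge_params[(e.source, e.target)].threshold,
                "hill": parameters.edge_params[(e.source, e.target)].hill,
            }
            for e in topology.edges
        ],
        "basal": dict(parameters.basal),
        "removal": dict(parameters.removal),
        "forcing": {"t_start": parameters.forcing.t_start,
                    "slope": parameters.forcing.slope},
    }


def model_from_config(cfg: Mapping) -> tuple[NetworkTopology, NetworkParameters]:
    try:
        topology = NetworkTopology(
            nodes=tuple(cfg["nodes"]),
            edges=tuple(Edge(e["source"], e["target"], e["sign"])
                        for e in cfg["edges"]),
        )
        parameters = NetworkParameters(
            basal=dict(cfg["basal"]),
            removal=dict(cfg["removal"]),
            edge_params={(e["source"], e["target"]):
                         EdgeParams(e["weight"], e["threshold"], e["hill"])
                         for e in cfg["edges"]},
            forcing=RampSchedule(**cfg.get("forcing", {})),
            exogenous=cfg.get("exogenous", "SRGAP1"),
        )
    except KeyError as exc:
        raise ValidationError(f"model config missing key {exc}") from exc
    parameters.validate_against(topology)
    return topology, parameters


def save_model(path, topology, parameters) -> None:
    path = Path(path)
    cfg = model_to_config(topology, parameters)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")


def load_model(path) -> tuple[NetworkTopology, NetworkParameters]:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return model_from_config(cfg)
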