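"""Continuous (normalized-Hill / HillCube) semantics.

Each node i follows

    dx_i/dt = tau * ( Bbar_i( f(x_parents) ) - x_i ),        x_i in [0, 1]

where ``Bbar_i`` is the multilinear (BooleCube) interpolation of the node's
Boolean rule over the unit hypercube and ``f`` is the normalized Hill
transfer applied to each parent activity:

    f(x; k, h) = x**h * (1 + k**h) / (x**h + k**h)

with ``f(0) = 0`` and ``f(1) = 1`` exactly.  At high steepness ``h`` the
continuous steady states approach the Boolean fixed points; the defaults
(decay ``tau = 1.0`` per second, steepness ``h = 10``, global threshold
``k = 0.5``, ``dt = 0.05`` s, horizon 400 s) are the standard
SQUAD/Odefy-style parameterisation of the case study.

Perturbations are deterministic clamp schedules: a node may be held at a
constant or at a bounded sinusoidal waveform over a time window, overriding
its ODE; outside the window the ODE resumes from the clamped value (which is
how an un-replenished inhibitor decays back to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .network import ActivityState, RegulatoryNetwork
from .logic import CUSTOM, CONSTITUTIVE_NOT, OR_AND_NOT, SOURCE_ZERO, LogicRule

_LOG_FLOOR = 1e-300  # keeps log(1-f) finite when f == 1 exactly


class SimulationNumericalError(RuntimeError):
    """NaN/Inf encountered during integration."""


@dataclass
class SimulationConfig:
    """Integration and transfer-function parameters.

    steepness : Hill exponent h (dimensionless, >= 1)
    decay     : relaxation rate tau (per second, > 0)
    threshold : half-activation point k in (0, 1); a global value, optionally
                overridden per edge via ``edge_thresholds[(source, target)]``
    dt        : integration step (seconds)
    t_end     : horizon (seconds)
    integrator: "rk4" (default) or "euler"
    """

    steepness: float = 10.0
    decay: float = 1.0
    threshold: float = 0.5
    dt: float = 0.05
    t_end: float = 400.0
    integrator: str = "rk4"
    edge_thresholds: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.steepness < 1:
            raise ValueError("steepness must be >= 1")
        if self.decay <= 0:
            raise ValueError("decay must be > 0")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.integrator not in ("rk4", "euler"):
            raise ValueError("integrator must be 'rk4' or 'euler'")

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["edge_thresholds"] = {
            f"{s}->{t}": v for (s, t), v in self.edge_thresholds.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        et = {}
        for key, v in (d.pop("edge_thresholds", {}) or {}).items():
            s, t = key.split("->", 1)
            et[(s, t)] = float(v)
        return cls(edge_thresholds=et, **d)


@dataclass
class ClampEntry:
    """Hold ``node`` over ``[t_start, t_stop]`` at a constant or waveform.

    mode "clamp_constant": value = ``value``.
    mode "clamp_waveform": value = baseline + amplitude*sin(2*pi*t/period + phase),
    clipped to [0, 1].
    """

    node: str
    t_start: float
    t_stop: float
    mode: str = "clamp_constant"
    value: float = 0.0
    baseline: float = 0.0
    amplitude: float = 0.0
    period: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("clamp_constant", "clamp_waveform"):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if self.t_stop < self.t_start:
            raise ValueError("clamp window must have t_stop >= t_start")
        if self.mode == "clamp_constant" and not (0 <= self.value <= 1):
            raise ValueError("clamp value must lie in [0, 1]")
        if self.mode == "clamp_waveform" and self.period <= 0:
            raise ValueError("waveform period must be > 0")

    def active(self, t: float) -> bool:
        # small tolerance: accumulated float error in t must not drop the
        # final integration step out of a window ending exactly at t_end
        eps = 1e-9 * max(1.0, abs(self.t_stop))
        return self.t_start - eps <= t <= self.t_stop + eps

    def value_at(self, t: float) -> float:
        if self.mode == "clamp_constant":
            return self.value
        v = self.baseline + self.amplitude * math.sin(
            2 * math.pi * t / self.period + self.phase
        )
        return min(1.0, max(0.0, v))


@dataclass
class PerturbationSchedule:
    """A list of clamp entries; later entries win on overlap."""

    entries: list[ClampEntry] = field(default_factory=list)

    def clamp_value(self, node: str, t: float) -> float | None:
        val = None
        for e in self.entries:
            if e.node == node and e.active(t):
                val = e.value_at(t)
        return val

    def clamped_nodes(self) -> set[str]:
        return {e.node for e in self.entries}

    def validate(self, config: SimulationConfig) -> "PerturbationSchedule":
        for e in self.entries:
            if e.t_start < 0 or e.t_stop > config.t_end:
                raise ValueError(
                    f"clamp window [{e.t_start}, {e.t_stop}] outside "
                    f"[0, {config.t_end}]"
                )
        return self

    def to_dict(self) -> list[dict]:
        return [asdict(e) for e in self.entries]

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "PerturbationSchedule":
        return cls([ClampEntry(**dict(e)) for e in entries])


def config_to_yaml(config: SimulationConfig, schedule: PerturbationSchedule) -> str:
    doc = config.to_dict()
    doc["perturbations"] = schedule.to_dict()
    return yaml.safe_dump(doc, sort_keys=True)


def config_from_yaml(text: str) -> tuple[SimulationConfig, PerturbationSchedule]:
    doc = yaml.safe_load(text)
    perts = doc.pop("perturbations", [])
    return SimulationConfig.from_dict(doc), PerturbationSchedule.from_dict(perts)


# -- transfer functions --------------------------------------------------


def normalized_hill(x, k: float = 0.5, h: float = 10.0):
    """Normalized Hill transfer f(x) = x^h (1 + k^h) / (x^h + k^h).

    Monotone non-decreasing on [0, 1] with f(0) = 0 and f(1) = 1 exactly.
    Accepts scalars or arrays; raises on inputs outside [0, 1].
    """
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0) | (xa > 1)):
        raise ValueError(f"activity outside [0, 1]: {x!r}")
    kh = k ** h
    out = xa ** h * (1 + kh) / (xa ** h + kh)
    return out if isinstance(x, np.ndarray) else float(out)


def boolecube(rule: LogicRule, inputs: Mapping[str, float]) -> float:
    """Multilinear (BooleCube) interpolation of ``rule`` at ``inputs``.

    Sum over all Boolean vertices v of B(v) * prod_i [x_i if v_i else 1-x_i];
    equals the Boolean rule exactly on {0,1} vertices and is multilinear in
    each input.  For the OR/AND-NOT family the sum factorises:

        Bbar = (1 - prod_a (1-x_a)) * prod_i (1-x_i)
    """
    for p in rule.parents:
        if p not in inputs:
            raise KeyError(f"missing parent {p!r} for node {rule.node!r}")
        v = inputs[p]
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"input {p!r}={v} outside [0, 1]")
    if rule.form == SOURCE_ZERO:
        return 0.0
    if rule.form == CUSTOM:
        total = 0.0
        p = len(rule.parents)
        for vertex in range(1 << p):
            if not rule.table[vertex]:
                continue
            w = 1.0
            for i, parent in enumerate(rule.parents):
                xi = inputs[parent]
                w *= xi if (vertex >> i) & 1 else 1.0 - xi
            total += w
        return total
    not_inh = 1.0
    for i in rule.inhibitors:
        not_inh *= 1.0 - inputs[i]
    if rule.form == CONSTITUTIVE_NOT:
        return not_inh
    some_act = 1.0
    for a in rule.activators:
        some_act *= 1.0 - inputs[a]
    return (1.0 - some_act) * not_inh


# -- vectorised RHS ------------------------------------------------------


class _CompiledNetwork:
    """Per-network precomputation: adjacency matrices for the rule family.

    For nodes with factorisable rules the drive is computed with two
    matvecs in log space; nodes with custom truth tables or per-edge
    thresholds fall back to the generic boolecube path.
    """

    def __init__(self, net: RegulatoryNetwork, config: SimulationConfig):
        self.net = net
        self.config = config
        n = net.n_nodes
        self.act = np.zeros((n, n))
        self.inh = np.zeros((n, n))
        self.has_act = np.zeros(n, dtype=bool)
        self.is_source = np.zeros(n, dtype=bool)
        self.slow_nodes: list[int] = []
        slow_parents: set[str] = set()
        if config.edge_thresholds:
            slow_parents = {t for (_, t) in config.edge_thresholds}
        for i, name in enumerate(net.nodes):
            rule = net.logic[name]
            if rule.form == CUSTOM or name in slow_parents:
                self.slow_nodes.append(i)
                continue
            if rule.form == SOURCE_ZERO:
                self.is_source[i] = True
                continue
            self.has_act[i] = rule.form == OR_AND_NOT
            for a in rule.activators:
                self.act[i, net.index(a)] = 1.0
            for b in rule.inhibitors:
                self.inh[i, net.index(b)] = 1.0

    def drive(self, x: np.ndarray) -> np.ndarray:
        """Bbar_i(f(x)) for all nodes."""
        cfg = self.config
        f = normalized_hill(np.clip(x, 0.0, 1.0), cfg.threshold, cfg.steepness)
        log1mf = np.log(np.clip(1.0 - f, _LOG_FLOOR, 1.0))
        not_any_act = np.exp(self.act @ log1mf)   # prod_a (1-f_a)
        not_any_inh = np.exp(self.inh @ log1mf)   # prod_i (1-f_i)
        bbar = np.where(self.has_act, 1.0 - not_any_act, 1.0) * not_any_inh
        bbar[self.is_source] = 0.0
        for i in self.slow_nodes:
            name = self.net.nodes[i]
            rule = self.net.logic[name]
            inputs = {}
            for p in rule.parents:
                k = cfg.edge_thresholds.get((p, name), cfg.threshold)
                inputs[p] = normalized_hill(
                    float(np.clip(x[self.net.index(p)], 0.0, 1.0)),
                    k,
                    cfg.steepness,
                )
            bbar[i] = boolecube(rule, inputs)
        return bbar


def ode_rhs(
    state: ActivityState,
    net: RegulatoryNetwork,
    config: SimulationConfig,
    t: float = 0.0,
    schedule: PerturbationSchedule | None = None,
) -> dict[str, float]:
    """Rates dx/dt (per second) for a validated state.

    Unclamped node i: ``tau * (Bbar_i(f(parents)) - x_i)``; a node clamped at
    time ``t`` reports rate 0 (its activity is overridden by the clamp).
    """
    state.validate(net)
    x = state.as_vector(net)
    compiled = _CompiledNetwork(net, config)
    rates = _rhs_vec(compiled, x, t, schedule)
    return {n: float(rates[i]) for i, n in enumerate(net.nodes)}


def _apply_clamps(
    net: RegulatoryNetwork,
    x: np.ndarray,
    t: float,
    schedule: PerturbationSchedule | None,
) -> np.ndarray:
    if schedule is None:
        return x
    x = x.copy()
    for node in schedule.clamped_nodes():
        v = schedule.clamp_value(node, t)
        if v is not None:
            x[net.index(node)] = v
    return x


def _rhs_vec(
    compiled: _CompiledNetwork,
    x: np.ndarray,
    t: float,
    schedule: PerturbationSchedule | None,
) -> np.ndarray:
    net = compiled.net
    x = _apply_clamps(net, x, t, schedule)
    rates = compiled.config.decay * (compiled.drive(x) - x)
    if schedule is not None:
        for node in schedule.clamped_nodes():
            if schedule.clamp_value(node, t) is not None:
                rates[net.index(node)] = 0.0
    return rates


@dataclass
class Trajectory:
    """Time x node activity matrix with its provenance."""

    times: np.ndarray
    activities: np.ndarray  # shape (len(times), n_nodes)
    nodes: list[str]
    config: SimulationConfig
    schedule: PerturbationSchedule

    def final_state(self) -> ActivityState:
        return ActivityState(
            {n: float(self.activities[-1, i]) for i, n in enumerate(self.nodes)}
        )

    def series(self, node: str) -> np.ndarray:
        return self.activities[:, self.nodes.index(node)]

    def first_crossing(self, node: str, level: float = 0.5) -> float | None:
        """First upward crossing time of ``level`` (linear interpolation)."""
        y = self.series(node)
        above = y >= level
        if above[0]:
            return float(self.times[0])
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            return None
        i = int(idx[0])
        y0, y1 = y[i], y[i + 1]
        t0, t1 = self.times[i], self.times[i + 1]
        if y1 == y0:
            return float(t1)
        return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.activities, columns=self.nodes)
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        times = df["time_s"].to_numpy(dtype=float)
        nodes = [c for c in df.columns if c != "time_s"]
        return cls(
            times=times,
            activities=df[nodes].to_numpy(dtype=float),
            nodes=nodes,
            config=SimulationConfig(
                dt=float(times[1] - times[0]) if len(times) > 1 else 0.05,
                t_end=float(times[-1]) if len(times) > 1 else 0.05,
            ),
            schedule=PerturbationSchedule(),
        )


def simulate(
    net: RegulatoryNetwork,
    init: ActivityState,
    config: SimulationConfig | None = None,
    schedule: PerturbationSchedule | None = None,
) -> Trajectory:
    """Fixed-step integration from t=0 to t_end.

    RK4 by default (Euler available for cross-checks); activities are
    hard-clipped to [0, 1] after each step to guard against overshoot at
    high steepness, and clamped nodes are overwritten each step while inside
    their window.  Deterministic for fixed config and schedule.
    """
    config = config or SimulationConfig()
    schedule = (schedule or PerturbationSchedule()).validate(config)
    init.validate(net)
    compiled = _CompiledNetwork(net, config)
    n_steps = int(round(config.t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    acts = np.empty((n_steps + 1, net.n_nodes))
    x = _apply_clamps(net, init.as_vector(net), 0.0, schedule)
    acts[0] = x
    dt = config.dt
    rhs = lambda xx, tt: _rhs_vec(compiled, xx, tt, schedule)
    for step in range(n_steps):
        t = step * dt
        if config.integrator == "euler":
            x = x + dt * rhs(x, t)
        else:
            k1 = rhs(x, t)
            k2 = rhs(x + 0.5 * dt * k1, t + 0.5 * dt)
            k3 = rhs(x + 0.5 * dt * k2, t + 0.5 * dt)
            k4 = rhs(x + dt * k3, t + dt)
            x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            bad = net.nodes[int(np.nonzero(~np.isfinite(x))[0][0])]
            raise SimulationNumericalError(
                f"non-finite activity at node {bad!r}, t={t + dt:.3f} s"
            )
        x = np.clip(x, 0.0, 1.0)
        x = _apply_clamps(net, x, t + dt, schedule)
        acts[step + 1] = x
    return Trajectory(times=times, activities=acts, nodes=list(net.nodes),
                      config=config, schedule=schedule)


def steady_state_from_trajectory(
    traj: Trajectory, window: float = 50.0, tol: float = 1e-3
) -> tuple[ActivityState, bool]:
    """Endpoint extraction: (final state, settled?).

    ``settled`` is true when the maximum |change| of every node over the
    trailing ``window`` seconds is below ``tol`` — e.g. a node clamped to an
    oscillating waveform never settles.
    """
    if window > traj.config.t_end:
        raise ValueError("window exceeds the simulated horizon")
    n_tail = max(2, int(round(window / traj.config.dt)) + 1)
    tail = traj.activities[-n_tail:]
    drift = np.max(tail.max(axis=0) - tail.min(axis=0))
    return traj.final_state(), bool(drift < tol)
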