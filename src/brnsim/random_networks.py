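"""Random signed Boolean regulatory networks.

Generator for synthetic networks with the structural properties the analysis
assumes — a handful of parentless source nodes feeding a mostly tree-like
signed cascade of ~14 nodes — so that every stage (Boolean semantics,
continuous dynamics, scenario machinery, cross-oracles) is testable without
any download.

Acyclic generation orders the nodes and only draws forward edges; cyclic
mode adds a configurable number of feedback (back) edges afterwards.  The
steep-limit suite is the cross-oracle between the discrete and continuous
semantics: on acyclic networks with clamped sources, thresholding the
continuous endpoint at high steepness must recover a Boolean fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ACTIVATION, INHIBITION, Interaction, RegulatoryNetwork
from .logic import BooleanState, boolean_update_sync, enumerate_fixed_points
from .dynamics import (
    ClampEntry,
    PerturbationSchedule,
    SimulationConfig,
    simulate,
)


@dataclass
class GeneratorSpec:
    """Size/shape parameters for :func:`random_brn`.

    edge_density is the expected number of (incoming) edges per non-source
    node; inhibition_fraction the probability an edge is inhibitory.
    """

    n_nodes: int = 14
    edge_density: float = 1.5
    inhibition_fraction: float = 0.3
    n_sources: int = 2
    acyclic: bool = True
    n_feedback: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0.0 <= self.inhibition_fraction <= 1.0):
            raise ValueError("inhibition_fraction must lie in [0, 1]")
        if not (0 <= self.n_sources < self.n_nodes):
            raise ValueError("n_sources must satisfy 0 <= n_sources < n_nodes")
        if self.edge_density < 1.0:
            raise ValueError(
                "edge_density < 1 cannot give every non-source node a parent"
            )


def random_brn(spec: GeneratorSpec) -> RegulatoryNetwork:
    """A reproducible random signed network honouring ``spec``.

    Nodes are named N00, N01, ... in topological construction order (the
    first ``n_sources`` are parentless).  Every non-source node receives at
    least one parent; extra forward edges are drawn to match the expected
    density.  Default logic rules are attached.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"N{i:02d}" for i in range(spec.n_nodes)]
    edges: list[Interaction] = []
    seen: set[tuple[str, str]] = set()

    def draw_sign() -> str:
        return INHIBITION if rng.random() < spec.inhibition_fraction else ACTIVATION

    # guaranteed connectivity: one parent among earlier nodes
    for i in range(spec.n_sources, spec.n_nodes):
        j = int(rng.integers(i))
        edges.append(Interaction(names[j], names[i], draw_sign()))
        seen.add((names[j], names[i]))
    # extra forward edges up to expected density
    n_targets = spec.n_nodes - spec.n_sources
    n_extra = int(round((spec.edge_density - 1.0) * n_targets))
    attempts = 0
    while n_extra > 0 and attempts < 50 * n_targets:
        attempts += 1
        i = int(rng.integers(max(spec.n_sources, 1), spec.n_nodes))
        if i == 0:
            continue
        j = int(rng.integers(i))
        if (names[j], names[i]) in seen:
            continue
        edges.append(Interaction(names[j], names[i], draw_sign()))
        seen.add((names[j], names[i]))
        n_extra -= 1
    if not spec.acyclic:
        added = 0
        attempts = 0
        while added < spec.n_feedback and attempts < 50 * spec.n_nodes:
            attempts += 1
            i = int(rng.integers(spec.n_nodes - 1))
            j = int(rng.integers(i + 1, spec.n_nodes))
            if (names[j], names[i]) in seen or i < spec.n_sources:
                continue
            edges.append(Interaction(names[j], names[i], draw_sign()))
            seen.add((names[j], names[i]))
            added += 1
    return RegulatoryNetwork(names, edges)


def source_nodes(net: RegulatoryNetwork) -> list[str]:
    return [n for n in net.nodes if not net.parents_of(n)]


def steep_limit_suite(
    n_instances: int = 50,
    spec: GeneratorSpec | None = None,
    h_high: float = 50.0,
    t_end: float = 60.0,
    dt: float = 0.05,
    seed: int = 0,
) -> dict:
    """Cross-oracle: continuous endpoints at high steepness vs Boolean fixed points.

    For each generated acyclic instance, the source nodes are clamped to a
    random Boolean vertex; the Boolean fixed points are enumerated
    exhaustively and the continuous model is integrated from the same
    clamped all-zero configuration at steepness ``h_high``.  The endpoint is
    thresholded at 0.5 and checked for membership in the Boolean fixed-point
    set.  Returns the agreement fraction plus per-instance diagnostics
    (mismatching activities and their distance from the 0.5 threshold).
    """
    spec = spec or GeneratorSpec(n_nodes=10, n_sources=2, acyclic=True)
    if not spec.acyclic:
        raise ValueError("the steep-limit oracle requires acyclic networks")
    rng = np.random.default_rng(seed)
    agree = 0
    details = []
    for inst in range(n_instances):
        inst_spec = GeneratorSpec(
            n_nodes=spec.n_nodes,
            edge_density=spec.edge_density,
            inhibition_fraction=spec.inhibition_fraction,
            n_sources=spec.n_sources,
            acyclic=True,
            seed=int(rng.integers(2**31 - 1)),
        )
        net = random_brn(inst_spec)
        sources = source_nodes(net)
        clamp_bits = {s: int(rng.integers(2)) for s in sources}
        attractors = enumerate_fixed_points(net, clamps=clamp_bits)
        fp_codes = {
            tuple(s.bits[n] for n in net.nodes) for s in attractors.fixed_points
        }
        config = SimulationConfig(steepness=h_high, dt=dt, t_end=t_end)
        schedule = PerturbationSchedule(
            [
                ClampEntry(node=s, t_start=0.0, t_stop=t_end,
                           mode="clamp_constant", value=float(b))
                for s, b in clamp_bits.items()
            ]
        )
        from .network import ActivityState

        init = ActivityState.zeros(net)
        for s, b in clamp_bits.items():
            init.values[s] = float(b)
        traj = simulate(net, init, config, schedule)
        finals = traj.final_state()
        thresholded = tuple(int(finals.values[n] > 0.5) for n in net.nodes)
        hit = thresholded in fp_codes
        agree += int(hit)
        mism = [
            (n, finals.values[n])
            for n, b in zip(net.nodes, thresholded)
            if not hit
            and abs(finals.values[n] - 0.5) < 0.45  # away from saturation
        ]
        details.append(
            {"instance": inst, "agrees": hit, "ambiguous_nodes": mism}
        )
    return {
        "n_instances": n_instances,
        "n_agree": agree,
        "fraction": agree / n_instances,
        "h_high": h_high,
        "details": details,
    }
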