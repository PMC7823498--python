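"""Discrete (Boolean) semantics of a signed regulatory network.

Each node carries a LogicRule, a Boolean function of its parents.  The
default rule family is the standard one for signed networks:

* ``or_and_not`` — node is on iff at least one activator is on and no
  inhibitor is on: ``B = OR(activators) AND NOT OR(inhibitors)``;
* ``constitutive_not`` — a node with only inhibitors is on iff none of them
  is: ``B = NOT OR(inhibitors)`` (this is what lets low calcium de-repress
  BAD);
* ``source_zero`` — a parentless node has no drive and decays to 0 unless
  clamped (this is why an un-replenished Inhibitor relaxes from 1.0 to 0.0).

Custom truth tables may be attached per node for tuning.

The module provides synchronous and asynchronous-random updating and
exhaustive fixed-point localisation — the discrete first phase of
steady-state analysis, whose fixed points the continuous model approximates
at high steepness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import RegulatoryNetwork

OR_AND_NOT = "or_and_not"
CONSTITUTIVE_NOT = "constitutive_not"
SOURCE_ZERO = "source_zero"
CUSTOM = "custom"

#: refuse exhaustive enumeration above this many free (non-clamped) nodes
ENUMERATION_BOUND = 24


class CapabilityError(RuntimeError):
    """The requested exhaustive operation exceeds the supported size."""


@dataclass(frozen=True)
class LogicRule:
    """Boolean update function of one node over its parents.

    ``activators``/``inhibitors`` list the parent nodes by sign and are, for
    rules attached by :func:`default_logic_rule`, exactly the in-neighbours
    of the node.  For ``form == "custom"``, ``table`` holds 2**p entries
    (p = number of parents, activators then inhibitors) indexed by the
    bitmask with parent ``i`` at bit ``i``.
    """

    node: str
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()
    form: str = SOURCE_ZERO
    table: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.form not in (OR_AND_NOT, CONSTITUTIVE_NOT, SOURCE_ZERO, CUSTOM):
            raise ValueError(f"unknown rule form {self.form!r}")
        if self.form == CUSTOM:
            if self.table is None or len(self.table) != 2 ** len(self.parents):
                raise ValueError(
                    f"custom table for {self.node!r} must have exactly "
                    f"2**{len(self.parents)} entries"
                )
            if any(v not in (0, 1) for v in self.table):
                raise ValueError("custom table entries must be 0 or 1")

    @property
    def parents(self) -> tuple[str, ...]:
        return self.activators + self.inhibitors

    def evaluate(self, bits: Mapping[str, int]) -> int:
        """Boolean output for a parent assignment (0/1 values)."""
        if self.form == SOURCE_ZERO:
            return 0
        if self.form == CUSTOM:
            idx = 0
            for i, p in enumerate(self.parents):
                idx |= (1 if bits[p] else 0) << i
            return int(self.table[idx])
        act = any(bits[a] for a in self.activators)
        inh = any(bits[i] for i in self.inhibitors)
        if self.form == CONSTITUTIVE_NOT:
            return int(not inh)
        return int(act and not inh)


def default_logic_rule(net: RegulatoryNetwork, node: str) -> LogicRule:
    """The default rule for ``node`` given its signed in-neighbours."""
    if node not in net.nodes:
        raise KeyError(f"undeclared node {node!r}")
    acts = tuple(net.activators_of(node))
    inhs = tuple(net.inhibitors_of(node))
    if acts:
        return LogicRule(node, acts, inhs, OR_AND_NOT)
    if inhs:
        return LogicRule(node, (), inhs, CONSTITUTIVE_NOT)
    return LogicRule(node, (), (), SOURCE_ZERO)


@dataclass
class BooleanState:
    """A complete 0/1 assignment over the declared nodes."""

    bits: dict[str, int] = field(default_factory=dict)

    def validate(self, net: RegulatoryNetwork) -> "BooleanState":
        missing = [n for n in net.nodes if n not in self.bits]
        if missing:
            raise ValueError(f"state missing nodes: {missing}")
        bad = {n: v for n, v in self.bits.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary values: {bad}")
        return self

    def copy(self) -> "BooleanState":
        return BooleanState(dict(self.bits))


@dataclass
class AttractorSet:
    """Fixed points (and, for synchronous dynamics, limit cycles)."""

    fixed_points: list[BooleanState]
    cycles: list[list[BooleanState]] = field(default_factory=list)
    method: str = "exhaustive_sync"

    def to_json(self) -> str:
        return json.dumps(
            {
                "fixed_points": [s.bits for s in self.fixed_points],
                "cycles": [[s.bits for s in cyc] for cyc in self.cycles],
                "method": self.method,
            },
            indent=2,
            sort_keys=True,
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def boolean_update_sync(
    state: BooleanState,
    net: RegulatoryNetwork,
    clamps: Mapping[str, int] | None = None,
) -> BooleanState:
    """Update all nodes simultaneously by their LogicRules.

    ``clamps`` holds nodes at fixed 0/1 values during the update.
    """
    state.validate(net)
    clamps = clamps or {}
    nxt = {}
    for n in net.nodes:
        if n in clamps:
            nxt[n] = int(clamps[n])
        else:
            nxt[n] = net.logic[n].evaluate(state.bits)
    return BooleanState(nxt)


def boolean_update_async(
    state: BooleanState,
    net: RegulatoryNetwork,
    rng: np.random.Generator | int,
) -> BooleanState:
    """ARBN-style update: one uniformly chosen node recomputes its rule.

    ``rng`` is a seeded ``numpy`` Generator (or an integer seed); a single
    generator owned by the simulation run makes repeated calls reproducible.
    """
    state.validate(net)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chosen = net.nodes[int(rng.integers(net.n_nodes))]
    nxt = state.copy()
    nxt.bits[chosen] = net.logic[chosen].evaluate(state.bits)
    return nxt


def _state_matrix(n: int, offset: int, count: int) -> np.ndarray:
    """Rows = integers offset..offset+count-1 as n-bit vectors (bit i = col i)."""
    ints = np.arange(offset, offset + count, dtype=np.int64)
    return (ints[:, None] >> np.arange(n)) & 1


def enumerate_fixed_points(
    net: RegulatoryNetwork,
    clamps: Mapping[str, int] | None = None,
    _chunk: int = 1 << 18,
) -> AttractorSet:
    """All synchronous fixed points, by exhaustive enumeration.

    Clamped nodes are held at their clamp value throughout the test, so only
    the 2**(free nodes) assignments are enumerated.  Networks with more than
    24 free nodes are refused (use sampling on the continuous side instead).
    """
    clamps = dict(clamps or {})
    free = [n for n in net.nodes if n not in clamps]
    if len(free) > ENUMERATION_BOUND:
        raise CapabilityError(
            f"{len(free)} non-clamped nodes exceeds the exhaustive bound "
            f"of {ENUMERATION_BOUND}; consider sampled_async exploration"
        )
    nf = len(free)
    total = 1 << nf
    fixed: list[BooleanState] = []
    for offset in range(0, total, _chunk):
        count = min(_chunk, total - offset)
        mat = _state_matrix(nf, offset, count)  # count x nf
        cols = {n: mat[:, j] for j, n in enumerate(free)}
        for n, v in clamps.items():
            cols[n] = np.full(count, int(v), dtype=np.int64)
        ok = np.ones(count, dtype=bool)
        for n in free:
            nxt = _vector_rule(net.logic[n], cols)
            ok &= nxt == cols[n]
            if not ok.any():
                break
        for row in np.nonzero(ok)[0]:
            bits = {n: int(cols[n][row]) for n in net.nodes}
            fixed.append(BooleanState(bits))
    return AttractorSet(fixed_points=fixed, cycles=[], method="exhaustive_sync")


def _vector_rule(rule: LogicRule, cols: Mapping[str, np.ndarray]) -> np.ndarray:
    some = next(iter(cols.values()))
    if rule.form == SOURCE_ZERO:
        return np.zeros_like(some)
    if rule.form == CUSTOM:
        idx = np.zeros_like(some)
        for i, p in enumerate(rule.parents):
            idx |= cols[p] << i
        return np.asarray(rule.table, dtype=np.int64)[idx]
    act = np.zeros_like(some, dtype=bool)
    for a in rule.activators:
        act |= cols[a].astype(bool)
    inh = np.zeros_like(some, dtype=bool)
    for i in rule.inhibitors:
        inh |= cols[i].astype(bool)
    if rule.form == CONSTITUTIVE_NOT:
        return (~inh).astype(np.int64)
    return (act & ~inh).astype(np.int64)


def attractors_sync(
    net: RegulatoryNetwork,
    clamps: Mapping[str, int] | None = None,
    max_nodes: int = 20,
) -> AttractorSet:
    """Fixed points *and* synchronous limit cycles, rotation-deduplicated.

    Builds the full successor map of the synchronous dynamics, so it is
    limited to smaller networks than pure fixed-point enumeration.
    """
    clamps = dict(clamps or {})
    free = [n for n in net.nodes if n not in clamps]
    nf = len(free)
    if nf > max_nodes:
        raise CapabilityError(
            f"{nf} non-clamped nodes exceeds the successor-map bound of {max_nodes}"
        )
    total = 1 << nf
    mat = _state_matrix(nf, 0, total)
    cols = {n: mat[:, j] for j, n in enumerate(free)}
    for n, v in clamps.items():
        cols[n] = np.full(total, int(v), dtype=np.int64)
    succ = np.zeros(total, dtype=np.int64)
    for j, n in enumerate(free):
        succ |= _vector_rule(net.logic[n], cols) << j

    def unpack(code: int) -> BooleanState:
        bits = {n: (code >> j) & 1 for j, n in enumerate(free)}
        bits.update({n: int(v) for n, v in clamps.items()})
        return BooleanState({n: int(bits[n]) for n in net.nodes})

    fixed = [unpack(s) for s in range(total) if succ[s] == s]
    # find cycles: iterate successor map with colouring
    colour = np.zeros(total, dtype=np.int8)  # 0 unseen, 1 in-progress, 2 done
    cycles: list[list[BooleanState]] = []
    for start in range(total):
        if colour[start]:
            continue
        path = []
        s = start
        while colour[s] == 0:
            colour[s] = 1
            path.append(s)
            s = int(succ[s])
        if colour[s] == 1:  # found a new cycle; s is on it
            cyc = [s]
            t = int(succ[s])
            while t != s:
                cyc.append(t)
                t = int(succ[t])
            if len(cyc) >= 2:
                # canonical rotation: start at the smallest code
                k = cyc.index(min(cyc))
                cyc = cyc[k:] + cyc[:k]
                cycles.append([unpack(c) for c in cyc])
        for p in path:
            colour[p] = 2
    return AttractorSet(fixed_points=fixed, cycles=cycles, method="exhaustive_sync")
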