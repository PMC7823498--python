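"""The IP3R case-study pipeline: four scenarios, endpoints, event times.

The four scenarios are the columns of the published before/after activity
table:

* ``normal`` — intact IP3R signalling; the proliferative programme wins and
  apoptosis stays off;
* ``normal_perturbed`` — IP3R attenuated by a perturbation waveform; calcium
  collapses, BAD is de-repressed and the intrinsic apoptotic cascade fires;
* ``cancer`` — IP3R hyperactive (clamped at 1.0); maximal proliferation, no
  apoptosis;
* ``cancer_inhibitor`` — a pharmacological inhibitor pulls IP3R down; the
  apoptotic cascade fires early and latches even though IP3R later recovers.

Saturated reference endpoints (exactly 0.0 or 1.0) correspond to robust
attractors and are judged at a hard tolerance; intermediate endpoints depend
on the authors' unpublished logic tables and perturbation waveform and are
compared by qualitative activity band only (inactive < 0.2, low 0.2-0.5,
active > 0.5), reported but never gated.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .network import ActivityState, RegulatoryNetwork, ip3r_reference_network
from .dynamics import (
    PerturbationSchedule,
    SimulationConfig,
    Trajectory,
    simulate,
    steady_state_from_trajectory,
)

SCENARIO_NAMES = ("normal", "normal_perturbed", "cancer", "cancer_inhibitor")

#: qualitative activity bands of the scaled-concentration convention
BANDS = (("inactive", 0.0, 0.2), ("low", 0.2, 0.5), ("active", 0.5, 1.0))


def activity_band(x: float) -> str:
    """inactive (< 0.2), low (0.2-0.5) or active (> 0.5)."""
    if x < 0.2:
        return "inactive"
    if x <= 0.5:
        return "low"
    return "active"


@dataclass
class Scenario:
    """One column-pair of the reference table: initial state, clamps, targets."""

    name: str
    init: ActivityState
    schedule: PerturbationSchedule
    reference: dict[str, float]           # node -> expected final activity
    reference_before: dict[str, float] = field(default_factory=dict)
    perturbed_nodes: tuple[str, ...] = ()
    description: str = ""


@dataclass
class ScenarioResult:
    trajectory: Trajectory
    finals: ActivityState
    settled: bool
    deviations: dict[str, float]          # only nodes with a reference value
    events: dict[str, float | None]       # node -> first 0.5 upward crossing (s)


def _load_scenario_doc() -> dict:
    ref = importlib.resources.files("brnsim.data") / "scenarios.yaml"
    with importlib.resources.as_file(ref) as p:
        return yaml.safe_load(Path(p).read_text(encoding="utf-8"))


def build_scenario(name: str, net: RegulatoryNetwork | None = None) -> Scenario:
    """Build one of the packaged scenarios against the reference network."""
    doc = _load_scenario_doc()
    if name not in doc["scenarios"]:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {sorted(doc['scenarios'])}"
        )
    net = net or ip3r_reference_network()
    aliases: dict[str, str] = doc.get("reference_aliases", {}) or {}
    entry = doc["scenarios"][name]
    init = ActivityState.zeros(net)
    for node, v in (entry.get("init") or {}).items():
        init.values[node] = float(v)
    init.validate(net)
    schedule = PerturbationSchedule.from_dict(entry.get("clamps") or [])
    reference: dict[str, float] = {}
    before: dict[str, float] = {}
    perturbed: list[str] = []
    for label, cell in (entry.get("reference") or {}).items():
        node = aliases.get(label, label)
        if node not in net.nodes:
            raise KeyError(f"reference row {label!r} names undeclared node {node!r}")
        reference[node] = float(cell["after"])
        before[node] = float(cell["before"])
        if cell.get("perturbed"):
            perturbed.append(node)
    return Scenario(
        name=name,
        init=init,
        schedule=schedule,
        reference=reference,
        reference_before=before,
        perturbed_nodes=tuple(perturbed),
        description=entry.get("description", ""),
    )


def run_scenario(
    scn: Scenario,
    config: SimulationConfig | None = None,
    net: RegulatoryNetwork | None = None,
    settle_window: float = 50.0,
) -> ScenarioResult:
    """Simulate a scenario and extract endpoints, deviations and event times."""
    config = config or SimulationConfig()
    net = net or ip3r_reference_network()
    traj = simulate(net, scn.init, config, scn.schedule)
    finals, settled = steady_state_from_trajectory(traj, window=settle_window)
    deviations = {
        n: abs(finals.values[n] - ref) for n, ref in scn.reference.items()
    }
    events = {n: traj.first_crossing(n, 0.5) for n in net.nodes}
    return ScenarioResult(
        trajectory=traj,
        finals=finals,
        settled=settled,
        deviations=deviations,
        events=events,
    )


def run_all_scenarios(
    config: SimulationConfig | None = None,
    net: RegulatoryNetwork | None = None,
) -> dict[str, ScenarioResult]:
    net = net or ip3r_reference_network()
    return {
        name: run_scenario(build_scenario(name, net), config, net)
        for name in SCENARIO_NAMES
    }


def compare_to_reference(
    results: dict[str, ScenarioResult],
    tol_saturated: float = 0.05,
    tol_intermediate: float = 0.25,
) -> pd.DataFrame:
    """Per scenario x node comparison against the reference endpoints.

    Saturated references (exactly 0.0 or 1.0) are judged pass/fail at
    ``tol_saturated``.  Intermediate references are descriptive: the row
    records whether the computed endpoint falls in the same qualitative band
    and whether it is within ``tol_intermediate``, but ``pass`` is judged on
    saturated rows only (``band_match`` is informational).
    """
    if not results:
        raise ValueError("empty results map: run the four scenarios first")
    missing = [s for s in SCENARIO_NAMES if s not in results]
    if missing:
        raise ValueError(f"missing scenarios: {missing}")
    rows = []
    for name in SCENARIO_NAMES:
        scn = build_scenario(name)
        res = results[name]
        for node, ref in scn.reference.items():
            computed = res.finals.values[node]
            deviation = abs(computed - ref)
            saturated = ref in (0.0, 1.0)
            if saturated:
                ok = deviation <= tol_saturated
            else:
                ok = True  # descriptive only
            rows.append(
                {
                    "scenario": name,
                    "node": node,
                    "reference": ref,
                    "computed": round(computed, 6),
                    "deviation": round(deviation, 6),
                    "saturated": saturated,
                    "band_reference": activity_band(ref),
                    "band_computed": activity_band(computed),
                    "band_match": activity_band(ref) == activity_band(computed),
                    "within_tol_intermediate": deviation <= tol_intermediate,
                    "pass": bool(ok),
                }
            )
    return pd.DataFrame(rows)


def comparison_report_text(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`compare_to_reference`."""
    lines = []
    for scenario, grp in report.groupby("scenario", sort=False):
        lines.append(f"scenario: {scenario}")
        for _, r in grp.iterrows():
            kind = "saturated  " if r["saturated"] else "descriptive"
            verdict = "PASS" if r["pass"] else "FAIL"
            band = "" if r["saturated"] else (
                f"  band {r['band_reference']} vs {r['band_computed']}"
                f" ({'match' if r['band_match'] else 'differ'})"
            )
            lines.append(
                f"  {r['node']:<14} ref={r['reference']:<6} "
                f"got={r['computed']:<9.4f} dev={r['deviation']:<9.4f} "
                f"[{kind}] {verdict}{band}"
            )
        n_sat = int(grp["saturated"].sum())
        n_ok = int((grp["saturated"] & grp["pass"]).sum())
        lines.append(f"  saturated endpoints: {n_ok}/{n_sat} pass")
    total_sat = report[report["saturated"]]
    lines.append(
        f"overall: {int(total_sat['pass'].sum())}/{len(total_sat)} "
        "saturated endpoints pass"
    )
    return "\n".join(lines)
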