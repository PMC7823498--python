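# Methods

## Model

A signed regulatory network (nodes = gene products, edges = activation or
inhibition) is given discrete semantics by per-node Boolean rules and
continuous semantics by the normalized-HillCube construction:

```
dx_i/dt = τ · ( B̄_i( f(x_p1), …, f(x_pm) ) − x_i ),      x_i ∈ [0, 1]
```

`B̄_i` is the multilinear (BooleCube) interpolation of node *i*'s truth
table; `f(x) = x^h (1+k^h)/(x^h+k^h)` is the normalized Hill transfer on
each parent. The construction guarantees (i) exact agreement with the
Boolean rule on hypercube vertices, (ii) forward invariance of `[0,1]^N`,
and (iii) convergence of continuous steady states to Boolean fixed points as
`h → ∞`. The package verifies (i) exhaustively, (ii) by property tests, and
(iii) with a cross-oracle that compares thresholded continuous endpoints on
random acyclic networks (sources clamped to random Boolean vertices) against
exhaustive fixed-point enumeration of the discrete system.

Default Boolean rules follow the standard signed-network convention:
`OR(activators) AND NOT OR(inhibitors)`; only-inhibited nodes are
constitutively on unless repressed; parentless nodes decay unless clamped.
Custom truth tables can be attached per node.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| decay τ | 1.0 | 1/s | relaxation rate of every node |
| steepness h | 10 | — | Hill exponent; 10 is near-switch-like |
| threshold k | 0.5 | — | half-activation point, global (per-edge override supported) |
| dt | 0.05 | s | fixed RK4 step (Euler available for cross-checks) |
| t_end | 400 | s | horizon |

These are the standard SQUAD/Odefy-style settings of the case study; no
threshold is published, so the Odefy default k = 0.5 is used globally.

### Numerical choices

* Fixed-step RK4; activities hard-clipped to `[0,1]` after each step
  (guards against overshoot at high steepness). Halving dt moves the
  case-study endpoints by < 1e-10, far inside the 1e-4 convergence check.
* Clamped nodes are overridden *inside* the RHS at each integrator stage
  time (waveforms are therefore sampled stage-accurately) and report rate
  0; outside its window a node's ODE resumes from the clamped value.
* Clamp windows are tested with a 1e-9 relative tolerance so accumulated
  float error in `t` cannot drop the final step out of a window ending at
  `t_end`.
* `log`-space products compute the OR/AND-NOT BooleCube in two matvecs per
  RHS call; `1−f` is floored at 1e-300 so saturated inputs stay exact.
* Event time = first upward 0.5-crossing, linearly interpolated between
  steps. Steady-state detection: max per-node drift over the trailing 50 s
  below 1e-3.
* Exhaustive fixed-point enumeration refuses networks with more than 24
  free (non-clamped) nodes rather than silently sampling; enumeration is
  chunked (2^18 states at a time) to bound memory.
* Asynchronous (ARBN) updates draw the single updated node uniformly from
  one seeded generator owned by the run; topology is never randomized.

## The packaged IP3R network

The published edge list is not public; the fixture
(`src/brnsim/data/ip3r_network.tsv`, 16 nodes / 22 edges, one annotation
per edge) is reconstructed from the published figure and narrative:
Stimulus → IP3R → Ca²⁺ → {CALM → CAMK-II → Proliferation/Migration,
CaN → NFAT → Proliferation, Bcl-2}; Ca²⁺ and Bcl-2 repress BAD;
BAD → BAX → MOMP → Cyto.C → Apoptosis with Bcl-2 guarding BAX and MOMP;
Apoptosis shuts off Proliferation and Migration; an external Inhibitor
represses IP3R. Three modelling choices deserve note:

* **Stimulus.** The published table shows IP3R rising from 0 with no printed
  upstream activator; a constitutively clamped source node (ligand binding)
  supplies that drive in every scenario.
* **Irreversibility latch.** Cytochrome-c self-activates: once released it
  is not re-sequestered. This is what keeps Cyto.C and Apoptosis at 1.0 in
  the inhibitor scenario even though IP3R recovers after the inhibitor
  decays — exactly the endpoint pattern the published table reports
  (IP3R 0.949 *and* Apoptosis 1.0).
* **Bcl-2 guards.** All downstream nodes start at 0, so the only-inhibited
  BAD node would transiently fire at t≈1 s in *every* scenario (a start-up
  artifact of NOT gates). The canonical Bcl-2 ⊣ {BAD, BAX, MOMP} edges give
  the proliferative arm enough margin to win that race whenever calcium
  actually rises, without blocking genuine death signals.

## Scenarios

Defined in `src/brnsim/data/scenarios.yaml` (initial values, clamps,
waveforms, reference endpoints); the table's starred cells (perturbation
applied to IP3R and Ca²⁺) are modelled as deterministic sinusoidal clamps —
the original perturbation function is not recoverable, so the waveforms are
design choices documented in that file:

* **normal** — all nodes 0, stimulus on. Proliferative attractor; the death
  arm never crosses threshold.
* **normal_perturbed** — IP3R clamped to a slow sinusoid starting at the
  published 0.5 (rising), first sub-threshold dip at ≈103 s; Ca²⁺
  additionally carries a 40 s-period oscillation (range 0.55–0.95,
  engaging at t = 0.25 s so the recorded initial state equals the published
  before-column) released at 95 s. Apoptosis onsets at ≈110 s.
* **cancer** — IP3R clamped at 1.0 for the whole horizon. Proliferation,
  migration, CALM, CAMK-II saturate at 1.0; apoptosis stays 0.
* **cancer_inhibitor** — Inhibitor starts at 1.0 and decays freely
  (endpoint 0.0); IP3R follows a half-cosine 1.0 → 0 over [0, 140] s
  emulating the printed decline under the inhibitor, then is released and
  recovers. Apoptosis onsets at ≈76 s and latches.

The onset *ordering* (inhibitor before perturbation, matching the published
~85 s vs after-100 s) and the saturated endpoints are robust properties of
the reconstruction; the absolute onset times are carried by the waveform
periods/phases, because at τ = 1/s the network's intrinsic timescale is
~1 s (the original study's printed traces imply a much slower effective
timescale, e.g. calcium onset at ~30 s in the normal cell).

### Endpoint comparison policy

Saturated published endpoints (exactly 0.0/1.0) correspond to robust
attractors and are gated at |Δ| ≤ 0.05. Intermediate endpoints (0.945,
0.333, 0.892, …) depend on the authors' unpublished exact logic tables and
perturbation waveform; they are classified into the scaled-concentration
bands (inactive < 0.2, low 0.2–0.5, active > 0.5) and reported, never
gated, and no fitting of rules or thresholds toward them is performed.
17 of the 26 intermediate cells land in the published band; the mismatches
are concentrated where the latched death state overrides recovered upstream
signalling (CALM/CAMK-II in the inhibitor scenario) or where a node tracks
our particular waveform (Ca²⁺ after release).

## Synthetic networks

`random_brn` generates seed-reproducible signed networks: nodes in
topological order, every non-source node gets ≥1 parent from earlier nodes,
extra forward edges up to the expected density (default 1.5 edges/node,
30 % inhibitory, ~14 nodes — the shape of the case-study network), and
optional feedback edges in cyclic mode. The generator emulates the
*structural* properties the analysis assumes; it does not emulate scale-free
degree sequences, autoregulation motifs, or biologically meaningful logic,
so passing the steep-limit and boundedness suites on these instances shows
correctness of the semantics, not biological validity of any particular
reconstruction.

## Problem sizes

The default verification runs use: 4 scenarios × 8000 RK4 steps × 16 nodes
(~8 s total); 50 random 10-node acyclic instances at steepness 50 for the
steep-limit oracle (60 s horizon each); 100 random 10-node instances for
boundedness (5 s horizon). These sizes make the whole suite run in well
under a minute while the exhaustive Boolean oracles stay exact.

## Known limitations

* No stiff/adaptive solvers, delays, or stochastic (Langevin/Gillespie)
  semantics; the perturbation machinery is deterministic by design so the
  endpoint comparisons are reproducible.
* Dual-sign (source, target) edge pairs are rejected rather than merged.
* The fixture is a reconstruction: intermediate endpoint values and
  absolute event times inherit the uncertainty of the unpublished edge
  list and perturbation function (see the comparison policy above).
* Exhaustive attractor search covers fixed points (≤ 24 free nodes) and
  synchronous cycles (≤ 20 free nodes); no BDD/SCC symbolic methods.
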