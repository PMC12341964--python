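"""Ternary "chemokine switch" regulatory model and its MIG-knockout variant.

A small discrete-dynamics model of the IFNg -> (IP-10, MIG, MCP-1) -> IL-6
circuit in systemic inflammation. Each node takes a level in {0, 1, 2}
(absent / non-zero / elevated) — the rules distinguish "non-zero expression"
from "elevated", which a binary alphabet cannot express — plus a constant
binary injury input. The update is synchronous and deterministic: every node
has a {0, 2} target implied by the rules, and moves one level toward it per
step (a gradual mode that yields graded multi-step trajectories; an
"instant" mode that jumps straight to the target is available).

Full-variant rules:

* IFNg is elevated in the absence of severe injury and of MCP-1.
* MIG is induced by IFNg (a reconstruction — see ``MIG_RULE`` below).
* IP-10 is induced by IFNg and by its own positive feedback, but suppressed
  by non-zero MCP-1 or MIG.
* MCP-1 sustains itself as long as IP-10 is not elevated.
* IL-6 is induced by MCP-1 or MIG; elevated IL-6 is suppressed by elevated
  IP-10.

The MIG-knockout (KO) variant — the in-silico proxy for vagotomy, whose
hallmark is diminished systemic MIG — removes the MIG node and every rule
term that reads it: IL-6 induction and IP-10 suppression depend on MCP-1
alone. The KO state space (3^4 = 81) and rule set are strict reductions of
the full variant's (3^5 = 243).

Variability enters only through uniform random initial states; ensembles of
1,000 runs are summarised by per-node mean and variance per step, and an
exact enumeration over all initial states provides the ground-truth
expectation. The deterministic update also induces a transition-state
diagram (out-degree 1) whose size and fixed points quantify model
complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

LEVELS = (0, 1, 2)

KO_NODES = ("IFNg", "IP-10", "MCP-1", "IL-6")
FULL_NODES = ("IFNg", "IP-10", "MCP-1", "IL-6", "MIG")

VARIANTS = ("full", "mig_ko")

#: How the full variant drives MIG. Not pinned down by the mouse study; set
#: to IFNg-inducible (MIG is "monokine induced by gamma interferon").
MIG_RULE = "ifng_inducible"

#: Parse of "elevated in the absence of severe injury or MCP-1": conjunctive
#: reads it as (no injury AND no MCP-1); "disjunctive" as (no injury OR no
#: MCP-1).
IFNG_ABSENCE_MODE = "conjunctive"


def nodes_for(variant: str) -> tuple[str, ...]:
    if variant == "full":
        return FULL_NODES
    if variant == "mig_ko":
        return KO_NODES
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


@dataclass(frozen=True)
class SwitchState:
    """Levels of the switch nodes plus the constant injury input."""

    levels: tuple[int, ...]
    injury: int = 0
    variant: str = "mig_ko"

    def __post_init__(self):
        names = nodes_for(self.variant)
        if len(self.levels) != len(names):
            raise ValueError(
                f"{self.variant} variant has {len(names)} nodes, "
                f"got {len(self.levels)} levels"
            )
        if any(l not in LEVELS for l in self.levels):
            raise ValueError(f"levels must be in {LEVELS}, got {self.levels}")
        if self.injury not in (0, 1):
            raise ValueError(f"injury must be 0 or 1, got {self.injury}")

    def as_dict(self) -> dict:
        return dict(zip(nodes_for(self.variant), self.levels))


def _targets_array(
    levels: np.ndarray,
    injury: int,
    variant: str,
    ifng_absence_mode: str = IFNG_ABSENCE_MODE,
) -> np.ndarray:
    """Vectorised {0,2} targets for an (n_states, n_nodes) level array."""
    ifng = levels[:, 0]
    ip10 = levels[:, 1]
    mcp1 = levels[:, 2]
    il6 = levels[:, 3]
    if variant == "full":
        mig = levels[:, 4]
        suppressor = (mcp1 > 0) | (mig > 0)  # gates IP-10 off
        il6_inducer = (mcp1 > 0) | (mig > 0)
    elif variant == "mig_ko":
        suppressor = mcp1 > 0
        il6_inducer = mcp1 > 0
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")

    targets = np.zeros_like(levels)
    if ifng_absence_mode == "conjunctive":
        ifng_on = (injury == 0) & (mcp1 == 0)
    elif ifng_absence_mode == "disjunctive":
        ifng_on = (injury == 0) | (mcp1 == 0)
    else:
        raise ValueError(f"unknown ifng_absence_mode {ifng_absence_mode!r}")
    targets[:, 0] = np.where(ifng_on, 2, 0)
    # suppression dominates induction
    targets[:, 1] = np.where(suppressor, 0, np.where((ifng > 0) | (ip10 > 0), 2, 0))
    targets[:, 2] = np.where((mcp1 > 0) & (ip10 < 2), 2, 0)
    targets[:, 3] = np.where(
        (il6 == 2) & (ip10 == 2), 0, np.where(il6_inducer, 2, 0)
    )
    if variant == "full":
        if MIG_RULE == "ifng_inducible":
            targets[:, 4] = np.where(ifng > 0, 2, 0)
        else:  # constitutive off — effectively a second KO mode
            targets[:, 4] = 0
    return targets


def target_levels(state: SwitchState, variant: str | None = None) -> dict:
    """The {0, 2} target of every node given the current state."""
    variant = variant or state.variant
    levels = np.asarray([state.levels], dtype=int)
    t = _targets_array(levels, state.injury, variant)[0]
    return dict(zip(nodes_for(variant), (int(x) for x in t)))


def step(
    state: SwitchState,
    variant: str | None = None,
    mode: str = "gradual",
) -> SwitchState:
    """Advance one synchronous step.

    In "gradual" mode each node moves one level toward its target (or stays
    if already there); in "instant" mode it jumps to the target.
    """
    variant = variant or state.variant
    levels = np.asarray([state.levels], dtype=int)
    new = _step_array(levels, state.injury, variant, mode)[0]
    return SwitchState(levels=tuple(int(x) for x in new), injury=state.injury,
                       variant=variant)


def _step_array(levels, injury, variant, mode="gradual") -> np.ndarray:
    targets = _targets_array(levels, injury, variant)
    if mode == "gradual":
        return levels + np.sign(targets - levels)
    if mode == "instant":
        return targets
    raise ValueError(f"unknown update mode {mode!r}")


@dataclass
class EnsembleTrajectory:
    """Mean and variance per node per step across an ensemble of runs."""

    variant: str
    injury: int
    n_runs: int
    steps: int
    seed: int | None
    means: np.ndarray  # (steps + 1, n_nodes)
    variances: np.ndarray  # (steps + 1, n_nodes)

    @property
    def node_names(self) -> tuple[str, ...]:
        return nodes_for(self.variant)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.steps + 1):
            for j, node in enumerate(self.node_names):
                rows.append(
                    {"step": t, "node": node, "mean": self.means[t, j],
                     "variance": self.variances[t, j]}
                )
        return pd.DataFrame(rows)


def simulate_ensemble(
    variant: str,
    injury: int = 0,
    n_runs: int = 1000,
    steps: int = 10,
    seed: int | None = None,
    mode: str = "gradual",
) -> EnsembleTrajectory:
    """Monte-Carlo ensemble from uniform random initial states.

    Initial levels are i.i.d. uniform on {0, 1, 2} per node; the dynamics
    thereafter are deterministic, so the seed is the only randomness.
    Variance uses the population (ddof=0) convention.
    """
    if n_runs < 1 or steps < 1:
        raise ValueError("n_runs and steps must be >= 1")
    names = nodes_for(variant)
    rng = np.random.default_rng(seed)
    levels = rng.integers(0, 3, size=(n_runs, len(names)))
    means = np.empty((steps + 1, len(names)))
    variances = np.empty((steps + 1, len(names)))
    for t in range(steps + 1):
        means[t] = levels.mean(axis=0)
        variances[t] = levels.var(axis=0)
        if t < steps:
            levels = _step_array(levels, injury, variant, mode)
    return EnsembleTrajectory(
        variant=variant, injury=injury, n_runs=n_runs, steps=steps, seed=seed,
        means=means, variances=variances,
    )


def _all_states(n_nodes: int) -> np.ndarray:
    grids = np.meshgrid(*([np.array(LEVELS)] * n_nodes), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def exact_expectation(
    variant: str,
    injury: int = 0,
    steps: int = 10,
    mode: str = "gradual",
) -> EnsembleTrajectory:
    """Exact ensemble moments by enumerating every initial state.

    All |{0,1,2}|^n initial states (81 for the KO variant, 243 for the full
    one) are evolved deterministically with equal weight; the node count is
    capped at 8 to keep enumeration trivial.
    """
    names = nodes_for(variant)
    if len(names) > 8:
        raise ValueError("exact enumeration supports at most 8 nodes")
    levels = _all_states(len(names))
    means = np.empty((steps + 1, len(names)))
    variances = np.empty((steps + 1, len(names)))
    for t in range(steps + 1):
        means[t] = levels.mean(axis=0)
        variances[t] = levels.var(axis=0)
        if t < steps:
            levels = _step_array(levels, injury, variant, mode)
    return EnsembleTrajectory(
        variant=variant, injury=injury, n_runs=levels.shape[0], steps=steps,
        seed=None, means=means, variances=variances,
    )


@dataclass
class StateGraph:
    """Deterministic transition diagram over the full state space."""

    variant: str
    injury: int
    graph: nx.DiGraph
    fixed_points: list[tuple[int, ...]]
    complexity: dict  # n_states, n_transitions, n_fixed_points, n_successor_states

    def successor(self, levels: tuple[int, ...]) -> tuple[int, ...]:
        return next(iter(self.graph.successors(levels)))

    def path_from(self, levels: tuple[int, ...], steps: int) -> list[tuple[int, ...]]:
        path = [tuple(levels)]
        for _ in range(steps):
            path.append(self.successor(path[-1]))
        return path

    def to_dot(self) -> str:
        lines = [f"digraph switch_{self.variant} {{"]
        for s in self.graph.nodes:
            label = "".join(map(str, s))
            shape = ", shape=doublecircle" if s in set(self.fixed_points) else ""
            lines.append(f'  "{label}" [label="{label}"{shape}];')
        for a, b in self.graph.edges:
            lines.append(f'  "{"".join(map(str, a))}" -> "{"".join(map(str, b))}";')
        lines.append("}")
        return "\n".join(lines)


def build_transition_diagram(
    variant: str, injury: int = 0, mode: str = "gradual"
) -> StateGraph:
    """Map every state to its unique successor (out-degree exactly 1).

    Complexity summary: total states, distinct non-self transitions + self
    loops (= state count, one successor each), fixed points, and the number
    of distinct successor states (the image of the update map — states
    reachable after one step from anywhere).
    """
    names = nodes_for(variant)
    states = _all_states(len(names))
    succ = _step_array(states, injury, variant, mode)
    g = nx.DiGraph(variant=variant, injury=injury)
    fixed = []
    succ_set = set()
    for s, n in zip(map(tuple, states), map(tuple, succ)):
        s = tuple(int(x) for x in s)
        n = tuple(int(x) for x in n)
        g.add_edge(s, n)
        succ_set.add(n)
        if s == n:
            fixed.append(s)
    complexity = {
        "n_states": int(states.shape[0]),
        "n_transitions": g.number_of_edges(),
        "n_fixed_points": len(fixed),
        "n_successor_states": len(succ_set),
    }
    return StateGraph(variant=variant, injury=injury, graph=g,
                      fixed_points=fixed, complexity=complexity)
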