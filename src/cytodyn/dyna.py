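"""Dynamic network analysis (DyNA): intra-tissue mediator correlation graphs.

Within one tissue and condition, the nodes are mediators whose expression
changed significantly versus baseline (the t-test gate from
:mod:`cytodyn.group_stats`) and an edge joins two mediators whose Pearson
correlation across subjects exceeds a threshold in absolute value
(|r| > 0.90 by default; |r| >= 0.95 is flagged as the "strong" class, and
the LPS arms are typically run at |r| > 0.95). Negative correlations are
kept as signed edges: positive edges are read as propagation of tissue-local
inflammation, negative ones as concerted downregulation.

Network complexity is scored as edge density in percent,
100 * 2E / (N * (N - 1)); the score is used only comparatively, and any
metric monotone in the edge count at fixed node count preserves those
comparisons. A different callable can be plugged in via ``complexity_fn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .group_stats import ChangeGate


@dataclass
class DynaEdge:
    mediator_a: str
    mediator_b: str
    r: float
    strength: str  # "strong" (|r| >= strong_threshold) or "ordinary"
    sign: int  # +1 / -1

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.mediator_a, self.mediator_b)))


@dataclass
class DynaNetwork:
    """Correlation network over gated mediators for one tissue+condition."""

    tissue: str
    condition: str
    nodes: list[str]
    edges: list[DynaEdge]
    complexity: float = 0.0
    skipped_pairs: list = field(default_factory=list)  # < 3 complete pairs

    def edge_keys(self) -> set[tuple[str, str]]:
        return {e.key() for e in self.edges}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(tissue=self.tissue, condition=self.condition,
                     complexity=self.complexity)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.mediator_a, e.mediator_b, r=e.r, strength=e.strength,
                       sign=e.sign)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def dyna_complexity(n_nodes: int, n_edges: int) -> float:
    """Edge density as a percentage; 0 for networks with < 2 nodes."""
    if n_nodes < 2:
        return 0.0
    return 100.0 * 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def build_dyna(
    df: pd.DataFrame,
    tissue: str,
    condition: str,
    gates,
    r_threshold: float = 0.90,
    strong_threshold: float = 0.95,
    min_pairs: int = 3,
    complexity_fn=dyna_complexity,
) -> DynaNetwork:
    """Build the intra-tissue correlation network for one condition.

    ``gates`` is an iterable of :class:`~cytodyn.group_stats.ChangeGate`
    objects (only passing ones are used) or plain mediator names. Pearson r
    is computed on subjects observed for both mediators (pairwise-complete,
    since outlier filtering removes different subjects per mediator); pairs
    with fewer than ``min_pairs`` complete observations are skipped and
    listed in ``skipped_pairs``. Fewer than two gated mediators yields a
    valid empty network.
    """
    gates = list(gates)
    if gates and isinstance(gates[0], ChangeGate):
        nodes = sorted({g.mediator for g in gates if g.passes})
    else:
        nodes = sorted(set(gates))
    sub = df[
        (df["tissue"] == tissue)
        & (df["condition"] == condition)
        & (df["mediator"].isin(nodes))
    ]
    wide = sub.pivot_table(
        index="subject_id", columns="mediator", values="concentration",
        aggfunc="first",
    )

    edges, skipped = [], []
    for a, b in combinations(nodes, 2):
        if a not in wide.columns or b not in wide.columns:
            skipped.append(((a, b), "mediator unobserved"))
            continue
        pair = wide[[a, b]].dropna()
        if len(pair) < min_pairs:
            skipped.append(((a, b), f"only {len(pair)} complete pairs"))
            continue
        x = pair[a].to_numpy(dtype=float)
        y = pair[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append(((a, b), "zero variance"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) > r_threshold:
            edges.append(
                DynaEdge(
                    mediator_a=a,
                    mediator_b=b,
                    r=r,
                    strength="strong" if abs(r) >= strong_threshold else "ordinary",
                    sign=1 if r >= 0 else -1,
                )
            )
    net = DynaNetwork(
        tissue=tissue, condition=condition, nodes=nodes, edges=edges,
        skipped_pairs=skipped,
    )
    net.complexity = complexity_fn(len(net.nodes), len(net.edges))
    return net


def complexity_table(networks) -> pd.DataFrame:
    """Summary frame of complexity scores across networks."""
    return pd.DataFrame(
        [
            {
                "tissue": n.tissue,
                "condition": n.condition,
                "n_nodes": len(n.nodes),
                "n_edges": len(n.edges),
                "complexity": n.complexity,
            }
            for n in networks
        ]
    )
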