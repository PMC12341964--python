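"""Dynamic hypergraphs (DyHyp): cross-tissue mediator hyperedges.

Tissues are the nodes; a mediator becomes a signed hyperedge covering every
tissue where its rate of change is outstanding. Within one tissue, mediators
with positive velocity are pooled separately from those with negative
velocity; a mediator qualifies as a positive edge of that tissue when its
velocity exceeds mean + 1 SD of the increasing pool, and as a negative edge
when it falls below mean - 1 SD of the decreasing pool (strict inequalities,
sample SD, zero-velocity mediators in neither pool). Selection is run
independently per tissue; the hyperedge for a (mediator, sign) then covers
the union of qualifying tissues — including singletons, since a hyperedge may
surround a single node.

Per-node edge distribution (hyperedge membership counts split by sign) is the
hypergraph's complexity readout; the negative counts summarise pro-resolution
network complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TissueEdgeSet:
    """Mediators qualifying as signed edges in one tissue."""

    tissue: str
    condition: str
    positive_mediators: frozenset
    negative_mediators: frozenset
    thresholds: dict  # mean_pos, sd_pos, mean_neg, sd_neg (None if class < 2)


@dataclass
class Hyperedge:
    mediator: str
    sign: int  # +1 / -1
    tissues: frozenset

    def key(self) -> tuple[str, int]:
        return (self.mediator, self.sign)


@dataclass
class DyHypModel:
    """Cross-tissue hypergraph: tissue nodes, signed mediator hyperedges."""

    condition: str
    nodes: tuple[str, ...]
    hyperedges: list[Hyperedge]
    overlay: dict = field(default_factory=dict)  # tissue -> DynaNetwork export

    def to_json(self) -> dict:
        return {
            "condition": self.condition,
            "nodes": list(self.nodes),
            "hyperedges": [
                {
                    "mediator": h.mediator,
                    "sign": "+" if h.sign > 0 else "-",
                    "tissues": sorted(h.tissues),
                }
                for h in self.hyperedges
            ],
        }

    def incidence_matrix(self) -> pd.DataFrame:
        """0/1 node x hyperedge incidence, columns labelled mediator(sign)."""
        cols = {}
        for h in self.hyperedges:
            label = f"{h.mediator}({'+' if h.sign > 0 else '-'})"
            cols[label] = [1 if t in h.tissues else 0 for t in self.nodes]
        return pd.DataFrame(cols, index=list(self.nodes), dtype=int)


def _one_sd_cut(values: dict, sd_mode: str) -> tuple[set, float | None, float | None, set, float | None, float | None]:
    ddof = 1 if sd_mode == "sample" else 0
    pos = {m: v for m, v in values.items() if v > 0}
    neg = {m: v for m, v in values.items() if v < 0}
    mean_p = sd_p = mean_n = sd_n = None
    pos_sel, neg_sel = set(), set()
    if len(pos) >= 2:
        arr = np.fromiter(pos.values(), dtype=float)
        mean_p, sd_p = float(arr.mean()), float(arr.std(ddof=ddof))
        pos_sel = {m for m, v in pos.items() if v > mean_p + sd_p}
    if len(neg) >= 2:
        arr = np.fromiter(neg.values(), dtype=float)
        mean_n, sd_n = float(arr.mean()), float(arr.std(ddof=ddof))
        neg_sel = {m for m, v in neg.items() if v < mean_n - sd_n}
    return pos_sel, mean_p, sd_p, neg_sel, mean_n, sd_n


def select_edge_mediators(
    velocities,
    tissue: str | None = None,
    condition: str | None = None,
    sd_mode: str = "sample",
) -> TissueEdgeSet:
    """Apply the one-SD velocity rule within one tissue.

    ``velocities`` is either a mapping mediator -> velocity value or an
    iterable of :class:`~cytodyn.rate_of_change.Velocity` for one tissue (in
    which case tissue/condition are taken from them). Sign classes with fewer
    than two members yield no edges of that sign (their SD is undefined).
    ``sd_mode`` is "sample" (n-1 denominator, default) or "population".
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    if isinstance(velocities, dict):
        values = {m: float(v) for m, v in velocities.items()}
    else:
        velocities = list(velocities)
        tissues = {v.tissue for v in velocities}
        if len(tissues) > 1:
            raise ValueError(f"velocities span multiple tissues: {sorted(tissues)}")
        if tissues and tissue is None:
            tissue = tissues.pop()
        if condition is None and velocities:
            condition = "->".join(
                (velocities[0].from_condition, velocities[0].to_condition)
            )
        values = {v.mediator: v.value for v in velocities}

    pos_sel, mean_p, sd_p, neg_sel, mean_n, sd_n = _one_sd_cut(values, sd_mode)
    return TissueEdgeSet(
        tissue=tissue or "",
        condition=condition or "",
        positive_mediators=frozenset(pos_sel),
        negative_mediators=frozenset(neg_sel),
        thresholds={"mean_pos": mean_p, "sd_pos": sd_p,
                    "mean_neg": mean_n, "sd_neg": sd_n},
    )


def build_dyhyp(edge_sets, condition: str | None = None) -> DyHypModel:
    """Assemble tissue edge sets into one hypergraph.

    One hyperedge per (mediator, sign) covering every tissue where it
    qualified; singleton hyperedges are kept. All edge sets must carry the
    same condition label.
    """
    edge_sets = list(edge_sets)
    conditions = {s.condition for s in edge_sets}
    if condition is None:
        if len(conditions) > 1:
            raise ValueError(f"edge sets span multiple conditions: {sorted(conditions)}")
        condition = conditions.pop() if conditions else ""
    elif conditions - {condition}:
        raise ValueError(
            f"edge sets labelled {sorted(conditions)} do not match {condition!r}"
        )

    nodes = tuple(sorted({s.tissue for s in edge_sets}))
    membership: dict[tuple[str, int], set] = {}
    for s in edge_sets:
        for m in s.positive_mediators:
            membership.setdefault((m, 1), set()).add(s.tissue)
        for m in s.negative_mediators:
            membership.setdefault((m, -1), set()).add(s.tissue)
    hyperedges = [
        Hyperedge(mediator=m, sign=sign, tissues=frozenset(tissues))
        for (m, sign), tissues in sorted(membership.items())
    ]
    return DyHypModel(condition=condition, nodes=nodes, hyperedges=hyperedges)


def edge_distribution(model: DyHypModel) -> pd.DataFrame:
    """Per-node hyperedge membership counts, split by sign.

    The negative column summed over nodes is the pro-resolution complexity
    of the hypergraph.
    """
    rows = []
    for node in model.nodes:
        pos = sum(1 for h in model.hyperedges if h.sign > 0 and node in h.tissues)
        neg = sum(1 for h in model.hyperedges if h.sign < 0 and node in h.tissues)
        rows.append({"tissue": node, "positive": pos, "negative": neg,
                     "total": pos + neg})
    return pd.DataFrame(rows)


def overlay_dyna(model: DyHypModel, networks) -> dict:
    """Pair each hypergraph node with its intra-tissue DyNA network.

    ``networks`` is an iterable of :class:`~cytodyn.dyna.DynaNetwork`.
    Nodes without a matching network get an empty inset; networks for
    tissues absent from the model are ignored. Returns a JSON-ready dict and
    stores it on ``model.overlay``.
    """
    by_tissue = {}
    for net in networks:
        if net.tissue not in model.nodes:
            continue
        by_tissue[net.tissue] = net

    overlay = {}
    for node in model.nodes:
        net = by_tissue.get(node)
        if net is None:
            overlay[node] = {"nodes": [], "edges": []}
        else:
            overlay[node] = {
                "nodes": list(net.nodes),
                "edges": [
                    {"a": e.mediator_a, "b": e.mediator_b, "r": e.r,
                     "strength": e.strength, "sign": e.sign}
                    for e in net.edges
                ],
            }
    model.overlay = overlay
    return {"hypergraph": model.to_json(), "dyna": overlay}
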