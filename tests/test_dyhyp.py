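"""One-SD hyperedge qualification, hypergraph assembly and edge distribution."""

import numpy as np
import pytest

from cytodyn import (
    TissueEdgeSet,
    build_dyhyp,
    edge_distribution,
    overlay_dyna,
    select_edge_mediators,
)
from cytodyn.dyna import DynaEdge, DynaNetwork


def brute_force_edge_set(values, sd_mode="sample"):
    """Independent re-statement of the one-SD rule, straight from its definition."""
    ddof = 1 if sd_mode == "sample" else 0
    pos = {m: v for m, v in values.items() if v > 0}
    neg = {m: v for m, v in values.items() if v < 0}
    pos_sel = set()
    if len(pos) >= 2:
        arr = np.array(list(pos.values()))
        cut = arr.mean() + arr.std(ddof=ddof)
        pos_sel = {m for m, v in pos.items() if v > cut}
    neg_sel = set()
    if len(neg) >= 2:
        arr = np.array(list(neg.values()))
        cut = arr.mean() - arr.std(ddof=ddof)
        neg_sel = {m for m, v in neg.items() if v < cut}
    return pos_sel, neg_sel


def edge_set(tissue, pos=(), neg=(), condition="sham"):
    return TissueEdgeSet(
        tissue=tissue, condition=condition,
        positive_mediators=frozenset(pos), negative_mediators=frozenset(neg),
        thresholds={},
    )


class TestSelectEdgeMediators:
    def test_worked_example(self):
        # positive pool {10,1,1,1}: mean 3.25, sample SD 4.5 -> cut 7.75 -> {A}
        # negative pool {-12,-1}: mean -6.5, SD ~7.78 -> cut ~-14.28 -> {}
        rates = {"A": 10, "B": 1, "C": 1, "D": 1, "E": -12, "F": -1}
        es = select_edge_mediators(rates, tissue="spleen", condition="sham")
        assert es.positive_mediators == {"A"}
        assert es.negative_mediators == frozenset()
        assert es.thresholds["mean_pos"] == pytest.approx(3.25)
        assert es.thresholds["sd_pos"] == pytest.approx(4.5)
        assert es.thresholds["mean_neg"] == pytest.approx(-6.5)

    def test_equal_positive_rates_yield_no_edges(self):
        es = select_edge_mediators({m: 2.0 for m in "ABCD"}, tissue="gut")
        assert es.positive_mediators == frozenset()

    def test_single_member_class_yields_no_edge(self):
        es = select_edge_mediators({"A": 5.0, "B": -1.0, "C": -8.0}, tissue="gut")
        assert es.positive_mediators == frozenset()  # class size 1
        assert es.negative_mediators == frozenset()  # cut not exceeded

    def test_zero_velocity_in_neither_class(self):
        es = select_edge_mediators({"A": 0.0, "B": 0.0, "C": 1.0, "D": 10.0},
                                   tissue="gut")
        # positive pool is {C, D} only; neither exceeds mean + SD
        assert es.positive_mediators == frozenset()

    def test_population_sd_mode(self):
        rates = {"A": 10, "B": 1, "C": 1, "D": 1}
        es = select_edge_mediators(rates, tissue="gut", sd_mode="population")
        pos_expected, _ = brute_force_edge_set(rates, sd_mode="population")
        assert es.positive_mediators == pos_expected

    def test_oracle_equivalence_on_random_tables(self, rng):
        """500 random velocity tables match the brute-force rule exactly."""
        for _ in range(500):
            n_med = rng.integers(1, 11)
            values = {
                f"M{i}": float(v)
                for i, v in enumerate(rng.normal(0, 10, size=n_med))
            }
            # sprinkle exact zeros to exercise the exclusion rule
            for m in list(values)[:: 4]:
                if rng.random() < 0.3:
                    values[m] = 0.0
            es = select_edge_mediators(values, tissue="t")
            pos, neg = brute_force_edge_set(values)
            assert es.positive_mediators == pos
            assert es.negative_mediators == neg


class TestBuildDyhyp:
    def test_union_rule_spans_common_tissues(self):
        model = build_dyhyp([
            edge_set("spleen", neg=["MIG"]),
            edge_set("gut", neg=["MIG"]),
            edge_set("liver", neg=["MIG"]),
        ])
        assert len(model.hyperedges) == 1
        h = model.hyperedges[0]
        assert h.mediator == "MIG" and h.sign == -1
        assert h.tissues == {"spleen", "gut", "liver"}

    def test_singleton_hyperedge_kept(self):
        model = build_dyhyp([
            edge_set("plasma", pos=["KC"]),
            edge_set("liver"),
        ])
        assert [h.tissues for h in model.hyperedges] == [frozenset({"plasma"})]
        assert model.nodes == ("liver", "plasma")

    def test_opposite_signs_make_distinct_hyperedges(self):
        model = build_dyhyp([
            edge_set("lung", pos=["TNF"]),
            edge_set("gut", neg=["TNF"]),
        ])
        keys = {h.key() for h in model.hyperedges}
        assert keys == {("TNF", 1), ("TNF", -1)}

    def test_mismatched_condition_labels_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            build_dyhyp([
                edge_set("lung", pos=["TNF"], condition="sham"),
                edge_set("gut", pos=["TNF"], condition="vagotomy"),
            ])

    def test_nonqualifying_tissue_does_not_change_hyperedge(self):
        sets = [edge_set("spleen", pos=["MIG"]), edge_set("gut", pos=["MIG"])]
        before = {h.key(): h.tissues for h in build_dyhyp(sets).hyperedges}
        sets.append(edge_set("heart"))  # MIG does not qualify there
        after_model = build_dyhyp(sets)
        after = {h.key(): h.tissues for h in after_model.hyperedges}
        assert before == after
        assert "heart" in after_model.nodes

    def test_oracle_equivalence_full_rule_to_hyperedges(self, rng):
        """Velocity table -> edge sets -> hyperedges matches brute force end to end."""
        for _ in range(100):
            tissues = [f"t{i}" for i in range(rng.integers(2, 10))]
            mediators = [f"M{i}" for i in range(rng.integers(1, 11))]
            table = {
                t: {m: float(rng.normal(0, 5)) for m in mediators} for t in tissues
            }
            sets = [
                select_edge_mediators(vals, tissue=t, condition="x")
                for t, vals in table.items()
            ]
            model = build_dyhyp(sets)
            expected = {}
            for t, vals in table.items():
                pos, neg = brute_force_edge_set(vals)
                for m in pos:
                    expected.setdefault((m, 1), set()).add(t)
                for m in neg:
                    expected.setdefault((m, -1), set()).add(t)
            got = {h.key(): set(h.tissues) for h in model.hyperedges}
            assert got == expected


class TestEdgeDistributionAndOverlay:
    def test_empty_model_all_zero(self):
        model = build_dyhyp([edge_set("liver"), edge_set("gut")])
        dist = edge_distribution(model)
        assert (dist[["positive", "negative", "total"]] == 0).all().all()

    def test_counts_split_by_sign(self):
        model = build_dyhyp([
            edge_set("spleen", pos=["A", "B"], neg=["C"]),
            edge_set("gut", pos=["A"]),
        ])
        dist = edge_distribution(model).set_index("tissue")
        assert tuple(dist.loc["spleen"]) == (2, 1, 3)
        assert tuple(dist.loc["gut"]) == (1, 0, 1)

    def test_pro_resolution_complexity_monotone_in_negative_edges(self):
        base = [edge_set("spleen", neg=["A"]), edge_set("gut")]
        more = [edge_set("spleen", neg=["A", "B"]), edge_set("gut", neg=["B"])]
        s1 = edge_distribution(build_dyhyp(base))["negative"].sum()
        s2 = edge_distribution(build_dyhyp(more))["negative"].sum()
        assert s2 > s1

    def test_overlay_pairs_nodes_with_networks(self):
        model = build_dyhyp([edge_set("spleen", pos=["A"]), edge_set("gut")])
        net = DynaNetwork(
            tissue="spleen", condition="sham", nodes=["A", "B"],
            edges=[DynaEdge("A", "B", 0.97, "strong", 1)],
        )
        stray = DynaNetwork(tissue="brain", condition="sham", nodes=[], edges=[])
        combined = overlay_dyna(model, [net, stray])
        assert combined["dyna"]["spleen"]["edges"][0]["r"] == 0.97
        assert combined["dyna"]["gut"] == {"nodes": [], "edges": []}
        assert "brain" not in combined["dyna"]
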