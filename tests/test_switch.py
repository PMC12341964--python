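"""Ternary chemokine-switch dynamics: rules, ensembles, transition diagrams."""

import numpy as np
import pytest

from cytodyn import (
    SwitchState,
    build_transition_diagram,
    exact_expectation,
    simulate_ensemble,
    step,
    target_levels,
)
from cytodyn.switch import FULL_NODES, KO_NODES, nodes_for


def ko(levels, injury=0):
    return SwitchState(levels=tuple(levels), injury=injury, variant="mig_ko")


def full(levels, injury=0):
    return SwitchState(levels=tuple(levels), injury=injury, variant="full")


class TestTargetLevels:
    def test_ko_quiescent_state_drives_ifng_up(self):
        t = target_levels(ko([0, 0, 0, 0]))
        assert t == {"IFNg": 2, "IP-10": 0, "MCP-1": 0, "IL-6": 0}

    def test_ko_mcp1_suppresses_ifng_and_ip10_and_drives_il6(self):
        t = target_levels(ko([0, 0, 2, 0]))
        assert t == {"IFNg": 0, "IP-10": 0, "MCP-1": 2, "IL-6": 2}

    def test_full_mig_suppresses_ip10_without_mcp1(self):
        # IFNg=0, IP-10=2, MCP-1=0, IL-6=0, MIG=2
        t = target_levels(full([0, 2, 0, 0, 2]))
        assert t["IP-10"] == 0
        assert t["IL-6"] == 2  # MIG also induces IL-6 in the full variant

    def test_ko_has_no_mig_induction_path_for_il6(self):
        # same core levels, no MCP-1: IL-6 stays off in the KO variant
        t = target_levels(ko([0, 2, 0, 0]))
        assert t["IL-6"] == 0
        assert t["IP-10"] == 2  # self-feedback, no suppressor

    def test_injury_suppresses_ifng(self):
        assert target_levels(ko([0, 0, 0, 0], injury=1))["IFNg"] == 0

    def test_elevated_ip10_suppresses_elevated_il6(self):
        # MCP-1 active would otherwise keep IL-6 at 2
        t = target_levels(ko([0, 2, 2, 2]))
        assert t["IL-6"] == 0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            nodes_for("sham")


class TestStep:
    def test_fixed_point_is_unchanged(self):
        s = ko([2, 2, 0, 0])
        assert step(s) == s

    def test_gradual_trace_from_quiescent(self):
        s = ko([0, 0, 0, 0])
        s1 = step(s)
        assert s1.levels == (1, 0, 0, 0)
        s2 = step(s1)
        assert s2.levels == (2, 1, 0, 0)
        s3 = step(s2)
        assert s3.levels == (2, 2, 0, 0)
        assert step(s3) == s3  # fixed point

    def test_gradual_trace_reaches_mcp1_attractor(self):
        s = ko([0, 0, 2, 0])
        for _ in range(5):
            s = step(s)
        assert s.levels == (0, 0, 2, 2)
        assert step(s) == s

    def test_instant_mode_jumps_to_target(self):
        s = step(ko([0, 0, 0, 0]), mode="instant")
        assert s.levels == (2, 0, 0, 0)

    def test_levels_stay_in_alphabet(self, rng):
        for variant in ("mig_ko", "full"):
            n = len(nodes_for(variant))
            for _ in range(50):
                s = SwitchState(
                    levels=tuple(int(x) for x in rng.integers(0, 3, size=n)),
                    injury=int(rng.integers(0, 2)),
                    variant=variant,
                )
                for _ in range(12):
                    s = step(s)
                    assert all(l in (0, 1, 2) for l in s.levels)


class TestEnsembles:
    def test_seed_reproducibility(self):
        a = simulate_ensemble("full", n_runs=200, steps=5, seed=11)
        b = simulate_ensemble("full", n_runs=200, steps=5, seed=11)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.variances, b.variances)

    def test_initial_exact_mean_is_one(self):
        for variant in ("mig_ko", "full"):
            tr = exact_expectation(variant, injury=0, steps=1)
            np.testing.assert_allclose(tr.means[0], 1.0)
            np.testing.assert_allclose(tr.variances[0], 2.0 / 3.0)

    @pytest.mark.parametrize("variant", ["mig_ko", "full"])
    @pytest.mark.parametrize("injury", [0, 1])
    def test_ensemble_means_match_enumeration(self, variant, injury):
        """Monte-Carlo means stay within 3 SE of the exact enumeration."""
        n_runs, steps = 1000, 10
        sim = simulate_ensemble(variant, injury=injury, n_runs=n_runs,
                                steps=steps, seed=99)
        exact = exact_expectation(variant, injury=injury, steps=steps)
        se = np.sqrt(np.maximum(exact.variances, 1e-12) / n_runs)
        assert np.all(np.abs(sim.means - exact.means) <= 3 * se + 1e-12)

    def test_enumeration_matches_weighted_simulation_exactly(self):
        # a large ensemble initialised at every state once reproduces enumeration
        exact = exact_expectation("mig_ko", injury=0, steps=4)
        from cytodyn.switch import _all_states, _step_array

        levels = _all_states(4)
        for t in range(5):
            np.testing.assert_allclose(exact.means[t], levels.mean(axis=0))
            levels = _step_array(levels, 0, "mig_ko")

    def test_trajectory_frame_shape(self):
        tr = simulate_ensemble("mig_ko", n_runs=50, steps=3, seed=1)
        frame = tr.to_frame()
        assert len(frame) == 4 * len(KO_NODES)
        assert set(frame["node"]) == set(KO_NODES)


class TestTransitionDiagram:
    def test_every_state_has_out_degree_one(self):
        for variant in ("mig_ko", "full"):
            d = build_transition_diagram(variant)
            assert all(d.graph.out_degree(s) == 1 for s in d.graph.nodes)

    def test_known_fixed_points_of_ko(self):
        d = build_transition_diagram("mig_ko", injury=0)
        assert (0, 0, 2, 2) in d.fixed_points
        assert (2, 2, 0, 0) in d.fixed_points

    def test_fixed_points_agree_with_step_self_map(self):
        for variant in ("mig_ko", "full"):
            d = build_transition_diagram(variant, injury=0)
            from itertools import product

            expected = [
                s for s in product((0, 1, 2), repeat=len(nodes_for(variant)))
                if step(SwitchState(s, 0, variant)).levels == s
            ]
            assert sorted(d.fixed_points) == sorted(expected)

    def test_ko_diagram_is_smaller_than_full(self):
        ko_d = build_transition_diagram("mig_ko")
        full_d = build_transition_diagram("full")
        assert ko_d.complexity["n_states"] < full_d.complexity["n_states"]
        assert ko_d.complexity["n_transitions"] < full_d.complexity["n_transitions"]

    def test_simulated_path_equals_diagram_path(self, rng):
        d = build_transition_diagram("full", injury=0)
        for _ in range(20):
            start = tuple(int(x) for x in rng.integers(0, 3, size=len(FULL_NODES)))
            s = SwitchState(start, 0, "full")
            sim_path = [s.levels]
            for _ in range(8):
                s = step(s)
                sim_path.append(s.levels)
            assert sim_path == d.path_from(start, 8)

    def test_dot_export_mentions_fixed_points(self):
        d = build_transition_diagram("mig_ko")
        dot = d.to_dot()
        assert dot.startswith("digraph")
        assert dot.count("doublecircle") == len(d.fixed_points)
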