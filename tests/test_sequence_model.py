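"""Assembly, lazy cached evaluation and protocol checking."""

import numpy as np
import networkx as nx
import pytest

from mrforge._units import MS
from mrforge.hardware_events import ADCEvent, ExecutionBlock, build_block
from mrforge.sequence_model import (
    AssemblyError,
    Blueprint,
    BlueprintRegistry,
    Protocol,
    Rule,
    RULE_FUNCTIONS,
    assemble,
    check_protocol,
    const,
    dump_bundle,
    load_bundle,
    rule_function,
    solve_min_tr,
)


def _ident(x):
    return x


def _sub3(a, b, c):
    return a - b - c


RULE_FUNCTIONS.setdefault("test.ident", _ident)
RULE_FUNCTIONS.setdefault("test.sub3", _sub3)


def _simple_registry(n_lines=96, n_parts=120, block_ns=1_000_000):
    reg = BlueprintRegistry()
    reg.add(Blueprint("leaf", rules={"raw": const(ExecutionBlock(duration=block_ns))},
                      is_atomic=True))
    reg.add(Blueprint("line_loop", rules={"count": const(n_lines)},
                      children=(("tr", "leaf"),), is_loop=True))
    reg.add(Blueprint("part_loop", rules={"count": const(n_parts)},
                      children=(("line_loop", "line_loop"),), is_loop=True))
    reg.add(Blueprint("seq", children=(("part_loop", "part_loop"),)))
    return reg


class TestAssemble:
    def test_single_element_no_rules(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("solo"))
        tree, graph = assemble("solo", Protocol(), reg)
        assert len(list(tree.iter_elements())) == 1
        assert not [n for n in graph.node_ids() if not n.startswith(("protocol.", "limits."))]

    def test_nested_loop_visit_count(self):
        # 96 lines x 120 partitions as implied by a 192-matrix/PAT-2 phase
        # dimension and a 160x0.75 partition dimension
        tree, graph = assemble("seq", Protocol(), _simple_registry())
        assert tree.count_atomic_visits(graph) == 96 * 120 == 11_520

    def test_cycle_detection_names_members(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("cyc", rules={
            "a": Rule("test.ident", ("b",)),
            "b": Rule("test.ident", ("c",)),
            "c": Rule("test.ident", ("a",)),
        }))
        with pytest.raises(AssemblyError, match="cyc.a.*cyc.b.*cyc.c"):
            assemble("cyc", Protocol(), reg)

    def test_unknown_blueprint_reference(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("root", children=(("x", "missing"),)))
        with pytest.raises(AssemblyError, match="missing"):
            assemble("root", Protocol(), reg)

    def test_non_integer_loop_count_rejected(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("leaf", rules={"raw": const(ExecutionBlock(duration=10_000))},
                          is_atomic=True))
        reg.add(Blueprint("loop", rules={"count": const(2.5)},
                          children=(("x", "leaf"),), is_loop=True))
        with pytest.raises(AssemblyError, match="nonnegative integer"):
            assemble("loop", Protocol(), reg)

    def test_deterministic_traversal(self):
        reg = _simple_registry(3, 2)
        order1, order2 = [], []
        for order in (order1, order2):
            tree, graph = assemble("seq", Protocol(), reg)
            tree.traverse(graph, lambda el: order.append(el.path))
        assert order1 == order2 and len(order1) == 6

    def test_strategy_is_topological(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("m", rules={
            "a": const(1),
            "b": Rule("test.ident", ("a",)),
            "c": Rule("test.sub3", ("b", "a", "a")),
        }))
        _, graph = assemble("m", Protocol(), reg)
        strat = graph.strategy("m.c")
        assert strat.index("m.a") < strat.index("m.b") < strat.index("m.c")


class TestEvaluate:
    def test_constant_rule_single_evaluation(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("m", rules={"tr": const(10.0)}))
        _, graph = assemble("m", Protocol(), reg)
        assert graph.evaluate("m.tr") == 10.0
        assert graph.eval_counts == {"m.tr": 1}

    def test_echo_fill_arithmetic(self):
        # TE - rf_center - readout_center on toy values
        reg = BlueprintRegistry()
        reg.add(Blueprint("m", rules={
            "te": const(5.0),
            "rf_center": const(1.28),
            "readout_center": const(1.6),
            "fill": Rule("test.sub3", ("te", "rf_center", "readout_center")),
        }))
        _, graph = assemble("m", Protocol(), reg)
        assert graph.evaluate("m.fill") == pytest.approx(2.12)

    def test_independent_subgraph_not_evaluated(self):
        reg = BlueprintRegistry()
        reg.add(Blueprint("m", rules={
            "a1": const(1), "a2": Rule("test.ident", ("a1",)),
            "b1": const(2), "b2": Rule("test.ident", ("b1",)),
        }))
        _, graph = assemble("m", Protocol(), reg)
        graph.evaluate("m.a2")
        assert set(graph.eval_counts) == {"m.a1", "m.a2"}
        assert graph.total_evaluations == 2  # laziness: closure size only

    def test_error_carries_parameter_path(self):
        def boom():
            raise ValueError("bad rule")

        RULE_FUNCTIONS.setdefault("test.boom", lambda: boom())
        reg = BlueprintRegistry()
        reg.add(Blueprint("m", rules={
            "x": Rule("test.boom", ()),
            "y": Rule("test.ident", ("x",)),
        }))
        _, graph = assemble("m", Protocol(), reg)
        from mrforge.sequence_model import EvaluationError

        with pytest.raises(EvaluationError, match="m.y -> m.x"):
            graph.evaluate("m.y")


class TestUpdate:
    def test_leaf_invalidation_is_itself(self, toy_flash):
        _, graph = toy_flash
        dirty = graph.update("protocol.slice_offset_z", 1.0)
        # nothing was evaluated yet, but the set must contain the source
        assert "protocol.slice_offset_z" in dirty

    def test_dirty_set_equals_reachability(self, toy_flash):
        tree, graph = toy_flash
        tree.count_atomic_visits(graph)  # force full evaluation
        g = nx.DiGraph()
        for nid in graph.node_ids():
            g.add_node(nid)
        for nid in graph.node_ids():
            for dep in graph._nodes[nid].dep_ids:
                g.add_edge(dep, nid)
        expected = nx.descendants(g, "protocol.te") | {"protocol.te"}
        dirty = graph.update("protocol.te", 6.0)
        assert dirty == expected

    def test_reevaluation_after_no_change_costs_nothing(self, toy_flash):
        tree, graph = toy_flash
        for nid in graph.node_ids():
            if not graph.is_source(nid):
                graph.evaluate(nid)
        graph.reset_counters()
        for nid in graph.node_ids():
            if not graph.is_source(nid):
                graph.evaluate(nid)
        assert graph.total_evaluations == 0  # cache identity

    def test_update_unknown_parameter(self, toy_flash):
        _, graph = toy_flash
        with pytest.raises(KeyError):
            graph.update("protocol.nonexistent", 1)


class TestCacheOracle:
    def test_random_dags_match_naive_recomputation(self):
        """Seeded random update/evaluate interleavings agree bit-exactly
        with from-scratch recomputation on random DAGs."""
        rng = np.random.default_rng(2024)
        total_ops = 0
        for trial in range(25):
            n = int(rng.integers(5, 50))
            graph, naive = _random_dag(rng, n)
            sources = [i for i in range(n) if not naive["deps"][i]]
            for _ in range(40):
                total_ops += 1
                if rng.random() < 0.4 and sources:
                    src = int(rng.choice(sources))
                    val = float(rng.integers(-100, 100))
                    graph.update(f"n{src}", val)
                    naive["values"][src] = val
                else:
                    node = int(rng.integers(0, n))
                    got = graph.evaluate(f"n{node}")
                    want = _naive_eval(naive, node)
                    assert got == want  # bit-exact
        assert total_ops == 1000


def _random_dag(rng, n):
    from mrforge.sequence_model import ParameterGraph

    deps = {}
    for i in range(n):
        k = int(rng.integers(0, min(i, 3) + 1)) if i else 0
        deps[i] = sorted(rng.choice(i, size=k, replace=False)) if k else []
    values = {i: float(rng.integers(-100, 100)) for i in range(n) if not deps[i]}
    coefs = {i: [float(rng.integers(1, 5)) for _ in deps[i]] for i in range(n)}

    graph = ParameterGraph()
    for i in range(n):
        if not deps[i]:
            graph.add_source(f"n{i}", values[i])
        else:
            cs = coefs[i]
            graph.add_rule(f"n{i}",
                           (lambda *a, cs=cs: sum(c * v for c, v in zip(cs, a)) + 1.0),
                           [f"n{d}" for d in deps[i]])
    graph.finalize()
    return graph, {"deps": deps, "values": values, "coefs": coefs}


def _naive_eval(naive, i):
    if not naive["deps"][i]:
        return naive["values"][i]
    return sum(c * _naive_eval(naive, d)
               for c, d in zip(naive["coefs"][i], naive["deps"][i])) + 1.0


class TestCheckProtocol:
    def test_te_below_minimum_reports_computed_minimum(self):
        from mrforge.sequence_library import build_sequence

        proto = Protocol(tr=10, te=1.7, matrix=(16, 16, 1), fov=(256, 256, 8),
                         slice_thickness=5.0)
        tree, graph = build_sequence("flash", proto)
        report = check_protocol(tree, graph)
        timing = [v for v in report if v.kind == "timing"]
        assert timing and "TE below minimum" in timing[0].message
        assert timing[0].value > 1.7  # the computed feasible minimum

    def test_generous_protocol_is_clean(self, toy_flash):
        tree, graph = toy_flash
        assert check_protocol(tree, graph).ok

    def test_gradient_over_limit_names_event(self):
        from mrforge._units import HardwareLimits
        from mrforge.sequence_library import build_sequence

        proto = Protocol(tr=10, te=5, matrix=(16, 16, 1), fov=(256, 256, 8),
                         slice_thickness=5.0)
        limits = HardwareLimits(gmax=5.0, slew=150.0)
        tree, graph = build_sequence("flash", proto)  # designed for defaults
        report = check_protocol(tree, graph, limits)
        amp = [v for v in report if v.kind == "gradient_amplitude"]
        assert amp and "gradient" in amp[0].where

    def test_solve_handler_extends_tr(self):
        from mrforge.sequence_library import build_sequence

        proto = Protocol(tr=2.0, te=1.9, matrix=(16, 16, 1), fov=(256, 256, 8),
                         slice_thickness=5.0)
        tree, graph = build_sequence("flash", proto)
        with pytest.warns(UserWarning, match="extended to minimum"):
            new_tr = solve_min_tr(tree, graph)
        assert new_tr is not None and new_tr > 2.0
        assert not [v for v in check_protocol(tree, graph)
                    if v.kind == "timing" and "TR" in v.message]


class TestBundle:
    def test_bundle_roundtrip_lossless(self):
        from mrforge.sequence_library import sequence_definition

        root, reg = sequence_definition("flash")
        proto = Protocol(tr=10, te=5)
        doc = dump_bundle(root, reg, proto)
        root2, reg2, proto2 = load_bundle(doc)
        assert dump_bundle(root2, reg2, proto2) == doc
        assert proto2 == proto

    def test_bundle_has_required_sections(self):
        from mrforge.sequence_library import sequence_definition

        root, reg = sequence_definition("rare")
        doc = dump_bundle(root, reg, Protocol())
        assert set(doc) >= {"blueprints", "hierarchy", "parameter_rules", "protocol"}
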