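"""Expression evaluation, rule-file parsing, and update semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from disc1net.boolean_core import (
    BoolExpr,
    BooleanNetwork,
    ClampSet,
    NetworkState,
    RuleSyntaxError,
    async_step,
    evaluate,
    parse_rules,
    serialize_rules,
    sync_step,
)
from disc1net.packed import pack_network
from disc1net.synth import SyntheticNetworkSpec, random_network

from conftest import sync_oracle


# ---------------------------------------------------------------------------
# expressions
# ---------------------------------------------------------------------------

def test_evaluate_basic_truth_functions():
    assert evaluate(BoolExpr.not_(BoolExpr.const(True)), {}) is False
    e = BoolExpr.and_(BoolExpr.var("DISC1"), BoolExpr.not_(BoolExpr.var("GSK3B")))
    assert evaluate(e, {"DISC1": True, "GSK3B": False}) is True
    assert evaluate(e, {"DISC1": True, "GSK3B": True}) is False


def test_evaluate_unassigned_variable_raises():
    with pytest.raises(KeyError):
        evaluate(BoolExpr.var("X"), {})


_names = st.sampled_from(["a", "b", "c", "d"])


def _exprs(depth: int = 3):
    base = st.one_of(_names.map(BoolExpr.var), st.booleans().map(BoolExpr.const))
    return st.recursive(
        base,
        lambda kids: st.one_of(
            kids.map(BoolExpr.not_),
            st.lists(kids, min_size=2, max_size=3).map(lambda c: BoolExpr.and_(*c)),
            st.lists(kids, min_size=2, max_size=3).map(lambda c: BoolExpr.or_(*c)),
        ),
        max_leaves=8,
    )


@given(expr=_exprs(), bits=st.integers(min_value=0, max_value=15))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_evaluate_matches_python_eval_oracle(expr, bits):
    """The serialized expression, evaluated by Python itself, is the oracle."""
    env = {n: bool((bits >> i) & 1) for i, n in enumerate(["a", "b", "c", "d"])}
    py = str(expr).replace("!", " not ").replace("&", " and ").replace("|", " or ")
    assert evaluate(expr, env) == bool(eval(py, {}, env))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def test_parse_identity_rule():
    net = parse_rules("A = A\n")
    assert net.nodes == ("A",)
    s1 = NetworkState.from_dict(net, {"A": True})
    assert sync_step(net, s1) == s1


def test_parse_negation_rule():
    net = parse_rules("GSK3B = !DISC1\nDISC1 = DISC1\n")
    state = NetworkState.from_dict(net, {"GSK3B": False, "DISC1": False})
    nxt = sync_step(net, state)
    assert nxt["GSK3B"] is True and nxt["DISC1"] is False


@pytest.mark.parametrize(
    "text, fragment",
    [
        ("A = \n", "line 1"),
        ("A = B |\nB = A\n", "line 1"),
        ("A = A\nA = !A\n", "duplicate"),
        ("A = B\n", "undeclared"),
        ("A = (B\nB = 1\n", "unexpected end"),
    ],
)
def test_parse_errors_carry_line_and_reason(text, fragment):
    with pytest.raises(RuleSyntaxError, match=fragment):
        parse_rules(text)


def test_comments_and_precedence():
    net = parse_rules("# header\nA = !B & C | D  # trailing\nB=0\nC = 1\nD = 0\n")
    # ! binds tighter than &, & tighter than |
    state = NetworkState.from_dict(net, {"A": False, "B": False, "C": True, "D": False})
    assert sync_step(net, state)["A"] is True


@pytest.mark.parametrize("seed", range(6))
def test_parse_serialize_roundtrip_on_random_networks(seed):
    """serialize∘parse preserves node order and rule semantics (truth tables)."""
    net = random_network(SyntheticNetworkSpec(n_nodes=10, max_in_degree=3, seed=seed))
    text = serialize_rules(net)
    again = parse_rules(text)
    assert again.nodes == net.nodes
    p1, p2 = pack_network(net), pack_network(again)
    assert np.array_equal(p1.tables, p2.tables)
    assert np.array_equal(p1.reg_idx, p1.reg_idx)
    assert serialize_rules(again) == text


def test_derived_edges_match_rule_variables():
    net = parse_rules("A = B & !C\nB = A\nC = 1\n")
    assert net.edges == {("B", "A"), ("C", "A"), ("A", "B")}
    assert set(net.to_digraph().edges) == net.edges


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

@given(bits=st.integers(min_value=0, max_value=(1 << 20) - 1))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bitmask_roundtrip_bijection(bits):
    nodes = tuple(f"n{i}" for i in range(20))
    net = BooleanNetwork(nodes, {n: BoolExpr.var(n) for n in nodes})
    state = NetworkState.from_int(net, bits)
    assert state.to_int() == bits
    assert NetworkState.from_dict(net, state.as_dict()).to_int() == bits


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(4))
def test_sync_step_matches_componentwise_oracle(seed):
    net = random_network(SyntheticNetworkSpec(n_nodes=8, max_in_degree=3, seed=seed))
    rng = np.random.default_rng(seed)
    for bits in rng.integers(0, 1 << net.n, size=20):
        state = NetworkState.from_int(net, int(bits))
        assert sync_step(net, state) == sync_oracle(net, state)


def test_async_two_node_flip_flop_successors():
    """From (1,1) in A=!B, B=!A exactly (0,1) and (1,0) occur, each ~1/2."""
    net = parse_rules("A = !B\nB = !A\n")
    start = NetworkState.from_dict(net, {"A": True, "B": True})
    rng = np.random.default_rng(7)
    seen = {"01": 0, "10": 0}
    for _ in range(2000):
        nxt = async_step(net, start, rng=rng)
        seen[nxt.bitstring()] += 1
    assert seen["01"] + seen["10"] == 2000
    assert abs(seen["01"] - 1000) < 150  # ~5 sigma for p=1/2


@pytest.mark.parametrize("seed", range(3))
def test_async_successor_distribution_is_uniform_choice(seed):
    """Empirical successors match enumerating one update per node."""
    net = random_network(SyntheticNetworkSpec(n_nodes=3, max_in_degree=2, seed=seed))
    rng = np.random.default_rng(seed + 100)
    state = NetworkState.from_int(net, int(rng.integers(0, 8)))
    from disc1net.boolean_core import evaluate
    expected = {
        state.with_values({v: evaluate(net.rules[v], state)}).to_int()
        for v in net.nodes
    }
    seen = {async_step(net, state, rng=rng).to_int() for _ in range(500)}
    assert seen <= expected
    assert seen == expected  # 500 draws over 3 nodes: miss probability ~3*(2/3)^500


def test_fixed_point_invariant_under_both_schemes(migration_net):
    from disc1net.attractors import enumerate_fixed_points
    fp = enumerate_fixed_points(migration_net)[0]
    rng = np.random.default_rng(0)
    assert sync_step(migration_net, fp) == fp
    for _ in range(50):
        assert async_step(migration_net, fp, rng=rng) == fp


def test_clamping_overrides_rules():
    net = parse_rules("A = !A\nB = A\n")
    clamps = ClampSet.ko("A")
    state = NetworkState.from_dict(net, {"A": True, "B": True})
    rng = np.random.default_rng(1)
    for _ in range(20):
        state = async_step(net, state, clamps, rng)
        assert state["A"] is False
    assert sync_step(net, state, clamps)["A"] is False


def test_all_nodes_clamped_returns_state_unchanged():
    net = parse_rules("A = !A\n")
    state = NetworkState.from_dict(net, {"A": True})
    out = async_step(net, state, ClampSet.oe("A"), np.random.default_rng(0))
    assert out == state


def test_clamp_of_unknown_node_rejected():
    net = parse_rules("A = A\n")
    with pytest.raises(ValueError, match="not in network"):
        sync_step(net, NetworkState.from_int(net, 0), ClampSet.oe("Z"))
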