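"""Fixed-point identification, shuffle robustness, and FM classification."""

import numpy as np
import pytest

from disc1net.attractors import (
    RobustnessConfig,
    classify_attractor_fms,
    enumerate_fixed_points,
    make_records,
    random_walk_attractors,
    robustness_counts,
    shuffle_perturb,
    write_attractor_report,
)
from disc1net.boolean_core import NetworkState, parse_rules
from disc1net.packed import pack_network
from disc1net.synth import SyntheticNetworkSpec, random_network

from conftest import brute_force_fixed_points


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_identity_network_has_both_fixed_points():
    net = parse_rules("A = A\n")
    fps = enumerate_fixed_points(net)
    assert [s.to_int() for s in fps] == [0, 1]


@pytest.mark.parametrize("seed", range(5))
def test_enumeration_matches_brute_force_oracle(seed):
    net = random_network(SyntheticNetworkSpec(n_nodes=10, max_in_degree=3, seed=seed))
    fast = enumerate_fixed_points(net)
    slow = brute_force_fixed_points(net)
    assert [s.to_int() for s in fast] == [s.to_int() for s in slow]


def test_enumeration_refuses_oversized_networks():
    nodes = tuple(f"n{i}" for i in range(25))
    net = parse_rules("".join(f"{n} = {n}\n" for n in nodes))
    with pytest.raises(ValueError, match="exceeds"):
        enumerate_fixed_points(net)


@pytest.mark.parametrize("seed", range(4))
def test_fixed_points_are_update_scheme_invariant(seed):
    """sync fixed point ⇔ no single-node update changes the state (n ≤ 12)."""
    from disc1net.boolean_core import evaluate
    net = random_network(SyntheticNetworkSpec(n_nodes=8, max_in_degree=3, seed=seed + 50))
    fps = {s.to_int() for s in enumerate_fixed_points(net)}
    for bits in range(1 << net.n):
        state = NetworkState.from_int(net, bits)
        async_stable = all(
            evaluate(net.rules[v], state) == state[v] for v in net.nodes
        )
        assert async_stable == (bits in fps)


# ---------------------------------------------------------------------------
# random walks
# ---------------------------------------------------------------------------

def test_walk_finds_single_global_attractor():
    # contracting network: every state flows to all-OFF
    net = parse_rules("A = 0\nB = A\nC = A & B\n")
    found = random_walk_attractors(net, n_starts=50, walk_length=60, seed=3)
    assert {s.to_int() for s in found} == {0}


@pytest.mark.parametrize("seed", range(4))
def test_walk_results_subset_of_exhaustive(seed):
    net = random_network(SyntheticNetworkSpec(n_nodes=9, max_in_degree=3, seed=seed))
    exact = {s.to_int() for s in enumerate_fixed_points(net)}
    found = random_walk_attractors(net, n_starts=200, walk_length=300, seed=seed)
    assert {s.to_int() for s in found} <= exact


def test_walk_recovers_all_migration_attractors(migration_net):
    exact = {s.to_int() for s in enumerate_fixed_points(migration_net)}
    found = random_walk_attractors(migration_net, n_starts=10_000, walk_length=1000, seed=11)
    assert {s.to_int() for s in found} == exact


# ---------------------------------------------------------------------------
# shuffle perturbation
# ---------------------------------------------------------------------------

def test_shuffle_preserves_structure_and_output_multiset(migration_net):
    perturbed = shuffle_perturb(migration_net, seed=5, rules="all")
    assert perturbed.nodes == migration_net.nodes
    p0, p1 = pack_network(migration_net), pack_network(perturbed)
    assert np.array_equal(p0.reg_idx, p1.reg_idx)
    assert np.array_equal(p0.reg_len, p1.reg_len)
    for v in migration_net.nodes:
        assert sorted(p0.table_of(v)) == sorted(p1.table_of(v))
    # original untouched
    assert np.array_equal(pack_network(migration_net).tables, p0.tables)


def test_single_input_rule_shuffles_to_identity_or_negation():
    net = parse_rules("A = B\nB = B\n")
    seen = set()
    for seed in range(40):
        tab = pack_network(shuffle_perturb(net, seed, rules="all")).table_of("A")
        seen.add(tuple(tab))
    assert seen == {(0, 1), (1, 0)}


def test_shuffle_deterministic_and_seed_sensitive(migration_net):
    a = shuffle_perturb(migration_net, seed=9)
    b = shuffle_perturb(migration_net, seed=9)
    assert np.array_equal(pack_network(a).tables, pack_network(b).tables)
    others = [shuffle_perturb(migration_net, seed=s) for s in range(10, 16)]
    assert any(
        not np.array_equal(pack_network(a).tables, pack_network(o).tables)
        for o in others
    )


def test_default_shuffle_perturbs_exactly_one_rule(migration_net):
    p0 = pack_network(migration_net)
    changed_counts = []
    for seed in range(10):
        p1 = pack_network(shuffle_perturb(migration_net, seed))
        changed = sum(
            not np.array_equal(p0.table_of(v), p1.table_of(v))
            for v in migration_net.nodes
        )
        changed_counts.append(changed)
    assert all(c <= 1 for c in changed_counts)
    assert any(c == 1 for c in changed_counts)


# ---------------------------------------------------------------------------
# robustness counts
# ---------------------------------------------------------------------------

def test_zero_perturbations_give_zero_counts(migration_net):
    fps = enumerate_fixed_points(migration_net)
    counts = robustness_counts(migration_net, fps, RobustnessConfig(n_perturb=0))
    assert all(c == 0 for c in counts.values())


def test_counts_bounded_and_reproducible(migration_net):
    fps = enumerate_fixed_points(migration_net)
    cfg = RobustnessConfig(n_perturb=50, walk_starts=30, walk_length=200, seed=4)
    c1 = robustness_counts(migration_net, fps, cfg)
    c2 = robustness_counts(migration_net, fps, cfg)
    assert c1 == c2
    assert all(0 <= v <= 50 for v in c1.values())


def test_non_fixed_point_attractor_rejected(migration_net):
    bogus = NetworkState.from_int(migration_net, 1)
    with pytest.raises(ValueError, match="not a fixed point"):
        robustness_counts(migration_net, [bogus], RobustnessConfig(n_perturb=1))


# ---------------------------------------------------------------------------
# FM classification
# ---------------------------------------------------------------------------

def test_classification_reproduces_all_reference_rows(migration_net, table1_rows):
    """Exhaustive 18-row check of the FM facilitation classifier."""
    for row in table1_rows:
        state = NetworkState.from_on_set(migration_net, set(row.on_short_names))
        assert classify_attractor_fms(state) == row.facilitated_fms, f"row {row.row}"


def test_classifier_rejects_foreign_states():
    net = parse_rules("A = A\n")
    with pytest.raises(ValueError, match="lacks"):
        classify_attractor_fms(NetworkState.from_int(net, 0))


def test_attractor_report_layout(migration_net):
    fps = enumerate_fixed_points(migration_net)
    text = write_attractor_report(make_records(fps), header="probe")
    lines = text.strip().splitlines()
    assert lines[0] == "# probe"
    assert lines[1].split("\t") == ["bitstring", "on_nodes", "facilitated_fms", "robustness_count"]
    assert len(lines) == 2 + len(fps)
    assert all(len(l.split("\t")) == 4 for l in lines[2:])
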