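import itertools

import pytest

from disc1net.boolean_core import BooleanNetwork, NetworkState, evaluate, sync_step
from disc1net.model import load_fm_fixtures, load_migration_network, load_table1_reference


@pytest.fixture(scope="session")
def migration_net() -> BooleanNetwork:
    return load_migration_network()


@pytest.fixture(scope="session")
def table1_rows():
    return load_table1_reference()


@pytest.fixture(scope="session")
def fm_modules():
    return load_fm_fixtures()


def brute_force_fixed_points(net: BooleanNetwork) -> list[NetworkState]:
    """Independent oracle: test f(s)=s for every state via pure per-node evaluation."""
    out = []
    for bits in range(1 << net.n):
        state = NetworkState.from_int(net, bits)
        if all(evaluate(net.rules[v], state) == state[v] for v in net.nodes):
            out.append(state)
    return out


def sync_oracle(net: BooleanNetwork, state: NetworkState) -> NetworkState:
    """Componentwise synchronous successor, built without sync_step."""
    return NetworkState.from_dict(
        net, {v: evaluate(net.rules[v], state) for v in net.nodes}
    )


def all_states(net: BooleanNetwork):
    for bits in range(1 << net.n):
        yield NetworkState.from_int(net, bits)
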