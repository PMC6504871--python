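"""Steady-state attractor identification, robustness, and FM classification.

"Attractor" here means a fixed point: a state mapped to itself by every update,
hence invariant under both synchronous and asynchronous schemes.  Fixed points
are found two ways — exhaustively (every state of the 2^n state space tested
against f(s)=s) and by asynchronous random walks, whose yield must be a subset
of the exhaustive set.  Complex (cyclic) asynchronous attractors are detected
only as walk non-convergence and are not reported.

Robustness follows the shuffle protocol: in each of ``n_perturb`` perturbed
networks, one randomly chosen node's truth-table output column is randomly
permuted (wiring preserved), random walks are run on the perturbed network,
and an original
attractor is counted as occurring there iff some walk terminates in it *and*
it verifies as a fixed point of the perturbed network.

FM classification maps each steady state of the 19-protein migration network to
the subset of the eight functional modules (FM1–FM8) whose mode of migration it
facilitates; an empty subset means migration is inhibited in all modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolean_core import BooleanNetwork, NetworkState
from .packed import (
    PackedNetwork,
    fixed_point_bitmasks,
    pack_network,
    verify_fixed,
    walk_terminal_states,
)

__all__ = [
    "AttractorRecord",
    "RobustnessConfig",
    "enumerate_fixed_points",
    "random_walk_attractors",
    "shuffle_perturb",
    "robustness_counts",
    "classify_attractor_fms",
    "write_attractor_report",
]

ALL_FMS = tuple(f"FM{i}" for i in range(1, 9))

#: Proteins that must be ON in every migration-facilitating steady state.
CORE_FACILITATORS = frozenset(
    {"DISC1", "NDEL1", "LIS1", "CC141", "MYH2", "ACTB", "AKT1", "GRDN"}
)
#: Proteins that must be OFF in every migration-facilitating steady state.
CORE_INHIBITORS = frozenset({"GSK3B", "SOX10", "FOXD3", "RHEB"})
#: Additional proteins each FM requires ON, beyond the core set.
FM_EXTRA_REQUIREMENTS: dict[str, frozenset[str]] = {
    "FM1": frozenset({"PCM1", "BBS4"}),
    "FM2": frozenset({"ZN365"}),
    "FM3": frozenset({"CDK5", "DIXC1"}),
    "FM4": frozenset({"A4", "DAB1"}),
    "FM5": frozenset(),
    "FM6": frozenset(),
    "FM7": frozenset(),
    "FM8": frozenset(),
}


@dataclass(frozen=True)
class AttractorRecord:
    """A steady state with its FM facilitation and robustness count."""

    state: NetworkState
    facilitated_fms: tuple[str, ...]
    robustness_count: int = 0

    @property
    def inhibited_all(self) -> bool:
        return not self.facilitated_fms


@dataclass(frozen=True)
class RobustnessConfig:
    """Parameters of the shuffle-perturbation robustness study."""

    n_perturb: int = 3000
    walk_starts: int = 100
    walk_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_perturb < 0 or self.walk_starts < 1 or self.walk_length < 1:
            raise ValueError("robustness parameters must be positive")


# ---------------------------------------------------------------------------
# Fixed-point identification
# ---------------------------------------------------------------------------

def enumerate_fixed_points(net: BooleanNetwork) -> list[NetworkState]:
    """All fixed points of ``net``, complete, in ascending bitmask order.

    Exhaustive over the full 2^n state space; refuses networks above the
    enumeration limit (24 nodes).
    """
    packed = pack_network(net)
    masks = fixed_point_bitmasks(packed)
    return [NetworkState.from_int(net, int(m)) for m in masks]


def random_walk_attractors(
    net: BooleanNetwork,
    n_starts: int,
    walk_length: int,
    seed: int,
    packed: PackedNetwork | None = None,
) -> set[NetworkState]:
    """Fixed points found by asynchronous random walks from random initial states.

    Each walk applies up to ``walk_length`` single-node asynchronous updates;
    the terminal state is reported iff it verifies as a fixed point.  The
    result is always a subset of :func:`enumerate_fixed_points`.
    """
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    if packed is None:
        packed = pack_network(net)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 1 << net.n, size=n_starts, dtype=np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    terminals = walk_terminal_states(packed, starts, walk_length, kernel_seed)
    out: set[NetworkState] = set()
    for t in np.unique(terminals):
        if verify_fixed(packed, int(t)):
            out.add(NetworkState.from_int(net, int(t)))
    return out


# ---------------------------------------------------------------------------
# Shuffle perturbation and robustness
# ---------------------------------------------------------------------------

def shuffle_perturb(
    net: BooleanNetwork, seed: int, rules: str = "one"
) -> BooleanNetwork:
    """Perturbed copy of ``net`` with truth-table output columns randomly permuted.

    ``rules="one"`` (the robustness protocol) permutes the output column of a
    single uniformly chosen node's transition function; ``rules="all"``
    permutes every rule's column.  Node list and wiring (regulator sets) are
    preserved.  The original network is unmodified; the same seed reproduces
    the same perturbation.
    """
    rng = np.random.default_rng(seed)
    packed = pack_network(net)
    if rules == "one":
        chosen = [int(rng.integers(net.n))]
    elif rules == "all":
        chosen = None
    else:
        raise ValueError("rules must be 'one' or 'all'")
    return packed.shuffled(rng, chosen).to_network()


def robustness_counts(
    net: BooleanNetwork,
    attractors: list[NetworkState],
    cfg: RobustnessConfig,
) -> dict[NetworkState, int]:
    """Occurrences of each original attractor across shuffle-perturbed networks.

    For each of ``cfg.n_perturb`` perturbed networks, seeded asynchronous walks
    are run from ``cfg.walk_starts`` random initial states; an attractor is
    counted for that network iff at least one walk terminates in it and it is a
    fixed point of the perturbed network.  Counts lie in [0, n_perturb] and are
    reproducible under a fixed seed.
    """
    packed = pack_network(net)
    for a in attractors:
        if not verify_fixed(packed, a.to_int()):
            raise ValueError(f"{a!r} is not a fixed point of the network")
    attr_masks = np.array([a.to_int() for a in attractors], dtype=np.int64)
    counts = np.zeros(len(attractors), dtype=np.int64)
    master = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_perturb):
        shuffle_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        chosen = [int(shuffle_rng.integers(net.n))]
        perturbed = packed.shuffled(shuffle_rng, chosen)
        starts = master.integers(0, 1 << net.n, size=cfg.walk_starts, dtype=np.int64)
        kernel_seed = int(master.integers(0, 2**31 - 1))
        terminals = walk_terminal_states(perturbed, starts, cfg.walk_length, kernel_seed)
        hit = np.isin(attr_masks, terminals)
        for j in np.nonzero(hit)[0]:
            if verify_fixed(perturbed, int(attr_masks[j])):
                counts[j] += 1
    return {a: int(c) for a, c in zip(attractors, counts)}


# ---------------------------------------------------------------------------
# FM classification
# ---------------------------------------------------------------------------

def classify_attractor_fms(state: NetworkState) -> tuple[str, ...]:
    """Functional modules whose migration mode a steady state facilitates.

    An FM is facilitated iff the core facilitatory proteins are all ON, the
    core inhibitory proteins are all OFF, and the FM's additional requirement
    (e.g. PCM1 and BBS4 for FM1) holds.  Returns a possibly empty tuple in
    FM1..FM8 order; empty means migration is inhibited in all modules.
    """
    missing = (CORE_FACILITATORS | CORE_INHIBITORS) - set(state.nodes)
    if missing:
        raise ValueError(f"state lacks migration-network nodes: {sorted(missing)}")
    on = state.on_set()
    if not CORE_FACILITATORS <= on or CORE_INHIBITORS & on:
        return ()
    return tuple(
        fm for fm in ALL_FMS
        if FM_EXTRA_REQUIREMENTS[fm] <= on
    )


def make_records(
    attractors: list[NetworkState],
    counts: dict[NetworkState, int] | None = None,
) -> list[AttractorRecord]:
    counts = counts or {}
    return [
        AttractorRecord(a, classify_attractor_fms(a), counts.get(a, 0))
        for a in attractors
    ]


def write_attractor_report(records: list[AttractorRecord], header: str = "") -> str:
    """TSV report: bitstring, ON-node list, facilitated FMs, robustness count."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("bitstring\ton_nodes\tfacilitated_fms\trobustness_count")
    for r in records:
        on = ",".join(v for v in r.state.nodes if r.state[v])
        fms = ",".join(r.facilitated_fms) if r.facilitated_fms else "-"
        lines.append(f"{r.state.bitstring()}\t{on}\t{fms}\t{r.robustness_count}")
    return "\n".join(lines) + "\n"
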