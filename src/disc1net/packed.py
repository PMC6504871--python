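"""Packed truth-table form of a Boolean network, plus fast simulation kernels.

Every rule is flattened to a local truth table over its regulators (ordered by
network node order): node ``v`` with regulators ``r_0 < r_1 < ... < r_{k-1}``
stores a table of 2^k output bits, indexed by ``sum(X_{r_j} << j)``.  This form
makes three things cheap:

* exhaustive fixed-point enumeration over all 2^n states (vectorized numpy
  gathers, chunked to bound memory);
* asynchronous random walks and ensemble simulations (numba-jitted kernels over
  integer bitmask states);
* shuffle perturbation — a random permutation of a rule's output column — which
  is exact on a table and awkward on an expression tree.

States are int64 bitmasks with node ``i`` at bit ``i`` (networks up to 63
nodes; exhaustive enumeration is separately capped much lower).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from numba import njit

from .boolean_core import BoolExpr, BooleanNetwork, evaluate

__all__ = ["PackedNetwork", "pack_network", "table_to_expr"]

MAX_EXHAUSTIVE_NODES = 24


@dataclass(frozen=True)
class PackedNetwork:
    """Truth-table representation aligned with a :class:`BooleanNetwork`.

    ``reg_idx[i, :reg_len[i]]`` are regulator node indices of node ``i``;
    ``tables[offsets[i]:offsets[i+1]]`` is its 2^k output column (uint8).
    """

    nodes: tuple[str, ...]
    reg_idx: np.ndarray   # (n, max_k) int64
    reg_len: np.ndarray   # (n,) int64
    tables: np.ndarray    # (sum 2^k_i,) uint8
    offsets: np.ndarray   # (n+1,) int64

    @property
    def n(self) -> int:
        return len(self.nodes)

    def table_of(self, node: str) -> np.ndarray:
        i = self.nodes.index(node)
        return self.tables[self.offsets[i]:self.offsets[i + 1]].copy()

    def shuffled(
        self, rng: np.random.Generator, node_indices: list[int] | None = None
    ) -> "PackedNetwork":
        """Shuffle perturbation: permute the output columns of selected rules.

        ``node_indices=None`` shuffles every rule; otherwise only the listed
        nodes' tables are permuted.
        """
        tables = self.tables.copy()
        indices = range(self.n) if node_indices is None else node_indices
        for i in indices:
            lo, hi = self.offsets[i], self.offsets[i + 1]
            tables[lo:hi] = tables[lo:hi][rng.permutation(hi - lo)]
        return PackedNetwork(self.nodes, self.reg_idx, self.reg_len, tables, self.offsets)

    def to_network(self) -> BooleanNetwork:
        """Render back to an expression-tree network (tables become DNF rules)."""
        rules = {}
        for i, node in enumerate(self.nodes):
            k = int(self.reg_len[i])
            regs = [self.nodes[j] for j in self.reg_idx[i, :k]]
            table = self.tables[self.offsets[i]:self.offsets[i + 1]]
            rules[node] = table_to_expr(regs, table)
        return BooleanNetwork(self.nodes, rules)


def pack_network(net: BooleanNetwork) -> PackedNetwork:
    n = net.n
    reg_lists = [[net.index(r) for r in net.regulators(v)] for v in net.nodes]
    max_k = max((len(r) for r in reg_lists), default=0)
    reg_idx = np.zeros((n, max(max_k, 1)), dtype=np.int64)
    reg_len = np.zeros(n, dtype=np.int64)
    offsets = np.zeros(n + 1, dtype=np.int64)
    chunks = []
    for i, (node, regs) in enumerate(zip(net.nodes, reg_lists)):
        k = len(regs)
        reg_len[i] = k
        reg_idx[i, :k] = regs
        rule = net.rules[node]
        names = [net.nodes[j] for j in regs]
        col = np.empty(1 << k, dtype=np.uint8)
        for idx, bits in enumerate(product((False, True), repeat=k)):
            # product varies the LAST element fastest; regulator j maps to bit j
            assignment = {names[j]: bits[k - 1 - j] for j in range(k)}
            col[sum(bits[k - 1 - j] << j for j in range(k))] = evaluate(rule, assignment)
        chunks.append(col)
        offsets[i + 1] = offsets[i] + (1 << k)
    tables = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8)
    return PackedNetwork(net.nodes, reg_idx, reg_len, tables, offsets)


def table_to_expr(regs: list[str], table: np.ndarray) -> BoolExpr:
    """Disjunctive normal form of a regulator-ordered truth-table column."""
    k = len(regs)
    if k == 0:
        return BoolExpr.const(bool(table[0]))
    ones = [idx for idx in range(1 << k) if table[idx]]
    if not ones:
        return BoolExpr.const(False)
    if len(ones) == 1 << k:
        return BoolExpr.const(True)
    minterms = []
    for idx in ones:
        lits = [
            BoolExpr.var(regs[j]) if (idx >> j) & 1 else BoolExpr.not_(BoolExpr.var(regs[j]))
            for j in range(k)
        ]
        minterms.append(BoolExpr.and_(*lits))
    return BoolExpr.or_(*minterms)


# ---------------------------------------------------------------------------
# Exhaustive fixed-point enumeration (vectorized numpy)
# ---------------------------------------------------------------------------

def fixed_point_bitmasks(packed: PackedNetwork, chunk_bits: int = 20) -> np.ndarray:
    """All states s with f(s) = s, as an ascending int64 bitmask array."""
    n = packed.n
    if n > MAX_EXHAUSTIVE_NODES:
        raise ValueError(
            f"{n} nodes exceeds the exhaustive enumeration limit of "
            f"{MAX_EXHAUSTIVE_NODES}"
        )
    total = 1 << n
    chunk = min(total, 1 << chunk_bits)
    found = []
    for start in range(0, total, chunk):
        states = np.arange(start, min(start + chunk, total), dtype=np.int64)
        ok = np.ones(len(states), dtype=bool)
        for i in range(n):
            k = int(packed.reg_len[i])
            idx = np.zeros(len(states), dtype=np.int64)
            for j in range(k):
                r = packed.reg_idx[i, j]
                idx |= ((states >> r) & 1) << j
            nxt = packed.tables[packed.offsets[i] + idx]
            cur = ((states >> i) & 1).astype(np.uint8)
            ok &= nxt == cur
        found.append(states[ok])
    return np.concatenate(found)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _eval_node(state, i, reg_idx, reg_len, tables, offsets):
    idx = 0
    for j in range(reg_len[i]):
        idx |= ((state >> reg_idx[i, j]) & 1) << j
    return tables[offsets[i] + idx]


@njit(cache=True)
def _is_fixed(state, n, reg_idx, reg_len, tables, offsets):
    for i in range(n):
        if _eval_node(state, i, reg_idx, reg_len, tables, offsets) != (state >> i) & 1:
            return False
    return True


@njit(cache=True)
def _walk_terminals(
    reg_idx, reg_len, tables, offsets, n, starts, walk_length, seed, check_every
):
    """Asynchronous random walk from each start state; returns terminal states.

    A walk whose state is already a fixed point exits early (further updates
    cannot change it), making the common converged case cheap.
    """
    np.random.seed(seed)
    out = np.empty(len(starts), dtype=np.int64)
    for w in range(len(starts)):
        state = starts[w]
        steps = 0
        while steps < walk_length:
            if steps % check_every == 0 and _is_fixed(
                state, n, reg_idx, reg_len, tables, offsets
            ):
                break
            i = np.random.randint(0, n)
            val = _eval_node(state, i, reg_idx, reg_len, tables, offsets)
            if val:
                state |= np.int64(1) << i
            else:
                state &= ~(np.int64(1) << i)
            steps += 1
        out[w] = state
    return out


@njit(cache=True)
def _ensemble_counts(
    reg_idx, reg_len, tables, offsets, free_nodes, init_state,
    readout, n_runs, t_max, seed
):
    """ON-count of ``readout`` at each step t=0..t_max over n_runs async runs.

    Each run starts from ``init_state`` (clamps already applied); one uniformly
    chosen *free* node is updated per step; clamped nodes never change.
    """
    np.random.seed(seed)
    counts = np.zeros(t_max + 1, dtype=np.int64)
    n_free = len(free_nodes)
    for _ in range(n_runs):
        state = init_state
        for t in range(t_max + 1):
            counts[t] += (state >> readout) & 1
            if t == t_max or n_free == 0:
                continue
            i = free_nodes[np.random.randint(0, n_free)]
            val = _eval_node(state, i, reg_idx, reg_len, tables, offsets)
            if val:
                state |= np.int64(1) << i
            else:
                state &= ~(np.int64(1) << i)
    return counts


def walk_terminal_states(
    packed: PackedNetwork,
    starts: np.ndarray,
    walk_length: int,
    seed: int,
    check_every: int = 32,
) -> np.ndarray:
    """Terminal states of asynchronous walks from ``starts`` (int64 bitmasks)."""
    return _walk_terminals(
        packed.reg_idx, packed.reg_len, packed.tables, packed.offsets,
        packed.n, np.asarray(starts, dtype=np.int64),
        int(walk_length), int(seed) & 0x7FFFFFFF, int(check_every),
    )


def ensemble_on_counts(
    packed: PackedNetwork,
    free_nodes: np.ndarray,
    init_state: int,
    readout_index: int,
    n_runs: int,
    t_max: int,
    seed: int,
) -> np.ndarray:
    return _ensemble_counts(
        packed.reg_idx, packed.reg_len, packed.tables, packed.offsets,
        np.asarray(free_nodes, dtype=np.int64), np.int64(init_state),
        int(readout_index), int(n_runs), int(t_max), int(seed) & 0x7FFFFFFF,
    )


def verify_fixed(packed: PackedNetwork, state: int) -> bool:
    return bool(
        _is_fixed(
            np.int64(state), packed.n, packed.reg_idx, packed.reg_len,
            packed.tables, packed.offsets,
        )
    )
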