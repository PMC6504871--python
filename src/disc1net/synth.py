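"""Ground-truth generators: random Boolean networks and planted loop tables.

Random networks are drawn in truth-table space (each node gets up to
``max_in_degree`` random regulators and a random output column with a chosen
ON bias), then rendered to expression rules, so every generated network is
exactly representable in the rule-file dialect and shuffle perturbation is
trivially well-defined on it.  Planted edge tables embed a known set of mutual
miRNA-TF pairs among non-reciprocated noise edges, providing an oracle for
loop mining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boolean_core import BooleanNetwork
from .fbl import EDGE_COLUMNS, FeedbackLoop, RegulatoryEdgeTable, normalize_mirna_name
from .packed import table_to_expr

__all__ = [
    "SyntheticNetworkSpec",
    "PlantedLoopSpec",
    "random_network",
    "planted_edge_tables",
]


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    n_nodes: int
    max_in_degree: int = 3
    bias: float = 0.5     # probability a truth-table output is 1
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 <= self.bias <= 1:
            raise ValueError("bias must be in [0, 1]")
        if self.max_in_degree < 0:
            raise ValueError("max_in_degree must be >= 0")


@dataclass(frozen=True)
class PlantedLoopSpec:
    n_mirnas: int = 10
    n_tfs: int = 6
    n_genes: int = 12
    n_planted_loops: int = 5
    noise_edges: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_loops > self.n_mirnas * self.n_tfs:
            raise ValueError("cannot plant more loops than miRNA×TF pairs")


def random_network(spec: SyntheticNetworkSpec) -> BooleanNetwork:
    """Random Boolean network with bounded in-degree and biased truth tables.

    Reproducible under the spec's seed; node names are n0, n1, ...
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"n{i}" for i in range(spec.n_nodes)]
    rules = {}
    for i, name in enumerate(names):
        k = int(rng.integers(0, min(spec.max_in_degree, spec.n_nodes) + 1))
        regs = sorted(rng.choice(spec.n_nodes, size=k, replace=False).tolist())
        table = (rng.random(1 << k) < spec.bias).astype(np.uint8)
        rules[name] = table_to_expr([names[j] for j in regs], table)
    return BooleanNetwork(tuple(names), rules)


def _edge_frame(rows: list[tuple[str, str, str, str]]) -> RegulatoryEdgeTable:
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS[:4])
    df["source_db"] = "synthetic"
    df["evidence"] = "planted"
    return RegulatoryEdgeTable(df)


def planted_edge_tables(
    spec: PlantedLoopSpec,
) -> tuple[
    RegulatoryEdgeTable, RegulatoryEdgeTable, RegulatoryEdgeTable,
    RegulatoryEdgeTable, list[FeedbackLoop],
]:
    """Edge tables with exactly ``n_planted_loops`` mutual miRNA-TF pairs.

    Returns (mirna_to_tf, tf_to_mirna, tf_to_gene, mirna_to_gene, truth) where
    ``truth`` lists the planted loops; noise edges are never reciprocated, so
    loop mining must recover the truth exactly.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas = [f"miRS{i}" for i in range(spec.n_mirnas)]
    tfs = [f"TFS{i}" for i in range(spec.n_tfs)]
    genes = [f"GS{i}" for i in range(spec.n_genes)]

    all_pairs = [(m, t) for m in mirnas for t in tfs]
    order = rng.permutation(len(all_pairs))
    planted = [all_pairs[i] for i in order[: spec.n_planted_loops]]
    planted_set = set(planted)

    fwd = [(m, "miRNA", t, "TF") for m, t in planted]
    rev = [(t, "TF", m, "miRNA") for m, t in planted]
    # non-reciprocated noise: each unplanted pair may appear in one direction only
    candidates = [p for p in all_pairs if p not in planted_set]
    rng.shuffle(candidates)
    for j in range(min(spec.noise_edges, len(candidates))):
        m, t = candidates[j]
        if rng.random() < 0.5:
            fwd.append((m, "miRNA", t, "TF"))
        else:
            rev.append((t, "TF", m, "miRNA"))

    tf_gene = [
        (t, "TF", genes[int(rng.integers(spec.n_genes))], "gene") for t in tfs
    ]
    mir_gene = [
        (m, "miRNA", genes[int(rng.integers(spec.n_genes))], "gene") for m in mirnas
    ]
    # truth carries normalized identifiers, as loop mining reports them
    norm = sorted(
        ((normalize_mirna_name(m), t) for m, t in planted), key=lambda p: (p[1], p[0])
    )
    truth = [FeedbackLoop(mirna_id=m, tf_id=t) for (m, t) in norm]
    return (
        _edge_frame(fwd), _edge_frame(rev),
        _edge_frame(tf_gene), _edge_frame(mir_gene), truth,
    )
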