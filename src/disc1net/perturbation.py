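"""Per-FM regulatory network construction and OE/KO ensemble simulation.

Each functional module's network layers a miRNA-TF feedback-loop circuit over
the module's genes and a single migration readout node:

* TF nodes are expressed only when every loop miRNA repressing them is OFF
  (conjunction of negated miRNAs);
* miRNA nodes follow their regulating TF(s), with the sign set by the
  scenario's TF→miRNA direction (OR-combined over TFs);
* gene nodes combine a scenario-signed TF term with miRNA repression — under
  TF-activates-gene scenarios ``gene = (OR of TFs) | !(OR of miRNAs)`` (direct
  TF activation dominates miRNA repression), under TF-represses-gene scenarios
  ``gene = !(OR of TFs) & !(OR of miRNAs)`` — and protein-layer repressions
  (e.g. DISC1 ⊣ SOX10) are conjoined as ``& !repressor`` and dominate;
* the migration readout is the conjunction of the module's facilitatory genes
  and the negations of its inhibitory genes.

The four scenarios cover the unknown sign of TF regulation: 1 = TF activates
gene and miRNA; 2 = TF represses both; 3 = TF activates gene, represses miRNA;
4 = TF represses gene, activates miRNA.

Overexpression (OE) clamps a node TRUE for the whole run, knockout (KO) clamps
it FALSE.  Ensembles start every run from the all-OFF state (clamps applied)
and update one uniformly chosen free node per step; the activation curve is
the percentage of runs with the readout ON at each step, smoothed by a
trailing moving average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boolean_core import BoolExpr, BooleanNetwork, ClampSet
from .packed import ensemble_on_counts, pack_network

__all__ = [
    "ScenarioConfig",
    "SimulationConfig",
    "ActivationCurve",
    "PerturbationResult",
    "FMWiring",
    "READOUT_NODE",
    "build_fm_network",
    "run_ensemble",
    "moving_average",
    "perturbation_screen",
]

READOUT_NODE = "migration"

ACTIVATE = "activate"
REPRESS = "repress"


@dataclass(frozen=True)
class ScenarioConfig:
    """Signs of TF regulation: (TF→gene, TF→miRNA) ∈ {activate, repress}²."""

    tf_on_gene: str
    tf_on_mirna: str

    _NUMBERS = {
        (ACTIVATE, ACTIVATE): 1,
        (REPRESS, REPRESS): 2,
        (ACTIVATE, REPRESS): 3,
        (REPRESS, ACTIVATE): 4,
    }

    def __post_init__(self):
        if (self.tf_on_gene, self.tf_on_mirna) not in self._NUMBERS:
            raise ValueError("signs must be 'activate' or 'repress'")

    @property
    def number(self) -> int:
        return self._NUMBERS[(self.tf_on_gene, self.tf_on_mirna)]

    @classmethod
    def from_number(cls, n: int) -> "ScenarioConfig":
        for signs, num in cls._NUMBERS.items():
            if num == n:
                return cls(*signs)
        raise ValueError(f"scenario number must be 1-4, got {n}")


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble settings: runs, horizon, smoothing window, seed."""

    n_runs: int = 1000
    t_max: int = 150
    smooth_window: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 1 <= self.smooth_window <= self.t_max + 1:
            raise ValueError("smooth_window must be in [1, t_max + 1]")


@dataclass(frozen=True)
class ActivationCurve:
    """Per-step ON percentage of the readout across the ensemble."""

    freq: np.ndarray       # raw, length t_max + 1, values in [0, 100]
    smoothed: np.ndarray   # trailing moving average, length len(freq) - window + 1
    window: int

    @property
    def terminal(self) -> float:
        return float(self.smoothed[-1])


@dataclass(frozen=True)
class PerturbationResult:
    node: str | None       # None for the unperturbed baseline
    mode: str              # "OE" | "KO" | "baseline"
    scenario: int
    fm: str
    curve: ActivationCurve

    @property
    def terminal_freq(self) -> float:
        return self.curve.terminal


@dataclass(frozen=True)
class FMWiring:
    """Regulatory wiring of one FM's perturbation network.

    ``roles`` maps each module gene to ``facilitatory``/``inhibitory``; the
    remaining maps give, per target, its regulators of each layer.
    """

    fm: str
    roles: dict[str, str]                      # gene -> role
    tfs_of_gene: dict[str, tuple[str, ...]]
    mirnas_of_gene: dict[str, tuple[str, ...]]
    repressors_of_gene: dict[str, tuple[str, ...]]  # protein-layer
    tfs_of_mirna: dict[str, tuple[str, ...]]
    mirnas_of_tf: dict[str, tuple[str, ...]]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.roles)

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(sorted(self.mirnas_of_tf))

    @property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(sorted(self.tfs_of_mirna))


def _or_vars(names: tuple[str, ...]) -> BoolExpr:
    return BoolExpr.or_(*(BoolExpr.var(n) for n in names))


def build_fm_network(fm: str, scenario: ScenarioConfig, wiring: FMWiring) -> BooleanNetwork:
    """Compile one FM's wiring into a Boolean network under a scenario.

    Node order is deterministic: genes (fixture order), TFs (sorted), miRNAs
    (sorted), then the migration readout; the order is scenario-independent,
    so runs under different scenarios share identical update-order draws.
    """
    if wiring.fm != fm:
        raise ValueError(f"wiring is for {wiring.fm}, not {fm}")
    rules: dict[str, BoolExpr] = {}

    for gene in wiring.genes:
        tfs = wiring.tfs_of_gene.get(gene, ())
        mirs = wiring.mirnas_of_gene.get(gene, ())
        reps = wiring.repressors_of_gene.get(gene, ())
        terms: list[BoolExpr] = []
        if tfs or mirs:
            if scenario.tf_on_gene == ACTIVATE:
                parts = []
                if tfs:
                    parts.append(_or_vars(tfs))
                if mirs:
                    parts.append(BoolExpr.not_(_or_vars(mirs)))
                terms.append(BoolExpr.or_(*parts))
            else:
                if tfs:
                    terms.append(BoolExpr.not_(_or_vars(tfs)))
                if mirs:
                    terms.append(BoolExpr.not_(_or_vars(mirs)))
        base = BoolExpr.and_(*terms) if terms else None
        rep_terms = [BoolExpr.not_(BoolExpr.var(r)) for r in reps]
        if base is not None:
            rules[gene] = BoolExpr.and_(base, *rep_terms)
        elif rep_terms:
            rules[gene] = BoolExpr.and_(*rep_terms)
        else:
            rules[gene] = BoolExpr.var(gene)  # unregulated: holds its state

    for tf in wiring.tfs:
        mirs = wiring.mirnas_of_tf[tf]
        if not mirs:
            raise ValueError(f"TF {tf} has no loop miRNAs in {fm}")
        rules[tf] = BoolExpr.and_(*(BoolExpr.not_(BoolExpr.var(m)) for m in mirs))

    for mir in wiring.mirnas:
        tfs = wiring.tfs_of_mirna[mir]
        if not tfs:
            raise ValueError(f"miRNA {mir} has no regulating TF in {fm}")
        expr = _or_vars(tfs)
        rules[mir] = expr if scenario.tf_on_mirna == ACTIVATE else BoolExpr.not_(expr)

    facil = [g for g, role in wiring.roles.items() if role == "facilitatory"]
    inhib = [g for g, role in wiring.roles.items() if role == "inhibitory"]
    if not facil:
        raise ValueError(f"{fm} has no facilitatory genes for the readout")
    rules[READOUT_NODE] = BoolExpr.and_(
        *(BoolExpr.var(g) for g in facil),
        *(BoolExpr.not_(BoolExpr.var(g)) for g in inhib),
    )

    nodes = wiring.genes + wiring.tfs + wiring.mirnas + (READOUT_NODE,)
    return BooleanNetwork(nodes, rules)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing-window arithmetic mean; output length = len(values) - window + 1."""
    values = np.asarray(values, dtype=float)
    if not 1 <= window <= len(values):
        raise ValueError("window must satisfy 1 <= window <= len(values)")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def run_ensemble(
    net: BooleanNetwork,
    clamps: ClampSet,
    readout: str,
    cfg: SimulationConfig,
) -> ActivationCurve:
    """Activation curve of ``readout`` over a seeded asynchronous ensemble.

    All runs start from the all-OFF state with clamps applied; each of
    ``cfg.t_max`` steps updates one uniformly chosen unclamped node.
    ``freq[t]`` = 100 × (runs with readout ON at step t) / n_runs.
    Bit-reproducible for a fixed seed.
    """
    clamps.validate(net)
    if readout not in net.nodes:
        raise ValueError(f"readout {readout!r} not in network")
    if readout in clamps.clamped:
        warnings.warn(f"readout {readout!r} is clamped; curve is trivial")
    packed = pack_network(net)
    free = np.array(
        [i for i, v in enumerate(net.nodes) if v not in clamps.clamped],
        dtype=np.int64,
    )
    init = 0
    for i, v in enumerate(net.nodes):
        if clamps.clamped.get(v, False):
            init |= 1 << i
    counts = ensemble_on_counts(
        packed, free, init, net.index(readout), cfg.n_runs, cfg.t_max, cfg.seed
    )
    freq = 100.0 * counts / cfg.n_runs
    return ActivationCurve(freq, moving_average(freq, cfg.smooth_window), cfg.smooth_window)


def perturbation_screen(
    fm: str,
    wiring: FMWiring,
    cfg: SimulationConfig,
    scenarios: tuple[int, ...] = (1, 2, 3, 4),
    nodes: tuple[str, ...] | None = None,
) -> list[PerturbationResult]:
    """OE and KO of every network node under each scenario, plus baselines.

    The per-condition RNG stream depends on the node and mode but *not* the
    scenario, so scenario comparisons for one perturbation share update-order
    draws.
    """
    all_nodes = wiring.genes + wiring.tfs + wiring.mirnas
    if nodes is None:
        nodes = all_nodes
    else:
        unknown = set(nodes) - set(all_nodes)
        if unknown:
            raise ValueError(f"unknown nodes for {fm}: {sorted(unknown)}")
    results = []
    for s in scenarios:
        net = build_fm_network(fm, ScenarioConfig.from_number(s), wiring)
        conditions: list[tuple[str | None, str, ClampSet]] = [
            (None, "baseline", ClampSet())
        ]
        for node in nodes:
            conditions.append((node, "OE", ClampSet.oe(node)))
            conditions.append((node, "KO", ClampSet.ko(node)))
        for node, mode, clamps in conditions:
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=[
                        cfg.seed,
                        0 if node is None else all_nodes.index(node) + 1,
                        {"baseline": 0, "OE": 1, "KO": 2}[mode],
                    ]
                ).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            curve = run_ensemble(
                net,
                clamps,
                READOUT_NODE,
                SimulationConfig(cfg.n_runs, cfg.t_max, cfg.smooth_window, sub_seed),
            )
            results.append(PerturbationResult(node, mode, s, fm, curve))
    return results
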