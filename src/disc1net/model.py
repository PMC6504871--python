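"""Packaged DISC1-interactome fixtures and their validation.

Ships the 19-protein migration Boolean network, the reference table of its 18
published steady states, the short↔gene-symbol name map, the per-FM gene sets
and regulatory wiring, and the curated-style edge tables for feedback-loop
mining.  The rule set is a reverse-engineered reconstruction whose fixed-point
set equals the published attractor table exactly; any rule set passing
:func:`validate_against_table1` would be an acceptable replacement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .attractors import classify_attractor_fms, enumerate_fixed_points
from .boolean_core import BooleanNetwork, NetworkState, parse_rules
from .fbl import RegulatoryEdgeTable, enrichment_records, EnrichmentRecord
from .perturbation import FMWiring

__all__ = [
    "DATA_DIR",
    "NameMap",
    "FunctionalModule",
    "Table1Row",
    "ValidationReport",
    "load_name_map",
    "load_migration_network",
    "load_table1_reference",
    "validate_against_table1",
    "load_fm_fixtures",
    "fm_gene_sets",
    "load_fbl_tables",
    "load_enrichment_records",
]

DATA_DIR = Path(__file__).parent / "data"

FM_DESCRIPTIONS = {
    "FM1": "radial migration of immature neurons",
    "FM2": "radial migration of basal progenitors",
    "FM3": "radial migration of newborn neurons",
    "FM4": "radial migration of neuronal precursor cells",
    "FM5": "radial migration of apical and basal progenitors",
    "FM6": "tangential migration of cortical interneurons",
    "FM7": "cranial neural crest cell migration",
    "FM8": "migration of adult hippocampal progenitors",
}


@dataclass(frozen=True)
class NameMap:
    """Bijective short-symbol ↔ gene-symbol map (e.g. LIS1 ↔ PAFAH1B1)."""

    short_to_symbol: dict[str, str]

    def __post_init__(self):
        vals = list(self.short_to_symbol.values())
        if len(set(vals)) != len(vals):
            raise ValueError("name map is not bijective")

    @property
    def symbol_to_short(self) -> dict[str, str]:
        return {v: k for k, v in self.short_to_symbol.items()}

    def to_symbol(self, short: str) -> str:
        return self.short_to_symbol[short]

    def to_short(self, symbol: str) -> str:
        return self.symbol_to_short[symbol]

    def resolve_short(self, name: str) -> str:
        """Accept either a short symbol or a gene symbol; return the short form."""
        if name in self.short_to_symbol:
            return name
        if name in self.symbol_to_short:
            return self.symbol_to_short[name]
        raise KeyError(f"unknown protein identifier {name!r}")


@dataclass(frozen=True)
class FunctionalModule:
    """One functional module: id, description, genes with roles, and wiring."""

    id: str
    description: str
    roles: dict[str, str]
    wiring: FMWiring

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.roles)


@dataclass(frozen=True)
class Table1Row:
    row: int
    on_short_names: frozenset[str]
    facilitated_fms: tuple[str, ...]


@dataclass
class ValidationReport:
    passed: bool
    failures: list[str]
    n_fixed_points: int


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def load_name_map() -> NameMap:
    rows = _read_tsv(DATA_DIR / "name_map.tsv")
    return NameMap({r["short"]: r["symbol"] for r in rows})


def load_migration_network() -> BooleanNetwork:
    """The packaged 19-node migration network, nodes in published display order."""
    return parse_rules((DATA_DIR / "disc1_migration.bn").read_text())


def load_table1_reference() -> list[Table1Row]:
    """Reference steady states: ON-sets (short names) and FM classifications."""
    net = load_migration_network()
    out = []
    for r in _read_tsv(DATA_DIR / "table1_attractors.tsv"):
        bits = r["bitstring"]
        if len(bits) != net.n:
            raise ValueError(f"row {r['row']}: bitstring length != {net.n}")
        on = frozenset(v for v, b in zip(net.nodes, bits) if b == "1")
        fms = () if r["facilitated_fms"] == "-" else tuple(r["facilitated_fms"].split(","))
        out.append(Table1Row(int(r["row"]), on, fms))
    return out


def validate_against_table1(net: BooleanNetwork) -> ValidationReport:
    """Check a candidate migration network against the published attractor table.

    Verifies (a) the exhaustive fixed-point count, (b) a name-based ON-set
    match between fixed points and reference rows (order-independent), and
    (c) the FM classification of every row.  Collects all failures rather than
    stopping at the first.
    """
    reference = load_table1_reference()
    failures: list[str] = []
    fps = enumerate_fixed_points(net)
    if len(fps) != len(reference):
        failures.append(f"expected {len(reference)} fixed points, found {len(fps)}")
    found_on = {fp.on_set() for fp in fps}
    ref_on = {row.on_short_names for row in reference}
    for row in reference:
        if row.on_short_names not in found_on:
            failures.append(f"reference row {row.row} is not a fixed point")
    for extra in sorted(found_on - ref_on, key=sorted):
        failures.append(f"unexpected fixed point ON={sorted(extra)}")
    for row in reference:
        state = NetworkState.from_on_set(net, set(row.on_short_names))
        got = classify_attractor_fms(state)
        if got != row.facilitated_fms:
            failures.append(
                f"row {row.row}: classified {got or '()'} != "
                f"reference {row.facilitated_fms or '()'}"
            )
    return ValidationReport(not failures, failures, len(fps))


# ---------------------------------------------------------------------------
# Per-FM fixtures
# ---------------------------------------------------------------------------

def _append(d: dict[str, tuple[str, ...]], key: str, val: str) -> None:
    cur = d.get(key, ())
    if val not in cur:
        d[key] = cur + (val,)


def load_fm_fixtures() -> dict[str, FunctionalModule]:
    """All eight functional modules with their regulatory wiring."""
    gene_rows = _read_tsv(DATA_DIR / "fm_genes.tsv")
    reg_rows = _read_tsv(DATA_DIR / "fm_regulation.tsv")
    fms = sorted({r["fm"] for r in gene_rows})
    modules: dict[str, FunctionalModule] = {}
    for fm in fms:
        roles = {r["gene"]: r["role"] for r in gene_rows if r["fm"] == fm}
        tfs_of_gene: dict[str, tuple[str, ...]] = {}
        mirnas_of_gene: dict[str, tuple[str, ...]] = {}
        repressors_of_gene: dict[str, tuple[str, ...]] = {}
        tfs_of_mirna: dict[str, tuple[str, ...]] = {}
        mirnas_of_tf: dict[str, tuple[str, ...]] = {}
        for r in reg_rows:
            if r["fm"] not in (fm, "ALL"):
                continue
            reg, rt, tgt, tt = (
                r["regulator"], r["regulator_type"], r["target"], r["target_type"],
            )
            if tt == "gene":
                if r["fm"] != "ALL" and tgt not in roles:
                    raise ValueError(f"{fm}: regulation targets non-member gene {tgt}")
                if rt == "TF":
                    _append(tfs_of_gene, tgt, reg)
                elif rt == "miRNA":
                    _append(mirnas_of_gene, tgt, reg)
                elif rt == "protein":
                    _append(repressors_of_gene, tgt, reg)
                else:
                    raise ValueError(f"unknown regulator_type {rt!r}")
            elif tt == "miRNA":
                _append(tfs_of_mirna, tgt, reg)
            elif tt == "TF":
                _append(mirnas_of_tf, tgt, reg)
            else:
                raise ValueError(f"unknown target_type {tt!r}")
        wiring = FMWiring(
            fm=fm,
            roles=roles,
            tfs_of_gene=tfs_of_gene,
            mirnas_of_gene=mirnas_of_gene,
            repressors_of_gene=repressors_of_gene,
            tfs_of_mirna=tfs_of_mirna,
            mirnas_of_tf=mirnas_of_tf,
        )
        modules[fm] = FunctionalModule(fm, FM_DESCRIPTIONS[fm], roles, wiring)
    return modules


def fm_gene_sets(include_disc1: bool = False) -> dict[str, set[str]]:
    """FM → gene-symbol sets.

    DISC1 belongs to every module; for loop→FM assignment it is excluded by
    default, because the critical TFs regulate DISC1 in *all* modules and the
    assignment is meant to capture each loop's direct module-specific targets.
    """
    rows = _read_tsv(DATA_DIR / "fm_genes.tsv")
    out: dict[str, set[str]] = {}
    for r in rows:
        if not include_disc1 and r["gene"] == "DISC1":
            continue
        out.setdefault(r["fm"], set()).add(r["gene"])
    return out


# ---------------------------------------------------------------------------
# Feedback-loop tables
# ---------------------------------------------------------------------------

def load_fbl_tables() -> dict[str, RegulatoryEdgeTable]:
    """The four curated-style edge tables used by loop mining."""
    names = ["mirna_to_tf", "tf_to_mirna", "tf_to_gene", "mirna_to_gene"]
    return {
        name: RegulatoryEdgeTable.from_tsv(DATA_DIR / "fbl" / f"{name}.tsv")
        for name in names
    }


def load_enrichment_records() -> list[EnrichmentRecord]:
    """Per-TF enrichment contingency fixtures with computed Fisher p-values."""
    df = pd.read_csv(DATA_DIR / "fbl" / "tf_enrichment.tsv", sep="\t", comment="#")
    return enrichment_records(df)
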