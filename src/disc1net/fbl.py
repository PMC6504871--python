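"""miRNA-TF feedback-loop discovery from curated regulatory edge tables.

A feedback loop is a miRNA ``m`` and a transcription factor ``T`` that mutually
regulate each other: ``m → T`` appears in the miRNA-target table and ``T → m``
in the TF-miRNA table.  TFs first pass a Fisher-exact enrichment filter
(one-sided over-representation, p ≤ 0.05 inclusive, no multiple-testing
correction).  Each loop is then assigned the functional modules in which the
pair exerts direct transcriptional/post-transcriptional control: a loop
regulates an FM iff its TF or its miRNA has an edge onto at least one gene of
that FM's gene set.

Identifier normalization reconciles database naming: ``hsa-miR-155-5p``
(miRTarBase), ``hsa-mir-155`` (TransmiR stem-loop) and the short display form
``miR155`` all normalize to ``miR155``.  Arm suffixes (-5p/-3p) are collapsed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "RegulatoryEdgeTable",
    "EnrichmentRecord",
    "FeedbackLoop",
    "normalize_mirna_name",
    "fisher_exact_enrichment",
    "filter_tfs",
    "find_feedback_loops",
    "assign_loops_to_fms",
]

EDGE_COLUMNS = [
    "regulator", "regulator_type", "target", "target_type", "source_db", "evidence",
]

_MIRNA_RE = re.compile(r"^(mir|let)[-.]?(.*)$", re.IGNORECASE)
_ARM_RE = re.compile(r"[-.](5p|3p)$", re.IGNORECASE)


def normalize_mirna_name(name: str) -> str:
    """Canonical short miRNA name: ``hsa-miR-155-5p`` → ``miR155``.

    Strips the species prefix and arm suffix, removes separators, and
    canonicalizes capitalization (``miR``/``let``).  Non-miRNA identifiers are
    returned unchanged.
    """
    s = name.strip()
    if s.lower().startswith("hsa-"):
        s = s[4:]
    s = _ARM_RE.sub("", s)
    m = _MIRNA_RE.match(s)
    if not m:
        return name.strip()
    prefix = "miR" if m.group(1).lower() == "mir" else "let"
    body = re.sub(r"[-. ]", "", m.group(2))
    return prefix + body.lower()


def normalize_identifier(name: str, kind: str) -> str:
    """Normalize a regulator/target identifier by its type."""
    return normalize_mirna_name(name) if kind == "miRNA" else name.strip().upper()


@dataclass
class RegulatoryEdgeTable:
    """Typed regulator→target edges with evidence fields (pandas-backed)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = set(EDGE_COLUMNS[:4]) - set(self.frame.columns)
        if missing:
            raise ValueError(f"edge table lacks columns: {sorted(missing)}")
        for col in EDGE_COLUMNS[4:]:
            if col not in self.frame.columns:
                self.frame[col] = ""

    @classmethod
    def from_tsv(cls, path) -> "RegulatoryEdgeTable":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype=str))

    def normalized(self) -> "RegulatoryEdgeTable":
        """Normalize identifiers and drop duplicate (regulator, target) pairs."""
        df = self.frame.copy()
        df["regulator"] = [
            normalize_identifier(r, t)
            for r, t in zip(df["regulator"], df["regulator_type"])
        ]
        df["target"] = [
            normalize_identifier(r, t)
            for r, t in zip(df["target"], df["target_type"])
        ]
        df = df.drop_duplicates(subset=["regulator", "target"], keep="first")
        return RegulatoryEdgeTable(df.reset_index(drop=True))

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["regulator"], self.frame["target"]))

    def targets_of(self, regulator: str) -> set[str]:
        sel = self.frame["regulator"] == regulator
        return set(self.frame.loc[sel, "target"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class EnrichmentRecord:
    """A TF's 2×2 target-enrichment contingency table and its Fisher p-value."""

    tf_id: str
    contingency: tuple[int, int, int, int]  # (overlap, tf-only, set-only, rest)
    p_value: float


@dataclass
class FeedbackLoop:
    """A mutually regulating miRNA-TF pair with its FM assignment."""

    mirna_id: str
    tf_id: str
    fms_regulated: tuple[str, ...] = ()
    gene_targets: tuple[str, ...] = ()

    @property
    def multi_fm(self) -> bool:
        return len(self.fms_regulated) >= 2


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_exact_enrichment(contingency: tuple[int, int, int, int]) -> float:
    """One-sided (over-representation) Fisher exact p-value of a 2×2 table.

    The hypergeometric upper-tail probability P(X ≥ a) with the table's
    margins fixed; exact, no approximation.
    """
    a, b, c, d = (int(x) for x in contingency)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrichment_records(table: pd.DataFrame) -> list[EnrichmentRecord]:
    """Compute per-TF enrichment records from a (tf, a, b, c, d) count frame."""
    out = []
    for row in table.itertuples(index=False):
        cont = (int(row.a), int(row.b), int(row.c), int(row.d))
        out.append(EnrichmentRecord(str(row.tf), cont, fisher_exact_enrichment(cont)))
    return out


def filter_tfs(records: list[EnrichmentRecord], alpha: float = 0.05) -> set[str]:
    """TFs enriched at p ≤ alpha (boundary inclusive); no multiplicity correction."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return {r.tf_id for r in records if r.p_value <= alpha}


# ---------------------------------------------------------------------------
# Loop mining and FM assignment
# ---------------------------------------------------------------------------

def find_feedback_loops(
    mirna_to_tf: RegulatoryEdgeTable,
    tf_to_mirna: RegulatoryEdgeTable,
    tf_whitelist: set[str] | None = None,
) -> list[FeedbackLoop]:
    """All (miRNA, TF) pairs with edges in both directions.

    Tables are normalized internally, so raw database naming is accepted.
    ``tf_whitelist`` (e.g. the enrichment-filtered TF set) restricts the TFs
    considered.  Output order is deterministic: sorted by TF then miRNA.
    """
    fwd = mirna_to_tf.normalized().pairs()          # (mirna, tf)
    rev = tf_to_mirna.normalized().pairs()          # (tf, mirna)
    loops = {(m, t) for (m, t) in fwd if (t, m) in rev}
    if tf_whitelist is not None:
        loops = {(m, t) for (m, t) in loops if t in tf_whitelist}
    return [
        FeedbackLoop(mirna_id=m, tf_id=t)
        for (m, t) in sorted(loops, key=lambda p: (p[1], p[0]))
    ]


def assign_loops_to_fms(
    loops: list[FeedbackLoop],
    tf_to_gene: RegulatoryEdgeTable,
    mirna_to_gene: RegulatoryEdgeTable,
    fm_gene_sets: dict[str, set[str]],
) -> list[FeedbackLoop]:
    """Annotate each loop with the FMs it regulates.

    A loop regulates an FM iff its TF or its miRNA has an edge onto at least
    one gene in that FM's gene set.  Gene identifiers outside every FM set are
    tolerated (they simply contribute nothing).
    """
    tfg = tf_to_gene.normalized()
    mig = mirna_to_gene.normalized()
    fm_order = sorted(fm_gene_sets)
    out = []
    for loop in loops:
        genes = tfg.targets_of(loop.tf_id) | mig.targets_of(loop.mirna_id)
        fms = tuple(fm for fm in fm_order if genes & fm_gene_sets[fm])
        out.append(
            FeedbackLoop(
                mirna_id=loop.mirna_id,
                tf_id=loop.tf_id,
                fms_regulated=fms,
                gene_targets=tuple(sorted(genes)),
            )
        )
    return out


def loops_report(loops: list[FeedbackLoop]) -> pd.DataFrame:
    """Tabular loop report: mirna, tf, fms, n_fms."""
    return pd.DataFrame(
        {
            "mirna": [l.mirna_id for l in loops],
            "tf": [l.tf_id for l in loops],
            "fms": [",".join(l.fms_regulated) if l.fms_regulated else "-" for l in loops],
            "n_fms": [len(l.fms_regulated) for l in loops],
        }
    )


def enrichment_report(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tf": [r.tf_id for r in records],
            "a": [r.contingency[0] for r in records],
            "b": [r.contingency[1] for r in records],
            "c": [r.contingency[2] for r in records],
            "d": [r.contingency[3] for r in records],
            "p": [r.p_value for r in records],
        }
    )
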