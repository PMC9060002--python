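"""Replicate-filtered interactor sets and their partitions.

Co-IP mass-spectrometry identifications are accepted when the search
engine's Unused Protein Score is strictly above 1.3 at >= 95% confidence;
a protein enters a condition's interactome when it passes that filter in at
least two distinct biological replicates. Conditions are then compared by a
disjoint set partition (common / condition-specific) and against published
reference interactomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

HIT_COLUMNS = ["accession", "gene", "unused_score", "confidence"]


@dataclass(frozen=True)
class InteractorSet:
    """A condition's interactome with per-accession replicate provenance."""

    condition: str
    accessions: frozenset[str]
    replicate_counts: Mapping[str, int]
    gene_by_accession: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.accessions)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_by_accession[a] for a in self.accessions)


class Partition(NamedTuple):
    common: frozenset[str]
    a_specific: frozenset[str]
    b_specific: frozenset[str]


def filter_hits(
    table: pd.DataFrame,
    min_score: float = 1.3,
    min_confidence: float = 95.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the identification-score gates to one replicate table.

    Returns ``(kept, rejected)``: rows with ``unused_score`` strictly above
    ``min_score`` and ``confidence`` >= ``min_confidence`` pass; the
    rejected table carries a ``reject_reason`` column (first failing gate).
    """
    missing = set(HIT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    out = table.copy()
    reason = pd.Series("", index=out.index, dtype=object)
    reason[out["confidence"] < min_confidence] = "confidence"
    reason[out["unused_score"] <= min_score] = "score"  # strict "above"
    out["reject_reason"] = reason
    return out[out["reject_reason"] == ""].drop(columns="reject_reason"), out[
        out["reject_reason"] != ""
    ]


def replicate_consensus(
    replicates: Sequence[pd.DataFrame],
    condition: str,
    min_replicates: int = 2,
    min_score: float = 1.3,
    min_confidence: float = 95.0,
) -> InteractorSet:
    """Build a condition's interactome from its per-replicate tables.

    Membership requires detection (after score filtering) in at least
    ``min_replicates`` *distinct* replicates; duplicate rows within one
    replicate count once.
    """
    counts: dict[str, int] = {}
    genes: dict[str, str] = {}
    for rep in replicates:
        kept, _ = filter_hits(rep, min_score=min_score, min_confidence=min_confidence)
        for acc, gene in zip(kept["accession"], kept["gene"]):
            genes.setdefault(acc, gene)
        for acc in set(kept["accession"]):
            counts[acc] = counts.get(acc, 0) + 1
    members = frozenset(a for a, c in counts.items() if c >= min_replicates)
    return InteractorSet(
        condition=condition,
        accessions=members,
        replicate_counts={a: counts[a] for a in members},
        gene_by_accession={a: genes[a] for a in members},
    )


def partition(set_a: Iterable[str], set_b: Iterable[str]) -> Partition:
    """Disjoint partition of two interactomes into common and specific parts."""
    a, b = frozenset(set_a), frozenset(set_b)
    return Partition(common=a & b, a_specific=a - b, b_specific=b - a)


def reference_overlap(
    query: Iterable[str],
    references: Sequence[Iterable[str]],
    case_insensitive: bool = True,
) -> tuple[int, float]:
    """Overlap of an interactome with the union of reference lists.

    Returns ``(count, fraction_of_query)``. Identifiers are compared
    case-insensitively by default since published lists mix symbol casing.
    """
    norm = (lambda s: str(s).upper()) if case_insensitive else str
    q = {norm(g) for g in query}
    if not q:
        raise ValueError("empty query set")
    ref: set[str] = set()
    for r in references:
        ref.update(norm(g) for g in r)
    k = len(q & ref)
    return k, k / len(q)
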