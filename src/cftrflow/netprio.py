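"""Two-stage candidate prioritization and functional-association network analysis.

Stage 1 selects, from the condition-specific interactors, the proteins that
define at least one disease-relevant category: curated biological-process
categories (ECM, inflammation), hallmark gene sets (MYC signaling, EMT,
mitotic spindle, hypoxia, TGF-beta signaling), or oncogene / oncogenic-
signature membership. The bait (YAP1) and CFTR are excluded. Stage 2 keeps
the high-confidence subset: candidates appearing in more than one category
and/or present in the published CFTR interactome.

The surviving candidates are assembled into an undirected network from a
score-weighted edge list (a STRING-style export) at a minimum combined
score — 0.4 being the conventional "medium confidence" cutoff — and ranked
by degree to find hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

#: Category profiles for stage 1. "methods" restricts the curated BP
#: categories to ECM and inflammation; "results" additionally admits the
#: cell-cycle BP category.
CATEGORY_PROFILES: dict[str, frozenset[str]] = {
    "methods": frozenset(
        {"ECM", "inflammation", "MYC", "EMT", "mitotic spindle", "hypoxia", "TGFb", "oncogene"}
    ),
    "results": frozenset(
        {
            "ECM",
            "inflammation",
            "cell cycle",
            "MYC",
            "EMT",
            "mitotic spindle",
            "hypoxia",
            "TGFb",
            "oncogene",
        }
    ),
}


#: Substrings used to recognise the stage-1-relevant hallmark gene sets in a
#: GMT collection (matches both MSigDB naming and abbreviated set names).
HALLMARK_NAME_PATTERNS: dict[str, str] = {
    "MYC": "MYC",
    "EPITHELIAL_MESENCHYMAL": "EMT",
    "EMT": "EMT",
    "MITOTIC_SPINDLE": "mitotic spindle",
    "HYPOXIA": "hypoxia",
    "TGF": "TGFb",
}


def derive_category_genes(
    bp_categorized: pd.DataFrame,
    hallmark_results: pd.DataFrame,
    oncogenic_results: pd.DataFrame,
    max_p: float = 0.05,
    bp_categories: Iterable[str] = ("ECM", "inflammation", "cell cycle"),
) -> dict[str, set[str]]:
    """Collect each category's defining genes from the enrichment outputs.

    ``bp_categorized`` is a thresholded + categorized ORA table; its terms
    contribute to their curated category. Significant hallmark sets map to
    categories by name pattern; genes defining any significant oncogenic
    signature feed the "oncogene" category (the explicit oncogene list is
    merged separately at stage 1).
    """
    out: dict[str, set[str]] = {}
    wanted = set(bp_categories)
    for _, row in bp_categorized.iterrows():
        if row.get("category", "none") in wanted:
            out.setdefault(row["category"], set()).update(
                g for g in str(row["genes"]).split(";") if g
            )
    for _, row in hallmark_results.iterrows():
        if row["p_value"] >= max_p:
            continue
        for pattern, cat in HALLMARK_NAME_PATTERNS.items():
            if pattern in str(row["term"]).upper():
                out.setdefault(cat, set()).update(g for g in str(row["genes"]).split(";") if g)
                break
    for _, row in oncogenic_results.iterrows():
        if row["p_value"] < max_p:
            out.setdefault("oncogene", set()).update(
                g for g in str(row["genes"]).split(";") if g
            )
    return out


@dataclass
class CandidateProtein:
    gene: str
    categories: frozenset[str] = field(default_factory=frozenset)
    cftr_membership: str = "none"  # wt | f508del | both | none
    stage1: bool = False
    stage2: bool = False


def stage1_select(
    specific_interactors: Iterable[str],
    category_genes: Mapping[str, Iterable[str]],
    oncogenes: Iterable[str] = (),
    exclude: Iterable[str] = ("YAP1", "CFTR"),
    profile: str = "methods",
) -> list[CandidateProtein]:
    """Candidates defining at least one disease-relevant category.

    ``category_genes`` maps a category name to the genes defining it
    (typically the enriched terms' defining genes from the enrichment
    stage); ``oncogenes`` contribute to the "oncogene" category. Only
    categories admitted by the chosen profile count.
    """
    allowed = CATEGORY_PROFILES[profile]
    members = {str(g) for g in specific_interactors}
    excluded = {str(g) for g in exclude}
    cat_map: dict[str, set[str]] = {}
    for cat, genes in category_genes.items():
        if cat not in allowed:
            continue
        for g in genes:
            cat_map.setdefault(str(g), set()).add(cat)
    if "oncogene" in allowed:
        for g in oncogenes:
            cat_map.setdefault(str(g), set()).add("oncogene")
    out = []
    for gene in sorted(members - excluded):
        cats = frozenset(cat_map.get(gene, ()))
        if cats:
            out.append(CandidateProtein(gene=gene, categories=cats, stage1=True))
    return out


def stage2_select(
    candidates: Iterable[CandidateProtein],
    cftr_interactome: Mapping[str, str] | Iterable[str] = (),
) -> list[CandidateProtein]:
    """High-confidence filter: multi-category and/or CFTR-interactome members.

    ``cftr_interactome`` is either a mapping gene -> {'wt','f508del','both'}
    or a plain iterable of member genes (membership then recorded as
    'both'). Returns the kept candidates with ``stage2=True`` set.
    """
    if isinstance(cftr_interactome, Mapping):
        membership = {str(k): v for k, v in cftr_interactome.items()}
    else:
        membership = {str(g): "both" for g in cftr_interactome}
    kept = []
    for c in candidates:
        if not c.stage1:
            continue
        c.cftr_membership = membership.get(c.gene, "none")
        c.stage2 = len(c.categories) >= 2 or c.cftr_membership != "none"
        if c.stage2:
            kept.append(c)
    return kept


def candidates_frame(candidates: Iterable[CandidateProtein]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene,
            "categories": ";".join(sorted(c.categories)),
            "n_categories": len(c.categories),
            "cftr_membership": c.cftr_membership,
            "stage1": c.stage1,
            "stage2": c.stage2,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "categories", "n_categories", "cftr_membership", "stage1", "stage2"],
    )


def build_network(
    nodes: Iterable[str],
    edges: pd.DataFrame,
    min_score: float = 0.4,
) -> nx.Graph:
    """Induced subgraph on ``nodes`` keeping edges with score >= ``min_score``.

    ``edges`` needs columns ``node1, node2, combined_score``; scores on a
    0-1000 export scale are normalised to 0-1. Isolated nodes are retained,
    self-loops dropped, duplicate rows collapsed.
    """
    required = {"node1", "node2", "combined_score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    scores = edges["combined_score"].astype(float)
    if len(scores) and scores.max() > 1.0:
        scores = scores / 1000.0
    g = nx.Graph()
    g.add_nodes_from(str(n) for n in nodes)
    for (a, b), s in zip(zip(edges["node1"], edges["node2"]), scores):
        a, b = str(a), str(b)
        if a == b or s < min_score:
            continue
        if a in g and b in g:
            prev = g.edges[a, b]["combined_score"] if g.has_edge(a, b) else -1.0
            if s > prev:
                g.add_edge(a, b, combined_score=float(s))
    return g


def hub_analysis(graph: nx.Graph) -> pd.DataFrame:
    """Degree per node, ranked by degree (descending) then name."""
    rows = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    df["rank"] = range(1, len(df) + 1)
    return df
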