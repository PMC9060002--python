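"""Synthetic annotation, gene-set, reference and network resources.

Given the two conditions' interactor gene sets, this generator plants:

* biological-process terms whose query overlap ("defining genes") is an
  assigned subset of the condition-specific interactors, sized so the
  terms clear the fold-enrichment and p-value gates;
* hallmark and oncogenic-signature GMT collections with the same planting
  scheme, plus inert null sets;
* an oncogene list, a published-CFTR-interactome list and published
  reference interactomes with controlled overlaps;
* a score-weighted edge list over the high-confidence candidates.

Category assignments are constructed so that the two prioritization stages
recover exactly ``n_stage1`` and ``n_stage2_multi + n_stage2_membership``
candidates — the planted ground truth for the network-prioritization stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .. import io

#: The curated vocabulary used to group enriched BP terms.
CURATED_CATEGORIES = (
    "apoptosis",
    "barrier function",
    "cell cycle",
    "cell junction",
    "cytoskeleton",
    "differentiation",
    "ECM",
    "immune system",
    "inflammation",
    "miRNA",
    "stress",
)

#: Stage-1-relevant categories and where each is looked up.
BP_RELEVANT = ("ECM", "inflammation")
HALLMARK_RELEVANT = ("MYC", "EMT", "mitotic spindle", "hypoxia", "TGFb")


@dataclass
class AnnotationResources:
    background: list[str]
    annotation: dict[str, set[str]]
    category_map: dict[str, str]
    hallmark: dict[str, set[str]]
    oncogenic: dict[str, set[str]]
    oncogenes: set[str]
    cftr_interactome: set[str]
    reference_interactomes: list[set[str]]
    edges: pd.DataFrame
    truth: dict


def _planted_term(members: Sequence[str], filler_pool: list[str], rng) -> set[str]:
    # Term size ~1.4x its defining genes keeps FE comfortably above the gates.
    n_filler = max(1, int(0.4 * len(members)))
    filler = list(rng.choice(filler_pool, size=min(n_filler, len(filler_pool)), replace=False))
    return set(members) | set(filler)


def generate_annotation_resources(
    wt_genes: Iterable[str],
    f508del_genes: Iterable[str],
    seed: int = 0,
    background_size: int = 2000,
    n_null_terms: int = 60,
    n_null_sets: int = 15,
    n_stage1: int = 65,
    n_stage2_multi: int = 18,
    n_stage2_membership: int = 12,
    ref_overlap_core: int = 75,
    ref_overlap_wt_specific: int = 4,
    ref_overlap_f508_specific: int = 23,
) -> AnnotationResources:
    """Build the full resource bundle with planted prioritization truth."""
    rng = np.random.default_rng(seed)
    wt = frozenset(map(str, wt_genes))
    f508 = frozenset(map(str, f508del_genes))
    specific = sorted(f508 - wt)
    if len(specific) < n_stage1:
        raise ValueError("not enough condition-specific interactors to plant stage 1")
    if n_stage2_multi + n_stage2_membership > n_stage1:
        raise ValueError("stage-2 plant exceeds stage 1")

    union = sorted(wt | f508)
    n_filler_bg = background_size - len(union)
    if n_filler_bg < 200:
        raise ValueError("background too small")
    filler_bg = [f"BG{i:05d}" for i in range(n_filler_bg)]
    background = union + filler_bg

    picked = list(rng.choice(specific, size=n_stage1, replace=False))
    multi = picked[:n_stage2_multi]
    member_only = picked[n_stage2_multi : n_stage2_multi + n_stage2_membership]
    single = picked[n_stage2_multi + n_stage2_membership :]

    categories = list(BP_RELEVANT) + list(HALLMARK_RELEVANT) + ["oncogene"]
    assignment: dict[str, list[str]] = {c: [] for c in categories}
    for i, g in enumerate(single + member_only):
        assignment[categories[i % len(categories)]].append(g)
    for i, g in enumerate(multi):  # two distinct categories each
        assignment[categories[i % len(categories)]].append(g)
        assignment[categories[(i + 1) % len(categories)]].append(g)

    # --- BP annotation: planted relevant terms + inert null terms -----------
    annotation: dict[str, set[str]] = {}
    category_map: dict[str, str] = {}
    for cat in BP_RELEVANT:
        term = f"BP:{cat.replace(' ', '_')}_planted"
        annotation[term] = _planted_term(assignment[cat], filler_bg, rng)
        category_map[term] = cat
    inert_cats = [c for c in CURATED_CATEGORIES if c not in BP_RELEVANT]
    for i in range(n_null_terms):
        term = f"BP:null_{i:03d}"
        size = int(rng.integers(30, 120))
        annotation[term] = set(rng.choice(filler_bg, size=size, replace=False))
        if i % 3 == 0:  # some null terms carry an (irrelevant) curated category
            category_map[term] = inert_cats[i % len(inert_cats)]

    # --- hallmark / oncogenic GMT collections -------------------------------
    hallmark: dict[str, set[str]] = {}
    for cat in HALLMARK_RELEVANT:
        name = f"HALLMARK_{cat.replace(' ', '_').upper()}"
        hallmark[name] = _planted_term(assignment[cat], filler_bg, rng)
    for i in range(n_null_sets):
        size = int(rng.integers(40, 150))
        hallmark[f"HALLMARK_NULL_{i:02d}"] = set(rng.choice(filler_bg, size=size, replace=False))

    oncogenic: dict[str, set[str]] = {
        "ONC_SIG_PLANTED": _planted_term(assignment["oncogene"], filler_bg, rng)
    }
    for i in range(n_null_sets):
        size = int(rng.integers(40, 150))
        oncogenic[f"ONC_SIG_NULL_{i:02d}"] = set(rng.choice(filler_bg, size=size, replace=False))
    oncogenes = set(assignment["oncogene"])

    # --- reference lists -----------------------------------------------------
    cftr_interactome = set(member_only) | set(
        rng.choice(filler_bg, size=50, replace=False)
    )  # planted members + padding outside the query
    core = sorted(wt & f508)
    wt_only = sorted(wt - f508)
    ref = (
        list(rng.choice(core, size=ref_overlap_core, replace=False))
        + list(rng.choice(wt_only, size=min(ref_overlap_wt_specific, len(wt_only)), replace=False))
        + list(rng.choice(specific, size=ref_overlap_f508_specific, replace=False))
        + list(rng.choice(filler_bg, size=100, replace=False))
    )
    reference_interactomes = [set(ref[: len(ref) // 2]), set(ref[len(ref) // 2 :])]

    # --- edge list over the high-confidence candidates ----------------------
    stage2 = sorted(multi + member_only)
    nodes = stage2 + ["YAP1", "CFTR"]
    edge_rows = []
    degrees = {n: 0 for n in nodes}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            r = rng.random()
            if r < 0.15:
                edge_rows.append(
                    {"node1": a, "node2": b, "combined_score": float(rng.uniform(0.4, 1.0))}
                )
                degrees[a] += 1
                degrees[b] += 1
            elif r < 0.25:  # sub-threshold edge, must be dropped at medium confidence
                edge_rows.append(
                    {"node1": a, "node2": b, "combined_score": float(rng.uniform(0.05, 0.39))}
                )
    edges = pd.DataFrame(edge_rows, columns=["node1", "node2", "combined_score"])

    truth = {
        "stage1": sorted(picked),
        "stage2": stage2,
        "assignment": {c: sorted(g) for c, g in assignment.items()},
        "degrees": degrees,
        "planted_bp_terms": [f"BP:{c.replace(' ', '_')}_planted" for c in BP_RELEVANT],
        "ref_overlap_wt": ref_overlap_core + ref_overlap_wt_specific,
        "ref_overlap_f508del": ref_overlap_core + ref_overlap_f508_specific,
    }
    return AnnotationResources(
        background=background,
        annotation=annotation,
        category_map=category_map,
        hallmark=hallmark,
        oncogenic=oncogenic,
        oncogenes=oncogenes,
        cftr_interactome=cftr_interactome,
        reference_interactomes=reference_interactomes,
        edges=edges,
        truth=truth,
    )


def generate_null_ora_instance(
    seed: int = 0,
    background_size: int = 2000,
    query_size: int = 200,
    n_terms: int = 500,
    term_size_range: tuple[int, int] = (50, 150),
) -> tuple[set[str], dict[str, set[str]], list[str]]:
    """A no-signal ORA instance: random query, random terms, shared background.

    Under this null the hypergeometric p-values are (discretely) uniform,
    so ~5% of terms fall below p = 0.05.
    """
    rng = np.random.default_rng(seed)
    background = [f"G{i:05d}" for i in range(background_size)]
    query = set(rng.choice(background, size=query_size, replace=False))
    annotation = {
        f"T{i:04d}": set(
            rng.choice(background, size=int(rng.integers(*term_size_range)), replace=False)
        )
        for i in range(n_terms)
    }
    return query, annotation, background


def write_resources(res: AnnotationResources, outdir: str | Path) -> None:
    """Serialize the bundle in the pipeline's file formats (round-trippable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_annotation(res.annotation, outdir / "annotation_bp.tsv")
    io.write_gmt(res.hallmark, outdir / "hallmark.gmt")
    io.write_gmt(res.oncogenic, outdir / "oncogenic.gmt")
    io.write_gene_list(res.background, outdir / "background.txt")
    io.write_gene_list(sorted(res.oncogenes), outdir / "oncogenes.txt")
    io.write_gene_list(sorted(res.cftr_interactome), outdir / "cftr_interactome.txt")
    for i, ref in enumerate(res.reference_interactomes):
        io.write_gene_list(sorted(ref), outdir / f"reference_interactome_{i}.txt")
    with open(outdir / "category_map.tsv", "w") as fh:
        for term, cat in res.category_map.items():
            fh.write(f"{term}\t{cat}\n")
    res.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
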