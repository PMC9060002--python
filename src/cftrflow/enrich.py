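"""Over-representation analysis (ORA) with fold-enrichment thresholds.

Given an unranked query gene list, an annotation (term -> genes) and a
background universe, each term is scored by the hypergeometric upper tail
(Fisher's one-sided test) and by its fold enrichment

    FE = (k/n) / (K/N)

with k the query/term overlap, n the query size, K the term size and N the
background size. P-values are corrected by Benjamini-Hochberg within one
collection. The same machinery serves GO biological-process terms (reported
as fold enrichment at p < 0.05, thresholded at FE > 8.5 for the
differential figure and FE > 15 for the global one) and hallmark/oncogenic
signature collections in GMT form (reported as -log10 FDR).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["term", "k", "n", "K", "N", "fold_enrichment", "p_value", "fdr"]


def ora(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against an annotation.

    Only terms with overlap k >= 1 are reported. Query genes must all be
    members of the background; offenders are listed in the error message.
    Returns one row per tested term with columns ``RESULT_COLUMNS`` plus
    ``genes`` (the sorted overlap, semicolon-joined).
    """
    bg = frozenset(background)
    q = frozenset(query)
    stray = sorted(q - bg)
    if stray:
        raise ValueError(f"query genes absent from background: {stray[:10]}")
    n, N = len(q), len(bg)
    rows = []
    for term, genes in annotation.items():
        term_genes = frozenset(genes) & bg
        overlap = q & term_genes
        k, K = len(overlap), len(term_genes)
        if k == 0 or K == 0:
            continue
        fe = (k / n) / (K / N)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fe,
                "p_value": p,
                "genes": ";".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS + ["genes"])
    df = pd.DataFrame(rows).sort_values("term").reset_index(drop=True)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df[RESULT_COLUMNS + ["genes"]]


def filter_and_threshold(
    results: pd.DataFrame,
    max_p: float = 0.05,
    min_fold_enrichment: float = 8.5,
) -> pd.DataFrame:
    """Keep terms with p strictly below ``max_p`` and FE strictly above the cutoff.

    The cutoff profile used is recorded in ``df.attrs['fe_cutoff']``.
    """
    out = results[
        (results["p_value"] < max_p) & (results["fold_enrichment"] > min_fold_enrichment)
    ].reset_index(drop=True)
    out.attrs["fe_cutoff"] = min_fold_enrichment
    out.attrs["p_cutoff"] = max_p
    return out


def categorize(results: pd.DataFrame, category_map: Mapping[str, str]) -> pd.DataFrame:
    """Attach manually curated category labels to enriched terms.

    ``category_map`` maps term -> category (at most one per term; the
    curated vocabulary of this pipeline has 11 categories). Unmapped terms
    get ``"none"``.
    """
    out = results.copy()
    out["category"] = [category_map.get(t, "none") for t in out["term"]]
    return out


def signature_ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """ORA over a GMT collection, reported as -log10 FDR."""
    df = ora(query, gene_sets, background)
    with np.errstate(divide="ignore"):
        df["neg_log10_fdr"] = -np.log10(df["fdr"])
    return df


def flag_exclusive(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Compare two conditions' signature results; mark sets enriched in one only.

    Returns a table with one row per set significant in either condition and
    an ``exclusive_to`` column in {'a', 'b', 'shared'}.
    """
    sig_a = set(results_a.loc[results_a["p_value"] < max_p, "term"])
    sig_b = set(results_b.loc[results_b["p_value"] < max_p, "term"])
    rows = []
    for term in sorted(sig_a | sig_b):
        where = "shared" if term in sig_a and term in sig_b else ("a" if term in sig_a else "b")
        rows.append({"term": term, "exclusive_to": where})
    return pd.DataFrame(rows, columns=["term", "exclusive_to"])


def defining_genes(results: pd.DataFrame) -> dict[str, list[str]]:
    """The overlap genes that define each reported term, sorted."""
    return {t: g.split(";") if g else [] for t, g in zip(results["term"], results["genes"])}
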