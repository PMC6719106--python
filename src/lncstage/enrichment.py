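"""Hypergeometric over-representation of gene sets against a term map.

A plain upper-tail hypergeometric test with Benjamini-Hochberg adjustment.
Length-bias corrections (Wallenius-type) and live GO/KEGG databases are
deliberately out of scope: the term map is a user-supplied table.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeometric_enrichment", "bh_adjust", "read_term2gene", "top_terms"]


def read_term2gene(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"term_id", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"term table missing columns: {sorted(missing)}")
    return df


def hypergeometric_enrichment(
    study: set[str], population: set[str], term2genes: dict[str, set[str]]
) -> pd.DataFrame:
    """Upper-tail hypergeometric P(X >= k) per term, BH-adjusted.

    ``study`` must be a subset of ``population``; each term's gene set is
    intersected with the population first. Terms with no study hits are
    reported with p = 1. Results are sorted by p, then term id.
    """
    strays = set(study) - set(population)
    if strays:
        raise ValueError(f"study genes outside the population: {sorted(strays)[:10]}")
    N, n = len(population), len(study)
    rows = []
    for term_id in sorted(term2genes):
        genes = set(term2genes[term_id]) & set(population)
        K = len(genes)
        k = len(genes & set(study))
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.reindex(columns=["term_id", "k", "K", "n", "N", "p_value", "q_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [p, 1])."""
    import numpy as np

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return list(np.maximum(q, p))


def top_terms(results: pd.DataFrame, n_go: int = 10, n_pathway: int = 20) -> dict:
    """Top-N rows in the two sizes conventionally displayed (GO-like and
    pathway-like term lists)."""
    return {
        "top_go_like": results.head(n_go),
        "top_pathway_like": results.head(n_pathway),
    }
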