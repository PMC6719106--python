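"""Cross-species lncRNA conservation from tabular homology hits.

Hits are consumed as outfmt-6-style tables (query, subject, species,
evalue, bitscore). Matching is query-level set semantics: a lncRNA with ten
hits counts once. E-value thresholds are strict (<); conservation-score
filtering is strict (> 0.8). The loose-vs-strict retention contrast per
species is tested with a two-sided Fisher's exact test.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

__all__ = [
    "filter_hits_by_evalue",
    "matched_fraction",
    "reciprocal_match",
    "filter_by_score",
    "stringency_contrast",
    "read_hits",
]

HIT_COLUMNS = ["query", "subject", "species", "evalue", "bitscore"]


def read_hits(path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("negative E-values in hit table")
    return hits


def filter_hits_by_evalue(hits: pd.DataFrame, threshold: float) -> set[str]:
    """Queries with at least one hit at E-value strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("E-value threshold must be > 0")
    return set(hits.loc[hits["evalue"] < threshold, "query"])


def matched_fraction(total: int, matched: int) -> dict:
    """Matched percentage, raw and rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= matched <= total:
        raise ValueError("matched must lie in [0, total]")
    raw = 100.0 * matched / total
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return {"total": total, "matched": matched, "percent_raw": raw, "percent": rounded}


def reciprocal_match(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, threshold: float
) -> set[str]:
    """Query ids matched in both directions (two-way alignment support).

    An id is retained when it passes the E-value filter as a query in the
    forward table and also appears as the subject of a passing hit in the
    reverse table.
    """
    forward = filter_hits_by_evalue(hits_ab, threshold)
    reverse_subjects = set(hits_ba.loc[hits_ba["evalue"] < threshold, "subject"])
    return forward & reverse_subjects


def filter_by_score(scores: pd.DataFrame, min_score: float) -> list[str]:
    """lncRNA ids whose conservation score strictly exceeds ``min_score``."""
    if ((scores["score"] < 0) | (scores["score"] > 1)).any():
        bad = scores.loc[(scores["score"] < 0) | (scores["score"] > 1), "lncrna_id"]
        raise ValueError(f"conservation scores outside [0,1]: {list(bad[:5])}")
    return sorted(scores.loc[scores["score"] > min_score, "lncrna_id"])


def stringency_contrast(
    species_loose: int, species_strict: int, bg_loose: int, bg_strict: int
) -> float:
    """Two-sided Fisher's exact p for loose-to-strict retention vs background.

    The 2x2 table rows are {species, background}, columns are {retained at
    strict, lost between loose and strict}; the two-sided p sums the
    probabilities of all tables with fixed margins whose point probability
    does not exceed the observed one.
    """
    if species_strict > species_loose or bg_strict > bg_loose:
        raise ValueError("strict counts cannot exceed loose counts")
    if min(species_loose, species_strict, bg_loose, bg_strict) < 0:
        raise ValueError("counts must be non-negative")
    table = [
        [species_strict, species_loose - species_strict],
        [bg_strict, bg_loose - bg_strict],
    ]
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in row_sums or 0 in col_sums:
        warnings.warn("degenerate contingency table (zero margin); p = 1.0", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
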