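"""Stage-wise differential expression over the 7-stage x 3-replicate design.

A Welch two-sample t-test on log2(FPKM+1) between stage replicate groups
serves as the DE model; with n = 3 per group no multiplicity correction is
applied by default (raw p < alpha), though BH-adjusted flags are available.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .config import STAGE_ORDER, PipelineConfig
from .expression import ExpressionMatrix

__all__ = ["pairwise_de", "all_pairs_de", "de_union", "stage_detection_summary"]


def pairwise_de(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Per-feature Welch t-test between two stages on log2(FPKM+1).

    ``log2_fc`` is mean(stage_b) - mean(stage_a) so positive means up in the
    second stage; the pipeline always calls with the earlier stage first.
    Swapping the stages flips the sign and direction and leaves p unchanged.
    Features with zero variance in both groups get p = 1 when
    the group means are equal and p = 0 otherwise (the infinite-t limit).
    """
    for s in (stage_a, stage_b):
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage label {s!r}")
    log2 = expr.log2()
    xa = log2[expr.samples_of_stage(stage_a)].to_numpy()
    xb = log2[expr.samples_of_stage(stage_b)].to_numpy()
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("each stage needs >= 2 replicates")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
    log2_fc = xb.mean(axis=1) - xa.mean(axis=1)
    both_flat = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
    p = np.where(both_flat & (log2_fc == 0), 1.0, p)
    p = np.where(both_flat & (log2_fc != 0), 0.0, p)
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "stage_a": stage_a,
            "stage_b": stage_b,
            "log2_fc": log2_fc,
            "p_value": p,
            "direction": np.where(log2_fc >= 0, "up", "down"),
            "de": p < config.de_alpha,
        }
    )


def all_pairs_de(expr: ExpressionMatrix, config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Welch DE for all 21 unordered stage pairs, earlier stage first."""
    frames = [
        pairwise_de(expr, a, b, config)
        for a, b in combinations([s for s in STAGE_ORDER if s in expr.stages], 2)
    ]
    return pd.concat(frames, ignore_index=True)


def de_union(results: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Union of DE features over all tested pairs plus per-pair up/down counts.

    Returns the sorted DE feature list and a per-pair summary with the
    adjacent developmental transitions flagged.
    """
    if results.empty:
        return [], pd.DataFrame(columns=["stage_a", "stage_b", "adjacent", "n_up", "n_down"])
    de = results[results["de"]]
    union = sorted(de["feature_id"].unique())
    adjacent = set(zip(STAGE_ORDER, STAGE_ORDER[1:]))
    rows = []
    for (a, b), grp in results.groupby(["stage_a", "stage_b"], sort=False):
        sub = grp[grp["de"]]
        rows.append(
            {
                "stage_a": a,
                "stage_b": b,
                "adjacent": (a, b) in adjacent,
                "n_up": int((sub["direction"] == "up").sum()),
                "n_down": int((sub["direction"] == "down").sum()),
            }
        )
    return union, pd.DataFrame(rows)


def stage_detection_summary(
    expr: ExpressionMatrix, config: PipelineConfig = PipelineConfig()
) -> dict:
    """Detected-stage sets per feature and the share detected in all stages.

    A feature counts as detected in a stage when its mean FPKM over that
    stage's replicates exceeds ``detection_fpkm_min``. The shared-in-all
    percentage is reported integer-rounded (half-up), matching how such
    Venn overlaps are conventionally quoted.
    """
    stages = expr.stages
    means = pd.DataFrame(
        {s: expr.values[expr.samples_of_stage(s)].mean(axis=1) for s in stages}
    )
    detected = means > config.detection_fpkm_min
    sets = {f: [s for s in stages if detected.at[f, s]] for f in expr.feature_ids}
    n_total = len(expr.feature_ids)
    n_all = int(detected.all(axis=1).sum())
    from .conservation import matched_fraction

    pct = matched_fraction(n_total, n_all)["percent_raw"] if n_total else 0.0
    return {
        "detected_stages": sets,
        "n_total": n_total,
        "n_detected_in_all": n_all,
        "percent_detected_in_all": int(np.floor(pct + 0.5)),
    }
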