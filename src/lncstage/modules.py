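"""Signed weighted co-expression network and temporal module detection.

The chain is the classical weighted-network construction: Pearson
correlation on log2(FPKM+1), a soft-threshold power chosen by the
scale-free-topology criterion, signed adjacency a_ij = ((1+r_ij)/2)^beta,
the topological overlap matrix (TOM), average-linkage clustering of
1 - TOM, a static branch cut with a minimum module size, module eigengenes
(first singular vector of the standardized module expression), and
eigengene-stage correlation with Student-t p-values over the 21 samples.

Modules are finally classified by which stages they correlate with
significantly (r > 0.6 and p < 0.05 by default): ``early`` when >= 2
significant stages, all fetal-early (F45/F65/F90); ``late`` when >= 2, all
late (F135/B1/B90); ``stage_specific`` when exactly one; ``mixed`` or
``none`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import EARLY_STAGES, LATE_STAGES, STAGE_ORDER, PipelineConfig
from .expression import ExpressionMatrix

__all__ = [
    "pearson_matrix",
    "pick_soft_threshold",
    "signed_adjacency",
    "tom_similarity",
    "average_linkage",
    "tree_cut_modules",
    "kme_cleanup",
    "module_eigengene",
    "module_trait_correlation",
    "classify_temporal_modules",
    "detect_modules",
    "ModuleEigengene",
]

#: Conventional color aliases, assigned in decreasing module-size order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

GREY = "grey"  # reserved for unassigned features


def pearson_matrix(expr: ExpressionMatrix, feature_ids=None) -> pd.DataFrame:
    """Pearson correlation between features on log2(FPKM+1).

    Zero-variance features are an error: they must be removed upstream.
    """
    x = expr.log2()
    if feature_ids is not None:
        x = x.loc[list(feature_ids)]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = x.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance features: {flat[:5]}")
    cor = np.corrcoef(x.to_numpy())
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=x.index, columns=x.index)


def signed_adjacency(cor: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + r_ij) / 2) ** beta, diagonal forced to 1."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    a = ((1.0 + cor.to_numpy()) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def pick_soft_threshold(
    cor: pd.DataFrame,
    powers=range(1, 21),
    fit_target: float = 0.8,
    fallback: int = 12,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by the scale-free-topology criterion.

    For each candidate power, connectivities k_i are binned (10 log-spaced
    bins) and log10(frequency) is regressed on log10(mean k); the signed fit
    index is R^2 times the sign of the negative slope. The chosen beta is the
    smallest power whose signed R^2 reaches ``fit_target``, else the argmax;
    a degenerate (all-equal-k) network falls back to ``fallback``.
    """
    rows = []
    for beta in powers:
        a = signed_adjacency(cor, beta).to_numpy()
        k = a.sum(axis=0) - 1.0
        rows.append({"power": beta, **_scale_free_fit(k),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    if table["signed_r2"].isna().all():
        import warnings

        warnings.warn("degenerate connectivity distribution; falling back", stacklevel=2)
        return fallback, table
    ok = table[table["signed_r2"] >= fit_target]
    beta = int(ok["power"].iloc[0]) if not ok.empty else int(
        table.loc[table["signed_r2"].idxmax(), "power"]
    )
    return beta, table


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> dict:
    """Signed R^2 of the log-log degree-distribution fit."""
    if k.max() - k.min() < 1e-12:
        return {"signed_r2": np.nan, "slope": np.nan}
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return {"signed_r2": np.nan, "slope": np.nan}
    res = stats.linregress(xs, ys)
    return {"signed_r2": float(res.rvalue**2 * np.sign(-res.slope)), "slope": float(res.slope)}


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap of a [0,1] adjacency matrix.

    With k_i = sum_{u != i} a_iu and l_ij = sum_{u != i,j} a_iu * a_uj:

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),  TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    off = a - np.diag(np.diag(a))
    k = off.sum(axis=0)
    # off has a zero diagonal, so (off @ off)_ij already omits the u=i, u=j terms
    l = off @ off
    denom = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + off) / denom
    tom[~np.isfinite(tom)] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def average_linkage(dissimilarity: pd.DataFrame) -> np.ndarray:
    """UPGMA merge table (scipy linkage format) of a dissimilarity matrix."""
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    dd = d.copy()
    np.fill_diagonal(dd, 0.0)
    return linkage(squareform(dd, checks=False), method="average")


def tree_cut_modules(
    merges: np.ndarray,
    feature_ids,
    min_module_size: int = 20,
    cut_height: float | None = None,
    cut_height_fraction: float = 0.995,
) -> pd.Series:
    """Static branch cut of a dendrogram into size-filtered modules.

    Branches below ``cut_height`` (default: 99.5% of the maximum merge
    height) with at least ``min_module_size`` members become modules,
    labelled by color aliases in decreasing size order (ties broken by the
    smallest member id); everything else is 'grey'.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    feature_ids = list(feature_ids)
    if cut_height is None:
        cut_height = cut_height_fraction * float(merges[:, 2].max()) if len(merges) else 0.0
    raw = fcluster(merges, t=cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for fid, c in zip(feature_ids, raw):
        groups.setdefault(int(c), []).append(fid)
    big = [members for members in groups.values() if len(members) >= min_module_size]
    big.sort(key=lambda m: (-len(m), min(m)))
    labels = pd.Series(GREY, index=pd.Index(feature_ids, name="feature_id"), name="module")
    for rank, members in enumerate(big):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.loc[members] = color
    return labels


def kme_cleanup(
    expr: ExpressionMatrix,
    labels: pd.Series,
    kme_min: float = 0.7,
    min_module_size: int = 20,
) -> pd.Series:
    """Return weakly attached module members to grey.

    A static branch cut tends to absorb chance-correlated features into
    module branches. The standard remedy is a module-membership (kME)
    filter: each assigned feature must correlate with its own module's
    eigengene at r >= ``kme_min``; modules falling below the minimum size
    afterwards dissolve into grey entirely. Labels are re-ranked by size.
    """
    labels = labels.copy()
    log2 = expr.log2()
    for module in sorted(set(labels) - {GREY}):
        members = list(labels.index[labels == module])
        eg = module_eigengene(expr, members).values.to_numpy()
        x = log2.loc[members].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        ze = (eg - eg.mean()) / eg.std(ddof=1)
        kme = z @ ze / (len(eg) - 1)
        weak = [m for m, r in zip(members, kme) if r < kme_min]
        labels.loc[weak] = GREY
    # dissolve undersized modules, then re-rank colors by size
    sizes = labels.value_counts()
    for module in sizes.index:
        if module != GREY and sizes[module] < min_module_size:
            labels.loc[labels == module] = GREY
    groups = [
        list(labels.index[labels == m]) for m in set(labels) if m != GREY
    ]
    groups.sort(key=lambda g: (-len(g), min(g)))
    out = pd.Series(GREY, index=labels.index, name="module")
    for rank, members in enumerate(groups):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        out.loc[members] = color
    return out


@dataclass
class ModuleEigengene:
    module: str
    values: pd.Series          # per-sample, unit Euclidean norm
    variance_explained: float
    orientation_sign: int


def module_eigengene(expr: ExpressionMatrix, feature_ids) -> ModuleEigengene:
    """First right singular vector of the standardized module expression.

    Rows are z-scored per feature across samples (ddof=1); the eigengene is
    oriented so that it correlates positively with the per-sample mean of
    the standardized rows; variance_explained is s1^2 / sum(s^2).
    """
    feature_ids = list(feature_ids)
    if len(feature_ids) < 2:
        raise ValueError("a module needs >= 2 features")
    x = expr.log2().loc[feature_ids].to_numpy()
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [feature_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant expression rows in module: {bad[:5]}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    sign = 1
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig, sign = -eig, -1
    return ModuleEigengene(
        module="",
        values=pd.Series(eig, index=expr.sample_ids),
        variance_explained=float(s[0] ** 2 / np.sum(s**2)),
        orientation_sign=sign,
    )


def module_trait_correlation(
    eigengene: pd.Series,
    sample_meta: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Eigengene vs one-hot stage indicators: r, t, df, p, significance.

    p is the two-sided Student-t tail with df = n - 2; |r| = 1 maps to
    p = 0 exactly. A stage is called significant when r exceeds the
    configured threshold (positive, strict) and p < alpha.
    """
    stages = [s for s in STAGE_ORDER if s in set(sample_meta["stage"])]
    e = eigengene.loc[sample_meta.index].to_numpy(dtype=float)
    n = len(e)
    rows = []
    for stage in stages:
        x = (sample_meta["stage"] == stage).to_numpy(dtype=float)
        r = float(np.corrcoef(e, x)[0, 1])
        df = n - 2
        if abs(r) >= 1.0:
            r = float(np.sign(r))
            t, p = float("inf") * np.sign(r), 0.0
        else:
            t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
            p = 2.0 * stats.t.sf(abs(t), df)
        rows.append(
            {
                "stage": stage,
                "r": r,
                "t_stat": t,
                "df": df,
                "p_value": p,
                "significant": (r > config.module_trait_r_min) and (p < config.module_trait_alpha),
            }
        )
    return pd.DataFrame(rows)


def student_t_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p for a Pearson correlation at sample size n."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df))


def classify_temporal_modules(trait_stats: dict[str, pd.DataFrame]) -> dict[str, str]:
    """Temporal class per module from its significant positive stages.

    early: >= 2 significant stages, all within {F45,F65,F90};
    late: >= 2, all within {F135,B1,B90}; stage_specific: exactly 1;
    none: no significant stage; mixed: anything else.
    """
    classes = {}
    for module, df in trait_stats.items():
        sig = set(df.loc[df["significant"], "stage"])
        if not sig:
            classes[module] = "none"
        elif len(sig) == 1:
            classes[module] = "stage_specific"
        elif sig <= EARLY_STAGES:
            classes[module] = "early"
        elif sig <= LATE_STAGES:
            classes[module] = "late"
        else:
            classes[module] = "mixed"
    return classes


def detect_modules(
    expr: ExpressionMatrix,
    feature_ids,
    config: PipelineConfig = PipelineConfig(),
    beta: int | None = None,
) -> dict:
    """Full chain: correlation -> soft power -> adjacency -> TOM -> UPGMA ->
    static cut -> eigengenes -> stage correlations -> temporal classes.

    Returns a dict with the module labels, the chosen power and fit table,
    eigengenes, per-module trait statistics and temporal classes.
    """
    cor = pearson_matrix(expr, feature_ids)
    fit_table = None
    if beta is None:
        beta, fit_table = pick_soft_threshold(
            cor,
            powers=range(1, config.soft_power_max + 1),
            fit_target=config.scale_free_fit_target,
            fallback=config.soft_power_fallback,
        )
    adj = signed_adjacency(cor, beta)
    tom = tom_similarity(adj)
    merges = average_linkage(1.0 - tom)
    labels = tree_cut_modules(
        merges,
        tom.index,
        min_module_size=config.min_module_size,
        cut_height_fraction=config.cut_height_fraction,
    )
    labels = kme_cleanup(
        expr, labels, kme_min=config.kme_min, min_module_size=config.min_module_size
    )
    eigengenes: dict[str, ModuleEigengene] = {}
    trait_stats: dict[str, pd.DataFrame] = {}
    for module in sorted(set(labels) - {GREY}):
        members = labels.index[labels == module]
        eg = module_eigengene(expr, members)
        eg.module = module
        eigengenes[module] = eg
        trait_stats[module] = module_trait_correlation(eg.values, expr.sample_meta, config)
    return {
        "labels": labels,
        "beta": beta,
        "fit_table": fit_table,
        "merges": merges,
        "eigengenes": eigengenes,
        "trait_stats": trait_stats,
        "temporal_classes": classify_temporal_modules(trait_stats),
    }
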