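"""lncRNA target prediction and the bipartite hub network.

Two evidence modes produce lncRNA -> coding-gene edges: genomic proximity
(cis, within an inclusive 100 kb span-to-span window) and co-expression
(|Pearson r| strictly above 0.95 on log2(FPKM+1)). Edges are assembled into
a bipartite network restricted to lncRNAs passing the fold-change/p filter,
and hub lncRNAs are those with degree strictly above 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel
from .config import PipelineConfig
from .expression import ExpressionMatrix

__all__ = [
    "TargetEdge",
    "cis_targets",
    "coexpression_targets",
    "build_network",
    "hub_lncrnas",
]


@dataclass(frozen=True)
class TargetEdge:
    lncrna_id: str
    mrna_gene_id: str
    mode: str                     # 'cis' | 'coexpression'
    distance_bp: int | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "cis":
            if self.distance_bp is None or self.r is not None:
                raise ValueError("cis edges carry a distance and no correlation")
            if self.distance_bp < 0:
                raise ValueError("distance must be non-negative")
        elif self.mode == "coexpression":
            if self.r is None or self.distance_bp is not None:
                raise ValueError("coexpression edges carry r and no distance")
            if not -1.0 <= self.r <= 1.0:
                raise ValueError("r must lie in [-1, 1]")
        else:
            raise ValueError(f"unknown edge mode {self.mode!r}")


def cis_targets(
    lnc: TranscriptModel,
    genes: list[GeneModel],
    window: int | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> list[TargetEdge]:
    """Coding genes whose span lies within ``window`` bp of the lncRNA span.

    The gap is span-to-span (0 for overlap) and the window is inclusive;
    strand is ignored; only same-chromosome genes are considered.
    """
    if window is None:
        window = config.cis_window_bp
    span = lnc.span
    edges = []
    for g in genes:
        if g.biotype != "mRNA" or g.span.chrom != span.chrom:
            continue
        gap = span.gap_to(g.span)
        if gap <= window:
            edges.append(TargetEdge(lnc.transcript_id, g.gene_id, "cis", distance_bp=gap))
    return edges


def coexpression_targets(
    expr: ExpressionMatrix,
    lnc_ids,
    mrna_ids,
    min_abs_r: float | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> list[TargetEdge]:
    """lncRNA-mRNA pairs with |Pearson r| strictly above the threshold."""
    if min_abs_r is None:
        min_abs_r = config.coexpr_abs_r_min
    lnc_ids, mrna_ids = list(lnc_ids), list(mrna_ids)
    if not lnc_ids or not mrna_ids:
        return []
    x = expr.log2()
    xl = x.loc[lnc_ids].to_numpy()
    xm = x.loc[mrna_ids].to_numpy()

    def _drop_flat(mat, ids):
        sd = mat.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"skipping zero-variance features: {[i for i, f in zip(ids, flat) if f][:5]}",
                stacklevel=2,
            )
        return mat[~flat], [i for i, f in zip(ids, flat) if not f]

    xl, lnc_ids = _drop_flat(xl, lnc_ids)
    xm, mrna_ids = _drop_flat(xm, mrna_ids)
    if not len(lnc_ids) or not len(mrna_ids):
        return []
    zl = (xl - xl.mean(axis=1, keepdims=True)) / xl.std(axis=1, ddof=1, keepdims=True)
    zm = (xm - xm.mean(axis=1, keepdims=True)) / xm.std(axis=1, ddof=1, keepdims=True)
    r = np.clip(zl @ zm.T / (xl.shape[1] - 1), -1.0, 1.0)
    edges = []
    for i, j in zip(*np.where(np.abs(r) > min_abs_r)):
        edges.append(TargetEdge(lnc_ids[i], mrna_ids[j], "coexpression", r=float(r[i, j])))
    return edges


def build_network(
    de_results: pd.DataFrame,
    lnc_ids,
    edges: list[TargetEdge],
    config: PipelineConfig = PipelineConfig(),
) -> nx.Graph:
    """Bipartite lncRNA-mRNA network over fold-change-filtered lncRNAs.

    A lncRNA node is admitted when some stage pair is significant
    (p < de_alpha) and its maximum |log2FC| over all pairs reaches
    log2(fc_min). Parallel cis/coexpression evidence for one pair collapses
    to a single edge keeping both evidence records.
    """
    lnc_ids = set(lnc_ids)
    sub = de_results[de_results["feature_id"].isin(lnc_ids)]
    admitted = set()
    for fid, grp in sub.groupby("feature_id"):
        if (grp["p_value"] < config.de_alpha).any() and (
            grp["log2_fc"].abs().max() >= np.log2(config.fc_min)
        ):
            admitted.add(fid)
    g = nx.Graph()
    for e in edges:
        if e.lncrna_id not in admitted:
            continue
        if not g.has_node(e.lncrna_id):
            g.add_node(e.lncrna_id, kind="lncRNA")
        if not g.has_node(e.mrna_gene_id):
            g.add_node(e.mrna_gene_id, kind="mRNA")
        if g.has_edge(e.lncrna_id, e.mrna_gene_id):
            g.edges[e.lncrna_id, e.mrna_gene_id]["evidence"].append(e)
        else:
            g.add_edge(e.lncrna_id, e.mrna_gene_id, evidence=[e])
    g.graph["admitted_lncrnas"] = sorted(admitted)
    return g


def hub_lncrnas(
    network: nx.Graph,
    min_degree: int | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[tuple[str, int]], dict[str, nx.Graph]]:
    """Hub lncRNAs (degree strictly above the cut) and their star subnetworks.

    Hubs are ranked by decreasing degree, ties broken lexicographically.
    """
    if min_degree is None:
        min_degree = config.hub_min_degree
    hubs = [
        (n, d)
        for n, d in network.degree()
        if network.nodes[n].get("kind") == "lncRNA" and d > min_degree
    ]
    hubs.sort(key=lambda nd: (-nd[1], nd[0]))
    subnets = {
        n: network.subgraph([n] + list(network.neighbors(n))).copy() for n, _ in hubs
    }
    return hubs, subnets


def edges_to_frame(edges: list[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": e.lncrna_id,
                "mrna_gene_id": e.mrna_gene_id,
                "mode": e.mode,
                "distance_bp": e.distance_bp,
                "r": e.r,
            }
            for e in edges
        ],
        columns=["lncrna_id", "mrna_gene_id", "mode", "distance_bp", "r"],
    )
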