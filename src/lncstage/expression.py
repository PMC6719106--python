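"""FPKM expression matrix over staged, replicated samples."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import STAGE_ORDER

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "log2p1",
]


def log2p1(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """log2(FPKM + 1): the working scale for DE, correlation and networks."""
    return np.log2(values + 1.0)


@dataclass
class ExpressionMatrix:
    """FPKM values (features x samples) plus a sample sheet.

    ``sample_meta`` is indexed by sample id with columns ``stage`` and
    ``replicate``; stages must come from the seven-stage design and sample
    columns must match the sheet exactly.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM matrix contains negative values")
        if set(self.values.columns) != set(self.sample_meta.index):
            raise ValueError("expression columns and sample sheet disagree")
        unknown = set(self.sample_meta["stage"]) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage labels: {sorted(unknown)}")
        # order samples by stage, then replicate, for deterministic output
        order = self.sample_meta.sort_values(
            by=["stage", "replicate"],
            key=lambda s: s.map({st: i for i, st in enumerate(STAGE_ORDER)})
            if s.name == "stage"
            else s,
        ).index
        self.sample_meta = self.sample_meta.loc[order]
        self.values = self.values.loc[:, order]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        present = set(self.sample_meta["stage"])
        return [s for s in STAGE_ORDER if s in present]

    def samples_of_stage(self, stage: str) -> list[str]:
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")
        return list(self.sample_meta.index[self.sample_meta["stage"] == stage])

    def log2(self) -> pd.DataFrame:
        return log2p1(self.values)

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(feature_ids)],
            sample_meta=self.sample_meta.copy(),
        )


def write_expression(expr: ExpressionMatrix, expr_path, samples_path) -> None:
    expr.values.rename_axis("feature_id").to_csv(expr_path, sep="\t")
    expr.sample_meta.rename_axis("sample").to_csv(samples_path, sep="\t")


def read_expression(expr_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(Path(expr_path), sep="\t", index_col="feature_id")
    meta = pd.read_csv(Path(samples_path), sep="\t", index_col="sample")
    return ExpressionMatrix(values=values, sample_meta=meta)
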