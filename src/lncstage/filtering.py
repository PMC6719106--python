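"""lncRNA identification cascade and coding-potential consensus breakdown.

A candidate transcript is retained as a lncRNA when it is longer than
200 nt (strict), multi-exonic (>= 2 exons), and called non-coding by all
three upstream predictors (CPC, CNCI, Pfam-scan), whose outputs are
consumed here as boolean verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import TranscriptModel
from .config import PipelineConfig

__all__ = [
    "CodingVerdict",
    "read_verdicts",
    "apply_identification_filter",
    "venn_coding_potential",
    "type_composition",
]

VENN_REGIONS = (
    "cpc_only",
    "cnci_only",
    "pfam_only",
    "cpc_cnci",
    "cpc_pfam",
    "cnci_pfam",
    "all_three",
)


@dataclass(frozen=True)
class CodingVerdict:
    transcript_id: str
    cpc_is_coding: bool
    cnci_is_coding: bool
    pfam_has_hit: bool

    @property
    def noncoding_consensus(self) -> bool:
        return not (self.cpc_is_coding or self.cnci_is_coding or self.pfam_has_hit)


def read_verdicts(path) -> dict[str, CodingVerdict]:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "cpc_coding", "cnci_coding", "pfam_hit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"verdict table missing columns: {sorted(missing)}")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"]
        raise ValueError(f"duplicate verdicts for: {list(dups[:5])}")
    return {
        r.transcript_id: CodingVerdict(
            r.transcript_id, bool(r.cpc_coding), bool(r.cnci_coding), bool(r.pfam_hit)
        )
        for r in df.itertuples()
    }


def apply_identification_filter(
    transcripts: Iterable[TranscriptModel],
    verdicts: Mapping[str, CodingVerdict],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Run the identification cascade; returns survivors and drop counts.

    Stage order is structural-then-consensus: length, then exon count, then
    the triple non-coding consensus. Drop counts partition the input. A
    transcript passing both structural filters must have a verdict.
    """
    retained: list[TranscriptModel] = []
    drops = {"short": 0, "single_exon": 0, "coding": 0, "retained": 0}
    for t in transcripts:
        if not t.length > config.min_length_nt:
            drops["short"] += 1
            continue
        if t.exon_count < config.min_exons:
            drops["single_exon"] += 1
            continue
        v = verdicts.get(t.transcript_id)
        if v is None:
            raise ValueError(
                f"no coding-potential verdict for structurally retained "
                f"transcript {t.transcript_id}"
            )
        if v.noncoding_consensus:
            retained.append(t)
            drops["retained"] += 1
        else:
            drops["coding"] += 1
    return retained, drops


def venn_coding_potential(verdicts: Iterable[CodingVerdict]) -> dict[str, int]:
    """Counts of the 7 non-empty regions of the three non-coding predicates.

    Region keys name the predictors calling the transcript NON-coding;
    ``all_three`` is the consensus region retained by the filter. The
    8th cell (coding by all three) is reported as ``none``.
    """
    counts = dict.fromkeys(VENN_REGIONS + ("none",), 0)
    key_by_mask = {
        (True, False, False): "cpc_only",
        (False, True, False): "cnci_only",
        (False, False, True): "pfam_only",
        (True, True, False): "cpc_cnci",
        (True, False, True): "cpc_pfam",
        (False, True, True): "cnci_pfam",
        (True, True, True): "all_three",
        (False, False, False): "none",
    }
    for v in verdicts:
        mask = (not v.cpc_is_coding, not v.cnci_is_coding, not v.pfam_has_hit)
        counts[key_by_mask[mask]] += 1
    return counts


def type_composition(retained: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Counts and proportions of positional classes among retained lncRNAs."""
    if not retained:
        return pd.DataFrame(columns=["count", "proportion"])
    counts = pd.Series([t.biotype for t in retained]).value_counts().sort_index()
    return pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})
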