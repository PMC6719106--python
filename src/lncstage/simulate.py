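"""Synthetic fixture bundle with planted ground truth.

Emulates the staged skeletal-muscle study design — 7 developmental stages
(F45..B90) x 3 replicates — with co-expression modules planted on known
feature sets, lncRNA loci placed to realise all three positional classes,
coding "contaminants", homology-hit tables straddling the loose/strict
E-value cuts, conservation scores, and a term-to-gene map with one term
enriched per planted module. Everything is a deterministic function of the
design and its seed.

Expression is simulated on the log2(FPKM+1) scale and back-transformed, so
planted within-module correlations survive the pipeline's own transform:

    x_gs = baseline_g + lambda_g * E_s + eps,   FPKM = max(2**x - 1, 0)

where E_s is a step profile (``delta`` in the module's high stages, 0
elsewhere), lambda_g is a per-feature loading and eps is Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, TranscriptModel
from .config import EARLY_STAGES, LATE_STAGES, STAGE_ORDER
from .expression import ExpressionMatrix, write_expression
from .gtf import write_gtf

__all__ = [
    "PlantedModule",
    "SimulationDesign",
    "SyntheticBundle",
    "generate_annotation",
    "generate_expression",
    "generate_side_tables",
    "generate_bundle",
]

SPECIES = ("human", "cow", "mouse")

_BASES = np.array(list("ACGT"))
# codons with no stop anywhere when concatenated in frame
_SAFE_CODONS = np.array(["GCT", "GCC", "AAA", "GAA", "CTG", "TTC", "GGT", "CAT"])


@dataclass(frozen=True)
class PlantedModule:
    """A co-expression module planted into the synthetic expression matrix."""

    label: str
    temporal_class: str  # 'early' | 'late' | 'stage_specific:<stage>'
    size: int            # lncRNA members
    high_stages: tuple[str, ...]
    delta: float = 4.0
    n_mrna_members: int = 0  # protein-coding co-members (co-expression targets)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"module {self.label}: size must be >= 1")
        hs = set(self.high_stages)
        if not hs or not hs <= set(STAGE_ORDER):
            raise ValueError(f"module {self.label}: bad high_stages {self.high_stages}")
        if self.temporal_class == "early":
            if not hs <= EARLY_STAGES:
                raise ValueError(f"early module {self.label}: high stages must be early")
        elif self.temporal_class == "late":
            if not hs <= LATE_STAGES:
                raise ValueError(f"late module {self.label}: high stages must be late")
        elif self.temporal_class.startswith("stage_specific:"):
            stage = self.temporal_class.split(":", 1)[1]
            if hs != {stage}:
                raise ValueError(
                    f"stage-specific module {self.label}: high_stages must be exactly {{{stage}}}"
                )
        else:
            raise ValueError(f"module {self.label}: unknown temporal class {self.temporal_class!r}")

    @property
    def expected_class(self) -> str:
        if self.temporal_class.startswith("stage_specific"):
            return "stage_specific"
        return self.temporal_class


def default_planted_modules() -> tuple[PlantedModule, ...]:
    """Default plant: one early, one late, one single-stage-peaked module.

    High-stage sets have size <= 2: with one-hot stage indicators over
    21 samples, a step profile high in k stages correlates with each of its
    stage indicators at r = 1.0 (k=1), 0.645 (k=2) or 0.471 (k=3), so only
    k <= 2 can clear the r > 0.6 module-trait significance cut.
    """
    return (
        PlantedModule("early", "early", size=80, high_stages=("F45", "F65"),
                      n_mrna_members=160),
        PlantedModule("late", "late", size=60, high_stages=("B1", "B90"),
                      n_mrna_members=120),
        PlantedModule("peakF90", "stage_specific:F90", size=40, high_stages=("F90",),
                      n_mrna_members=80),
    )


@dataclass(frozen=True)
class SimulationDesign:
    n_mrna: int = 2000
    n_lncrna: int = 500
    stages: tuple[str, ...] = STAGE_ORDER
    replicates_per_stage: int = 3
    planted_modules: tuple[PlantedModule, ...] = field(default_factory=default_planted_modules)
    noise_sd: float = 0.3
    loading_range: tuple[float, float] = (0.6, 1.0)
    positional_proportions: tuple[float, float, float] = (0.5, 0.3, 0.2)  # linc/antisense/intronic
    contaminant_fraction: float = 0.1
    baseline_log2_range: tuple[float, float] = (2.0, 5.0)
    n_random_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mrna < 1 or self.n_lncrna < 1:
            raise ValueError("feature counts must be positive")
        if self.n_mrna < self.n_lncrna:
            raise ValueError("need at least one mRNA host locus per lncRNA")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if set(self.stages) != set(STAGE_ORDER):
            raise ValueError("stages must be the seven-stage design")
        if sum(m.size for m in self.planted_modules) > self.n_lncrna:
            raise ValueError("planted lncRNA module sizes exceed n_lncrna")
        if sum(m.n_mrna_members for m in self.planted_modules) > self.n_mrna:
            raise ValueError("planted mRNA module sizes exceed n_mrna")
        if abs(sum(self.positional_proportions) - 1.0) > 1e-9:
            raise ValueError("positional proportions must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.stages) * self.replicates_per_stage

    @property
    def background_fraction(self) -> float:
        """Fraction of features belonging to no planted module (derived)."""
        planted = sum(m.size + m.n_mrna_members for m in self.planted_modules)
        return 1.0 - planted / (self.n_mrna + self.n_lncrna)


def _rng(design: SimulationDesign, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator component
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


def mrna_ids(design: SimulationDesign) -> list[str]:
    w = len(str(design.n_mrna))
    return [f"MRNA_{i:0{w}d}" for i in range(1, design.n_mrna + 1)]


def lnc_ids(design: SimulationDesign) -> list[str]:
    w = len(str(design.n_lncrna))
    return [f"LNC_{i:0{w}d}" for i in range(1, design.n_lncrna + 1)]


def _exact_counts(total: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment so counts hit proportions exactly."""
    raw = [p * total for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def planted_membership(design: SimulationDesign) -> dict[str, str]:
    """Module label per feature id; background features map to 'background'.

    Deterministic in the design seed; shared by expression, side tables and
    the ground-truth manifest.
    """
    rng = _rng(design, 3)
    labels: dict[str, str] = {}
    lncs = lnc_ids(design)
    mrnas = mrna_ids(design)
    lnc_perm = rng.permutation(design.n_lncrna)
    mrna_perm = rng.permutation(design.n_mrna)
    li = mi = 0
    for m in design.planted_modules:
        for _ in range(m.size):
            labels[lncs[lnc_perm[li]]] = m.label
            li += 1
        for _ in range(m.n_mrna_members):
            labels[mrnas[mrna_perm[mi]]] = m.label
            mi += 1
    for f in lncs + mrnas:
        labels.setdefault(f, "background")
    return labels


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    """Random sequence with a long injected ORF (~2/3 of the length)."""
    orf_codons = max(2, int(length * 0.66) // 3)
    body = "".join(rng.choice(_SAFE_CODONS, size=orf_codons - 1))
    orf = "ATG" + body + "TAA"
    lead = _random_seq(rng, max(0, (length - len(orf)) // 2))
    tail = _random_seq(rng, max(0, length - len(orf) - len(lead)))
    return (lead + orf + tail)[:length]


def generate_annotation(
    design: SimulationDesign,
) -> tuple[dict[str, GeneModel], dict[str, TranscriptModel], dict[str, str]]:
    """Lay out mRNA genes and lncRNA loci on linear chromosomes.

    Returns gene models, transcript models (sequences attached) and the
    ground-truth positional class per lncRNA. One chromosome is opened per
    1000 features; mRNA genes are spaced with fixed 8 kb gaps; each lncRNA
    consumes one host mRNA locus and is placed intergenic (mid-gap),
    antisense (exon overlapping the host's first exon, opposite strand) or
    fully inside the host's first intron, at the design's exact proportions.
    """
    rng = _rng(design, 0)
    n_features = design.n_mrna + design.n_lncrna
    n_chroms = int(np.ceil(n_features / 1000))
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}

    # --- mRNA genes: 3 exons, introns >= 1500 bp, inter-gene gap 8 kb
    mrna_list = mrna_ids(design)
    per_chrom = int(np.ceil(design.n_mrna / n_chroms))
    cursor: dict[str, int] = {}
    for i, tid in enumerate(mrna_list):
        chrom = f"chr{i // per_chrom + 1}"
        pos = cursor.get(chrom, 1)
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(300, 800, size=3)
        intron_lens = rng.integers(1500, 2500, size=2)
        exons, p = [], pos
        for k in range(3):
            exons.append(GenomicInterval(chrom, p, p + int(exon_lens[k]) - 1, strand))
            p = exons[-1].end + 1 + (int(intron_lens[k]) if k < 2 else 0)
        gid = "G" + tid
        t = TranscriptModel(tid, gid, "mRNA", exons)
        t.sequence = _coding_seq(rng, t.length)
        transcripts[tid] = t
        genes[gid] = GeneModel(gid, t.span, [tid], biotype="mRNA")
        cursor[chrom] = t.span.end + 8000

    # --- lncRNA loci, host mRNA j for lncRNA j (one host per lncRNA)
    lnc_list = lnc_ids(design)
    counts = _exact_counts(design.n_lncrna, design.positional_proportions)
    classes = (
        ["lincRNA"] * counts[0] + ["antisense_lncRNA"] * counts[1] + ["intronic_lncRNA"] * counts[2]
    )
    rng.shuffle(classes)
    truth_class: dict[str, str] = {}
    for j, (tid, cls) in enumerate(zip(lnc_list, classes)):
        host = transcripts[mrna_list[j]]
        chrom = host.chrom
        if cls == "lincRNA":
            # centred in the 8 kb gap downstream of the host gene
            start = host.span.end + 3000
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [
                GenomicInterval(chrom, start, start + 149, strand),
                GenomicInterval(chrom, start + 250, start + 399, strand),
            ]
        elif cls == "antisense_lncRNA":
            # first exon overlaps the host's first exon on the opposite strand
            strand = "-" if host.strand == "+" else "+"
            e1 = host.exons[0]
            exons = [
                GenomicInterval(chrom, e1.start + 5, e1.start + 154, strand),
                GenomicInterval(chrom, e1.end + 100, e1.end + 249, strand),
            ]
        else:  # intronic: fully inside the host's first intron
            strand = host.strand if rng.random() < 0.5 else ("-" if host.strand == "+" else "+")
            istart = host.exons[0].end + 200
            exons = [
                GenomicInterval(chrom, istart, istart + 149, strand),
                GenomicInterval(chrom, istart + 250, istart + 399, strand),
            ]
        gid = "G" + tid
        t = TranscriptModel(tid, gid, "lncRNA_candidate", exons)
        t.sequence = _random_seq(rng, t.length)
        transcripts[tid] = t
        genes[gid] = GeneModel(gid, t.span, [tid], biotype="lncRNA_candidate")
        truth_class[tid] = cls
    return genes, transcripts, truth_class


def generate_expression(design: SimulationDesign) -> ExpressionMatrix:
    """Simulate the FPKM matrix with the planted module structure."""
    rng = _rng(design, 1)
    membership = planted_membership(design)
    features = lnc_ids(design) + mrna_ids(design)
    profiles = {
        m.label: np.array([m.delta if s in m.high_stages else 0.0 for s in STAGE_ORDER])
        for m in design.planted_modules
    }
    stage_of_sample = np.repeat(np.arange(len(STAGE_ORDER)), design.replicates_per_stage)
    n = len(features)
    s = design.n_samples
    lo, hi = design.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=n)
    loadings = rng.uniform(*design.loading_range, size=n)
    eps = rng.normal(0.0, design.noise_sd, size=(n, s))
    x = baseline[:, None] + eps
    for i, f in enumerate(features):
        lab = membership[f]
        if lab != "background":
            x[i] += loadings[i] * profiles[lab][stage_of_sample]
    fpkm = np.maximum(np.exp2(x) - 1.0, 0.0)
    sample_ids = [
        f"{st}_r{r}" for st in STAGE_ORDER for r in range(1, design.replicates_per_stage + 1)
    ]
    meta = pd.DataFrame(
        {
            "stage": np.repeat(list(STAGE_ORDER), design.replicates_per_stage),
            "replicate": list(range(1, design.replicates_per_stage + 1)) * len(STAGE_ORDER),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    values = pd.DataFrame(fpkm, index=pd.Index(features, name="feature_id"), columns=sample_ids)
    return ExpressionMatrix(values=values, sample_meta=meta)


# fraction of lncRNAs with a homology hit below the loose / strict cuts;
# mouse loses most homologs under the strict cut, so the stringency
# contrast is significant against cow for mouse but not for human
_SPECIES_MATCH = {
    "human": (0.44, 0.40),
    "cow": (0.26, 0.24),
    "mouse": (0.25, 0.12),
}


def generate_side_tables(
    design: SimulationDesign, transcripts: dict[str, TranscriptModel] | None = None
) -> dict:
    """Coding verdicts, homology hits (both directions), conservation scores
    and a term-to-gene map with one term enriched per planted module."""
    rng = _rng(design, 2)
    membership = planted_membership(design)
    lncs = lnc_ids(design)
    mrnas = mrna_ids(design)

    # --- coding verdicts: contaminants drawn from background lncRNAs only
    background = [f for f in lncs if membership[f] == "background"]
    n_contam = int(round(design.contaminant_fraction * design.n_lncrna))
    if n_contam > len(background):
        raise ValueError("not enough background lncRNAs to hold the contaminant fraction")
    contaminants = sorted(rng.choice(background, size=n_contam, replace=False))
    verdict_rows = []
    for tid in lncs:
        if tid in set(contaminants):
            flags = rng.random(3) < 0.6
            if not flags.any():
                flags[rng.integers(0, 3)] = True
        else:
            flags = np.zeros(3, dtype=bool)
        verdict_rows.append((tid, int(flags[0]), int(flags[1]), int(flags[2])))
    for tid in mrnas:
        verdict_rows.append((tid, 1, 1, 1))
    verdicts = pd.DataFrame(
        verdict_rows, columns=["transcript_id", "cpc_coding", "cnci_coding", "pfam_hit"]
    )

    # --- homology hits: E-values planted to straddle 1e-3 and 1e-10
    hit_rows, rev_rows = [], []
    truth_matched: dict[str, dict[str, list[str]]] = {}
    for sp in SPECIES:
        frac_loose, frac_strict = _SPECIES_MATCH[sp]
        perm = rng.permutation(design.n_lncrna)
        n_loose = int(round(frac_loose * design.n_lncrna))
        n_strict = int(round(frac_strict * design.n_lncrna))
        loose_ids = [lncs[i] for i in perm[:n_loose]]
        strict_ids = set(loose_ids[:n_strict])
        for q in loose_ids:
            subj = f"{sp}_{q}"
            if q in strict_ids:
                e = 10.0 ** rng.uniform(-15, -10.5)
            else:
                e = 10.0 ** rng.uniform(-9.5, -3.5)
            hit_rows.append((q, subj, sp, e, float(rng.uniform(40, 200))))
            if rng.random() < 0.7:  # reciprocal best-hit subset
                rev_rows.append((subj, q, sp, e * rng.uniform(0.5, 2.0), float(rng.uniform(40, 200))))
        # a few above-threshold hits that must never count as matched
        for q in (lncs[i] for i in perm[n_loose : n_loose + max(1, n_loose // 10)]):
            hit_rows.append((q, f"{sp}_{q}", sp, 10.0 ** rng.uniform(-2.5, -0.5),
                             float(rng.uniform(20, 40))))
        truth_matched[sp] = {"loose": sorted(loose_ids), "strict": sorted(strict_ids)}
    cols = ["query", "subject", "species", "evalue", "bitscore"]
    hits = pd.DataFrame(hit_rows, columns=cols)
    hits_reverse = pd.DataFrame(rev_rows, columns=cols)

    scores = pd.DataFrame({"lncrna_id": lncs, "score": rng.uniform(0, 1, design.n_lncrna)})

    # --- term map: one term per planted module covering its mRNA members
    # (gene-level ids, matching the network's coding-gene namespace)
    term_rows = []
    for m in design.planted_modules:
        for g in sorted("G" + f for f in mrnas if membership[f] == m.label):
            term_rows.append((f"TERM_{m.label}", g, f"planted term for module {m.label}"))
    for k in range(design.n_random_terms):
        size = int(rng.integers(10, 51))
        for g in sorted("G" + f for f in rng.choice(mrnas, size=size, replace=False)):
            term_rows.append((f"TERM_rand{k:02d}", g, f"random background term {k}"))
    term2gene = pd.DataFrame(term_rows, columns=["term_id", "gene_id", "term_name"])

    truth = {
        "contaminants": list(contaminants),
        "matched": truth_matched,
        "enriched_terms": {m.label: f"TERM_{m.label}" for m in design.planted_modules},
    }
    return {
        "verdicts": verdicts,
        "hits": hits,
        "hits_reverse": hits_reverse,
        "scores": scores,
        "term2gene": term2gene,
        "truth": truth,
    }


@dataclass
class SyntheticBundle:
    design: SimulationDesign
    genes: dict[str, GeneModel]
    transcripts: dict[str, TranscriptModel]
    expression: ExpressionMatrix
    verdicts: pd.DataFrame
    hits: pd.DataFrame
    hits_reverse: pd.DataFrame
    scores: pd.DataFrame
    term2gene: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out / "annotation.gtf",
            "fasta": out / "transcripts.fa",
            "verdicts": out / "coding_verdicts.tsv",
            "expression": out / "expression_fpkm.tsv",
            "samples": out / "samples.tsv",
            "hits": out / "homology_hits.tsv",
            "hits_reverse": out / "homology_hits_reverse.tsv",
            "scores": out / "conservation_scores.tsv",
            "term2gene": out / "term2gene.tsv",
            "manifest": out / "ground_truth.json",
        }
        write_gtf(paths["gtf"], self.genes.values(), self.transcripts.values())
        _write_fasta(paths["fasta"], self.transcripts)
        self.verdicts.to_csv(paths["verdicts"], sep="\t", index=False)
        write_expression(self.expression, paths["expression"], paths["samples"])
        self.hits.to_csv(paths["hits"], sep="\t", index=False)
        self.hits_reverse.to_csv(paths["hits_reverse"], sep="\t", index=False)
        self.scores.to_csv(paths["scores"], sep="\t", index=False)
        self.term2gene.to_csv(paths["term2gene"], sep="\t", index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def _write_fasta(path, transcripts: dict[str, TranscriptModel]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(t.sequence), id=tid, description="")
        for tid, t in sorted(transcripts.items())
        if t.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def generate_bundle(design: SimulationDesign | None = None, seed: int | None = None) -> SyntheticBundle:
    """Generate the full self-consistent fixture bundle."""
    if design is None:
        design = SimulationDesign(seed=seed if seed is not None else 0)
    elif seed is not None:
        from dataclasses import replace

        design = replace(design, seed=seed)
    genes, transcripts, truth_class = generate_annotation(design)
    expression = generate_expression(design)
    side = generate_side_tables(design, transcripts)
    membership = planted_membership(design)
    truth = {
        "positional_class": truth_class,
        "module": membership,
        "module_temporal_class": {m.label: m.expected_class for m in design.planted_modules},
        "module_high_stages": {m.label: list(m.high_stages) for m in design.planted_modules},
        **side["truth"],
    }
    return SyntheticBundle(
        design=design,
        genes=genes,
        transcripts=transcripts,
        expression=expression,
        verdicts=side["verdicts"],
        hits=side["hits"],
        hits_reverse=side["hits_reverse"],
        scores=side["scores"],
        term2gene=side["term2gene"],
        truth=truth,
    )
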