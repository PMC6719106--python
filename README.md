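# lncstage

Temporal analysis of long non-coding RNAs (lncRNAs) across staged
developmental RNA-seq, modelled on longitudinal skeletal-muscle studies that
sample seven stages — five fetal ages (F45, F65, F90, F120, F135) and two
postnatal ages (B1, B90) — with three biological replicates each. The
package takes the standard upstream products (a GTF annotation, transcript
FASTA, coding-potential verdicts from CPC/CNCI/Pfam-scan, an FPKM matrix,
BLAST-style homology hits, phastCons-style conservation scores) and carries
the analysis from lncRNA identification through temporal co-expression
modules to target networks and enrichment.

## What it computes

1. **Identification and positional classes.** A candidate transcript is kept
   as a lncRNA when it is longer than 200 nt, multi-exonic, and called
   non-coding by all three predictors. Survivors are classified as
   **lincRNA** (intergenic), **antisense** (exon overlap with an
   opposite-strand mRNA exon) or **intronic** (contained in a gene span with
   no exon overlap).
2. **Conservation.** Query-level homology matching under a loose
   (E < 10⁻³) and strict (E < 10⁻¹⁰) cut, reciprocal (two-way) matching,
   conservation-score filtering (score > 0.8), and a two-sided Fisher's
   exact test contrasting each species' loose→strict retention against a
   background species.
3. **Differential expression.** Welch's t-test on log₂(FPKM+1) between every
   pair of stages; the DE set is the union over all 21 pairs at p < 0.05.
4. **Co-expression modules.** A signed weighted network on the DE lncRNAs:
   Pearson correlation r, soft power β chosen by the scale-free-topology
   criterion, signed adjacency a_ij = ((1+r_ij)/2)^β, topological overlap

       TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
       ℓ_ij = Σ_u a_iu a_uj,  k_i = Σ_u a_iu,

   average-linkage clustering of 1 − TOM, a static branch cut with a kME
   membership cleanup, module eigengenes (first singular vector of the
   standardized module expression), and eigengene–stage correlation with
   Student-t p-values (df = n − 2 = 19). Modules are classed **early**,
   **late**, **stage-specific**, **mixed** or **none** from their
   significant stages (r > 0.6, p < 0.05).
5. **Targets and hubs.** lncRNA→gene edges by genomic proximity (≤ 100 kb,
   inclusive) and co-expression (|r| > 0.95, strict); a bipartite network
   over lncRNAs with |FC| > 2 and p < 0.05; hub lncRNAs with degree > 10.
6. **Enrichment.** Upper-tail hypergeometric over-representation of target
   sets against a user-supplied term→gene map, Benjamini–Hochberg adjusted.

Because the studies this mirrors deposit no public expression data, the
package ships a first-class synthetic-data generator
(`lncstage.simulate`) that plants early / late / stage-specific modules with
known ground truth, so the whole chain is testable end to end.

## Worked example

```python
from lncstage import SimulationDesign, generate_bundle, run_bundle

bundle = generate_bundle(SimulationDesign(seed=7))
results = run_bundle(bundle)
for module, cls in results["modules"]["temporal_classes"].items():
    print(module, cls)
print("ARI:", round(results["recovery"]["module_ari"], 3))
```

prints

```
blue late
brown stage_specific
turquoise early
ARI: 1.0
```

— the three planted modules are recovered exactly (adjusted Rand index 1.0
against the ground truth), and their eigengene–stage correlations classify
them into the planted temporal classes: e.g. the `brown` module correlates
with F90 at r = 1.00 (p = 1.5×10⁻²⁶), while `turquoise` is significant only
in F45 and F65 (r ≈ 0.65, p ≈ 0.0015 each). The `examples/` directory holds
one narrative script per capability (simulation, identification,
conservation, DE, modules, targets + enrichment); each prints its numbers
with a note on what they mean. A thin CLI mirrors the stages:
`lncstage simulate|identify|conserve|de|modules|enrich|run`.

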