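"""Generate a synthetic fixture bundle and inspect its ground truth.

The bundle emulates a 7-stage x 3-replicate developmental RNA-seq study:
annotation (GTF), transcript sequences (FASTA), coding-potential verdicts,
an FPKM matrix, homology hits, conservation scores and a term-to-gene map,
all with a known ground-truth manifest.
"""

from collections import Counter

from lncstage import SimulationDesign, generate_bundle

design = SimulationDesign(seed=7)
bundle = generate_bundle(design)

print(f"features: {design.n_lncrna} lncRNA candidates + {design.n_mrna} mRNAs")
print(f"samples:  {design.n_samples} ({len(design.stages)} stages x "
      f"{design.replicates_per_stage} replicates)")
print(f"background fraction: {design.background_fraction:.2f}")

print("\nplanted modules (label, temporal class, lncRNAs, mRNA co-members):")
for m in design.planted_modules:
    print(f"  {m.label:10s} {m.temporal_class:20s} {m.size:4d} {m.n_mrna_members:4d}"
          f"   high in {','.join(m.high_stages)}")

classes = Counter(bundle.truth["positional_class"].values())
print("\nplanted positional classes:", dict(classes))
print("planted coding contaminants:", len(bundle.truth["contaminants"]))

# bundle.write("bundle_out")  # writes GTF/FASTA/TSV/JSON files
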