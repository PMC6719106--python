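"""Identify lncRNAs: length > 200 nt, multi-exonic, non-coding by consensus.

Candidates must pass the structural filters and be called non-coding by all
three upstream predictors (consumed as boolean verdicts); survivors are then
classified by genomic position relative to the coding annotation.
"""

from lncstage import (
    SimulationDesign,
    apply_identification_filter,
    classify_lncrna_position,
    generate_bundle,
    type_composition,
    venn_coding_potential,
)
from lncstage.filtering import CodingVerdict

bundle = generate_bundle(SimulationDesign(seed=7))
candidates = [t for t in bundle.transcripts.values() if t.biotype != "mRNA"]
verdicts = {
    r.transcript_id: CodingVerdict(r.transcript_id, bool(r.cpc_coding),
                                   bool(r.cnci_coding), bool(r.pfam_hit))
    for r in bundle.verdicts.itertuples()
}

retained, drops = apply_identification_filter(candidates, verdicts)
print(f"retained {len(retained)} of {len(candidates)} candidates")
print("drop counts:", drops)

venn = venn_coding_potential([verdicts[t.transcript_id] for t in candidates])
print("\nnon-coding consensus breakdown (Venn regions):")
for region, n in venn.items():
    print(f"  {region:10s} {n}")
# 'all_three' is the consensus region the filter keeps.

mrnas = [t for t in bundle.transcripts.values() if t.biotype == "mRNA"]
coding_genes = [g for g in bundle.genes.values() if g.biotype == "mRNA"]
for t in retained:
    t.biotype = classify_lncrna_position(t, coding_genes, mrnas)
print("\npositional composition (lincRNA = intergenic):")
print(type_composition(retained))
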