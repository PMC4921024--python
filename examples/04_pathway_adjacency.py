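"""Metabolic interpretation: fusions of neighbouring enzymes.

Builds a toy reaction map for the histidine-pathway neighbour pair
(phosphoribosyl-ATP pyrophosphatase -> phosphoribosyl-AMP cyclohydrolase)
and shows that a gene fused for both roles brackets the shared
intermediate phosphoribosyl-AMP; then demonstrates the variety and
frequency accounting for a pathway role.
"""

from domfuse import GeneRecord, ReactionMap, adjacent_reaction_fusions, fusion_frequency, fusion_variety
from domfuse.caller import FusionCall, Stage

PPAT = "Phosphoribosyl-ATP pyrophosphatase"
CYC = "Phosphoribosyl-AMP cyclohydrolase"

rmap = ReactionMap(
    role_reactions={PPAT: {"rxn1"}, CYC: {"rxn2"}},
    substrates={"rxn1": {"Phosphoribosyl-ATP"}, "rxn2": {"Phosphoribosyl-AMP"}},
    products={"rxn1": {"Phosphoribosyl-AMP"}, "rxn2": {"ProFAR"}},
)
genes = {"hisIE": GeneRecord("hisIE", "G1", 700, [PPAT, CYC])}
calls = [FusionCall("hisIE", "G1", Stage.final_fusion)]

found, _ = adjacent_reaction_fusions(calls, genes, rmap)
for f in found:
    print(f"{f.gene_id}: {f.role_from} -> {f.role_to}, shared: {sorted(f.shared)}")
# The shared metabolite is the product of the first role and the
# substrate of the second — the configuration expected when a fusion
# protects an unstable intermediate.

# variety/frequency for a pathway role across a small cohort
cohort = {
    "hisIE": genes["hisIE"],
    "g2": GeneRecord("g2", "G2", 650, [CYC, "unknown partner domain"]),
    "g3": GeneRecord("g3", "G2", 240, [CYC]),
    "g4": GeneRecord("g4", "G3", 235, [CYC]),
}
cohort_calls = calls + [FusionCall("g2", "G2", Stage.final_fusion)]
variety = fusion_variety(CYC, cohort_calls, cohort, {PPAT: "same-pathway"})
freq = fusion_frequency(CYC, cohort_calls, cohort)
print(f"variety of {CYC}: {variety.total} architectures {variety.by_category}")
print(f"frequency: {freq:.2f} of its gene copies are fused")
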