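"""Positional annotation of N-terminal peptides against predicted cleavage sites.

Builds a three-protein toy database, maps a handful of observed N-terminal
peptides onto it, and prints each terminus' category, its signed offset to
the predicted transit-peptide cleavage site, and the monoisotopic mass
shifts of the labeling chemistry.
"""

from ntermflow.io_formats import AnalysisConfig, Compartment, ProteinEntry
from ntermflow.terminome_annotation import (
    MODIFICATIONS,
    NTermMod,
    NTermPeptide,
    annotate_peptides,
    mass_shift,
)

cfg = AnalysisConfig()  # window_W=5 residues, two-sided

proteome = {
    # cytosolic protein, no presequence
    "CYT1": ProteinEntry("CYT1", "MASTKLLQEGRVVDNPQ"),
    # plastid-imported protein: transit peptide ends at residue 50,
    # so the mature N-terminus is residue 51
    "PLA1": ProteinEntry(
        "PLA1", "M" + "A" * 49 + "SERLKGW" + "V" * 43, Compartment.PLASTID, cleavage_pos=50
    ),
}

peptides = [
    NTermPeptide("MASTK", "CYT1", 1, NTermMod.ACETYLATED),        # intact start
    NTermPeptide("ASTKL", "CYT1", 2, NTermMod.FREE_DIMETHYLATED), # Met excised
    NTermPeptide("SERLK", "PLA1", 51, NTermMod.FREE_DIMETHYLATED),# mature after TP
    NTermPeptide("ERLKG", "PLA1", 52, NTermMod.FREE_DIMETHYLATED),# ragged +1
    NTermPeptide("VVDNP", "CYT1", 12, NTermMod.FREE_DIMETHYLATED),# internal cleavage
]

annotations = annotate_peptides(peptides, proteome, cfg)
print(annotations[["accession", "start", "category", "offset", "expected"]])
print()
print("Each row is one observed terminus: POS1/POS2 are translation starts,")
print("CLEAVAGE_WINDOW termini fall within 5 residues of the predicted mature")
print("N-terminus (offset = observed start - predicted start), and anything")
print("else is UNANNOTATED (internal proteolysis or unpredicted maturation).")
print()
print("Label/modification monoisotopic mass shifts (Da):")
for name, mod in MODIFICATIONS.items():
    print(f"  {name:15s} {mass_shift(mod):+.6f}")
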