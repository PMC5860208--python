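"""Sequence features: interface propensity and conservation scoring.

The propensity of a residue type is the log-ratio of the share of interface
accessible area it carries versus its share of surface area, scaled by each
residue's own exposure.  Conservation is the weighted sum-of-pairs score of
an alignment column (1 = perfectly conserved), computed here on a small
hand-made alignment.
"""

from patchpred import (
    build_propensity_table,
    residue_hydrophobicity,
    residue_propensity,
    valdar01_scores,
)
from patchpred.sequence_features import TrainingResidue

# toy training set: TRP carries most interface area, LYS most surface area
residues = (
    [TrainingResidue("TRP", 60.0, "interface")] * 9
    + [TrainingResidue("TRP", 60.0, "surface")] * 1
    + [TrainingResidue("LYS", 60.0, "interface")] * 1
    + [TrainingResidue("LYS", 60.0, "surface")] * 9
)
table = build_propensity_table(residues)
for t in ("TRP", "LYS"):
    p = residue_propensity(t, 60.0, table)
    h = residue_hydrophobicity(t)
    print(f"{t}: propensity {p:+.3f} (positive = interface-enriched), hydropathy {h:+.1f}")

alignment = ["MKTAYIAK", "MKTAYIAK", "MKSAYIAK", "MKTAYLAK", "MKTAYIAK"]
scores = valdar01_scores(alignment, target_index=0)
print("conservation per position:", " ".join(f"{s:.2f}" for s in scores))
print("Positions 3 and 6 vary across the alignment and score below the")
print("fully conserved columns, which score exactly 1.")
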