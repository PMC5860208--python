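"""Decompose a protein surface into overlapping patches.

Builds an ideal 15-residue alpha-helix, computes solvent accessibility, and
grows a 14 A patch around every residue whose relative accessibility exceeds
25%.  Each patch is a contiguous cap of surface: residues joined to the
centre atom by van der Waals contacts whose solvent vectors diverge by less
than 120 degrees.
"""

import tempfile
import warnings
from pathlib import Path

from patchpred import annotate_accessibility, make_patches, read_structure
from patchpred.synthetic import make_helix

warnings.filterwarnings("ignore")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "helix.pdb"
    path.write_text(make_helix(15))
    (chain,) = read_structure(path)
    annotate_accessibility([chain])

patches = make_patches(chain)
print(f"chain of {len(chain.residues)} residues -> {len(patches)} surface patches")
for p in patches[:5]:
    _, num, _ = p.centre_residue_id
    members = ",".join(str(r[1]) for r in p.member_residue_ids)
    print(f"  centre residue {num:2d} (atom {p.centre_atom_name}): members {members}")
print("Each line is one patch: its centre residue, the most exposed atom used")
print("as the geometric seed, and every residue pulled in by the growth sweep.")
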