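"""Deterministic synthetic micro-structures in PDB format.

Every module of the pipeline is testable without downloading real structures:
this module writes small, valid PDB files with known geometry — ideal helices
and strands built from textbook backbone torsions, flat residue grids, a
U-shaped pocket whose opposite walls have antiparallel solvent vectors, a
caged (fully buried) atom, and two-slab toy complexes with a planted
interface.  Identical parameters and seed give byte-identical output.

The grids are chemically minimal: each residue carries N, CA, C, O and a CB
(plus CG where a longer side chain is needed), spaced so that neighbouring
residues are in atomic contact and a facing slab occludes the exposed face.
Side-chain identity is free, which is how compositional signal is planted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

# ideal backbone geometry (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0

# flat-grid spacing: dx gives a peptide-bond C->N link along a row, dy places
# next-row atoms inside contact range diagonally
GRID_DX, GRID_DY = 4.3, 4.0
CB_LENGTH = 1.53


@dataclass
class FixtureSpec:
    kind: str
    n_residues: int = 0
    params: dict | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# PDB text assembly
# ---------------------------------------------------------------------------

def _atom_line(serial, name, resname, chain, resseq, pos, element) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain}{resseq:4d}"
        f"{'':1s}   {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def atoms_to_pdb(residues: list[tuple[str, str, int, list[tuple[str, str, np.ndarray]]]]) -> str:
    """residues: (chain_id, resname, resseq, [(atom_name, element, xyz), ...])."""
    lines = []
    serial = 1
    prev_chain = None
    for chain_id, resname, resseq, atoms in residues:
        if prev_chain is not None and chain_id != prev_chain:
            lines.append("TER")
        prev_chain = chain_id
        for name, element, pos in atoms:
            lines.append(_atom_line(serial, name, resname, chain_id, resseq, pos, element))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# torsion-driven backbone construction (NeRF)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, length, angle_deg, torsion_deg) -> np.ndarray:
    """Position of the next atom given the three preceding ones."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -length * math.cos(angle),
            length * math.sin(angle) * math.cos(torsion),
            length * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n, ca, c) -> np.ndarray:
    """Approximate C-beta from the backbone frame (L-configuration)."""
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (c - ca) / np.linalg.norm(c - ca)
    bis = -(u + v)
    bis /= np.linalg.norm(bis)
    perp = np.cross(v, u)
    perp /= np.linalg.norm(perp)
    d = bis * math.cos(math.radians(54.0)) + perp * math.sin(math.radians(54.0))
    return ca + CB_LENGTH * d


def build_backbone(
    n: int, phi: float, psi: float, omega: float = 180.0, with_cb: bool = True
) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O, optionally CB) of n residues at fixed torsions."""
    if n < 1:
        raise ValueError("need at least one residue")
    residues = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    pos_n, pos_ca, pos_c = n0, ca0, c0
    for i in range(n):
        res = {"N": pos_n, "CA": pos_ca, "C": pos_c}
        next_n = _place_atom(pos_n, pos_ca, pos_c, _B_C_N, _A_CA_C_N, psi)
        res["O"] = _place_atom(pos_n, pos_ca, pos_c, _B_C_O, _A_CA_C_O, psi + 180.0)
        if with_cb:
            res["CB"] = _cb_position(pos_n, pos_ca, pos_c)
        residues.append(res)
        if i == n - 1:
            break
        next_ca = _place_atom(pos_ca, pos_c, next_n, _B_N_CA, _A_C_N_CA, omega)
        next_c = _place_atom(pos_c, next_n, next_ca, _B_CA_C, _A_N_CA_C, phi)
        pos_n, pos_ca, pos_c = next_n, next_ca, next_c
    return residues


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _backbone_to_residues(backbone, sequence, chain_id="A", start=1):
    out = []
    for i, res in enumerate(backbone):
        resname = _ONE_TO_THREE[sequence[i]]
        atoms = []
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in res:
                continue
            if name == "CB" and resname == "GLY":
                continue
            element = name[0]
            atoms.append((name, element, res[name]))
        out.append((chain_id, resname, start + i, atoms))
    return out


def make_helix(n: int, sequence: str | None = None) -> str:
    """Ideal alpha-helix (phi -57, psi -47); interior residues assign as H."""
    if n < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    sequence = sequence or "A" * n
    backbone = build_backbone(n, HELIX_PHI, HELIX_PSI)
    return atoms_to_pdb(_backbone_to_residues(backbone, sequence))


def make_strand(n: int, sequence: str | None = None) -> str:
    """Single fully extended strand; no H-bond partner, so it assigns as coil."""
    sequence = sequence or "A" * n
    backbone = build_backbone(n, STRAND_PHI, STRAND_PSI)
    return atoms_to_pdb(_backbone_to_residues(backbone, sequence))


def _canonicalise(residues: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    """Rotate/translate a chain so its CA principal axes align with x, y, z."""
    cas = np.array([r["CA"] for r in residues])
    centre = cas.mean(axis=0)
    u, s, vt = np.linalg.svd(cas - centre)
    rot = vt  # rows: principal directions
    # deterministic sign convention: chain runs +x, first O leans +y
    if (rot @ (cas[-1] - cas[0]))[0] < 0:
        rot[0] *= -1
    if (rot @ (residues[0]["O"] - centre))[1] < 0:
        rot[1] *= -1
    if np.linalg.det(rot) < 0:
        rot[2] *= -1
    return [{k: rot @ (v - centre) for k, v in res.items()} for res in residues]


# antiparallel placement of the partner strand; frozen from a deterministic
# scan maximising Kabsch-Sander sheet assignment on the fixture itself
SHEET_TRANSFORM = {"rot": "y", "dx": 0.0, "dy": 3.5, "dz": 0.25}


def make_sheet(n_per_strand: int = 8, sequence: str | None = None) -> str:
    """Two-strand antiparallel sheet; interior residues assign as E."""
    seq = sequence or "A" * n_per_strand
    s1 = _canonicalise(build_backbone(n_per_strand, STRAND_PHI, STRAND_PSI))
    # rotate the partner strand by pi (reversing the run direction)
    rot = np.diag([-1.0, -1.0, 1.0]) if SHEET_TRANSFORM["rot"] == "z" else np.diag([-1.0, 1.0, -1.0])
    t = np.array([SHEET_TRANSFORM["dx"], SHEET_TRANSFORM["dy"], SHEET_TRANSFORM["dz"]])
    s2 = [{k: rot @ v + t for k, v in res.items()} for res in s1]
    residues = _backbone_to_residues(s1, seq, "A", 1)
    residues += _backbone_to_residues(s2, seq, "A", n_per_strand + 10)
    return atoms_to_pdb(residues)


# ---------------------------------------------------------------------------
# flat grids, pockets, cages, slabs
# ---------------------------------------------------------------------------

def _grid_residue(x, y, z, cb_dir=+1.0, resname="ALA", with_cg=False):
    """A chemically minimal residue centred at (x, y, z), side chain along z."""
    atoms = [
        ("N", "N", np.array([x - 1.46, y, z])),
        ("CA", "C", np.array([x, y, z])),
        ("C", "C", np.array([x + 1.52, y, z])),
        ("O", "O", np.array([x + 1.52, y + 1.23, z])),
    ]
    if resname != "GLY":
        atoms.append(("CB", "C", np.array([x, y, z + cb_dir * CB_LENGTH])))
        if with_cg:
            atoms.append(("CG", "C", np.array([x, y, z + cb_dir * 2 * CB_LENGTH])))
    return atoms


def make_planar_grid(
    n_rows: int = 3,
    n_cols: int = 8,
    resname: str = "ALA",
    z: float = 0.0,
    cb_dir: float = +1.0,
    chain_id: str = "A",
    start: int = 1,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    resnames: list[str] | None = None,
    with_cg: bool = False,
) -> list:
    """Row-major flat grid of minimal residues (one chain), as residue tuples."""
    out = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            name = resnames[k] if resnames else resname
            x, y = c * GRID_DX, r * GRID_DY
            atoms = _grid_residue(x, y, z, cb_dir, name, with_cg)
            if jitter and rng is not None:
                atoms = [
                    (nm, el, p + rng.uniform(-jitter, jitter, 3)) for nm, el, p in atoms
                ]
            out.append((chain_id, name, start + k, atoms))
            k += 1
    return out


def make_planar_grid_pdb(n_rows=3, n_cols=8, resname="ALA") -> str:
    return atoms_to_pdb(make_planar_grid(n_rows, n_cols, resname))


def _backing_layer(n_rows, n_cols, z, start, chain_id="A"):
    """Dense CA-only layer; dominates the walls' nearest-neighbour centroids."""
    out = []
    k = 0
    for y in np.arange(-2.0, (n_rows - 1) * GRID_DY + 2.01, 2.0):
        for x in np.arange(-2.15, (n_cols - 1) * GRID_DX + 2.16, 2.15):
            out.append(
                (chain_id, "GLY", start + k,
                 [("CA", "C", np.array([float(x), float(y), z]))])
            )
            k += 1
    return out


def make_u_shape(n_cols: int = 6, arm_gap: float = 7.5) -> str:
    """Pocket fixture: two facing walls whose solvent vectors are antiparallel.

    Each wall is a 3-row grid with a two-carbon side chain pointing into the
    pocket, backed by a dense layer behind it so every wall residue's solvent
    vector points into the pocket.  The walls' side-chain tips are in atomic
    contact, but the two walls' solvent vectors oppose each other (angle about
    180 deg), so the solvent-angle test must keep the far wall out of a patch
    grown on the near wall.
    """
    bottom = make_planar_grid(3, n_cols, "MET", z=0.0, cb_dir=+1.0,
                              chain_id="A", start=1, with_cg=True)
    top = make_planar_grid(3, n_cols, "MET", z=arm_gap, cb_dir=-1.0,
                           chain_id="A", start=101, with_cg=True)
    backing = _backing_layer(3, n_cols, -3.2, 201)
    backing += _backing_layer(3, n_cols, arm_gap + 3.2, 401)
    return atoms_to_pdb(bottom + top + backing)


def make_cage(shell_radius: float = 4.0, n_shell: int = 120) -> str:
    """A central atom fully enclosed by a dense spherical shell of atoms."""
    residues = [("A", "GLY", 1, [("CA", "C", np.array([0.0, 0.0, 0.0]))])]
    k = np.arange(n_shell, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n_shell)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    pts = shell_radius * np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )
    for i, p in enumerate(pts):
        residues.append(("A", "GLY", 2 + i, [("CA", "C", p)]))
    return atoms_to_pdb(residues)


INTERFACE_POOL = ["ILE", "LEU", "VAL", "MET"]
SURFACE_POOL = ["LYS", "GLU", "ASP", "SER"]

SLAB_ROW_DY = 6.0  # A-chain row spacing; open enough that every residue is exposed


def _slab_residue(x, y, resname):
    """Exposed-slab residue: backbone in-plane, two-carbon side chain up."""
    return [
        ("N", "N", np.array([x - 1.46, y, 0.0])),
        ("CA", "C", np.array([x, y, 0.0])),
        ("C", "C", np.array([x + 1.52, y, 0.0])),
        ("O", "O", np.array([x + 1.52, y + 1.23, 0.0])),
        ("CB", "C", np.array([x, y, CB_LENGTH])),
        ("CG", "C", np.array([x, y, 2 * CB_LENGTH])),
    ]


def _occluder_residue(x, y, z_b):
    """Occluder residue: side chain down, ending in a 5-atom umbrella tip."""
    zt = z_b - 2 * CB_LENGTH
    atoms = [
        ("N", "N", np.array([x - 1.46, y, z_b])),
        ("CA", "C", np.array([x, y, z_b])),
        ("C", "C", np.array([x + 1.52, y, z_b])),
        ("O", "O", np.array([x + 1.52, y + 1.23, z_b])),
        ("CB", "C", np.array([x, y, z_b - CB_LENGTH])),
        ("CG", "C", np.array([x, y, zt])),
    ]
    for i, (dx, dy) in enumerate([(1.4, 0.0), (-1.4, 0.0), (0.0, 1.4), (0.0, -1.4)]):
        atoms.append((f"CD{i + 1}", "C", np.array([x + dx, y + dy, zt])))
    return atoms


def make_two_slab_complex(
    n_rows: int = 3,
    n_cols: int = 12,
    covered_cols: int = 4,
    gap: float = 4.0,
    seed: int = 0,
    signal: str = "strong",
    jitter: float = 0.05,
) -> str:
    """Two facing residue slabs with a planted interface.

    Chain A is a long open grid (two-carbon side chains pointing up); chain B
    is a denser occluding slab hovering above A's first ``covered_cols``
    columns with its side-chain tips ``gap`` A above A's tips.  At small gaps
    (~4 A) complexation strips >=10 RASA points from every covered A residue;
    the far columns lose nothing.  Under the ``strong`` signal profile,
    residues in the covered region draw from a hydrophobic pool and the rest
    from a polar pool, so patch composition separates the classes; under
    ``none`` every residue draws uniformly from the combined pool.
    """
    rng = np.random.default_rng(seed)
    pool_all = INTERFACE_POOL + SURFACE_POOL

    def pick(is_interface_region: bool) -> str:
        if signal == "none":
            return pool_all[rng.integers(len(pool_all))]
        # 80/20 enrichment keeps every type present in both surface sets, so
        # the propensity log-ratio is defined for all types
        favoured = INTERFACE_POOL if is_interface_region else SURFACE_POOL
        other = SURFACE_POOL if is_interface_region else INTERFACE_POOL
        pool = favoured if rng.random() < 0.8 else other
        return pool[rng.integers(len(pool))]

    residues = []
    serial = 1
    for r in range(n_rows):
        for c in range(n_cols):
            name = pick(c < covered_cols + 1)
            atoms = _slab_residue(c * GRID_DX, r * SLAB_ROW_DY, name)
            residues.append(("A", name, serial, atoms))
            serial += 1

    z_b = gap + 4 * CB_LENGTH  # A tips at 2*CB; B tips at z_b - 2*CB
    serial = 1
    ys = np.arange(-3.0, (n_rows - 1) * SLAB_ROW_DY + 3.01, 3.0)
    xs = np.arange(-GRID_DX, covered_cols * GRID_DX + 0.1, GRID_DX)
    for y in ys:
        for x in xs:
            name = pick(True)
            residues.append(("B", name, serial, _occluder_residue(float(x), float(y), z_b)))
            serial += 1

    if jitter:
        residues = [
            (ch, nm, s, [(an, el, p + rng.uniform(-jitter, jitter, 3)) for an, el, p in ats])
            for ch, nm, s, ats in residues
        ]
    return atoms_to_pdb(residues)


def make_training_corpus(
    n_complexes: int = 50,
    signal: str = "strong",
    seed: int = 0,
    out_dir=None,
) -> list[str]:
    """A corpus of two-slab complexes with varied coverage and composition.

    Returns PDB texts (and writes ``complex_###.pdb`` files when ``out_dir``
    is given).  The per-complex seeds derive from ``seed`` so the corpus is
    reproducible as a whole.
    """
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    rng = np.random.default_rng(seed)
    texts = []
    for i in range(n_complexes):
        covered = int(rng.integers(3, 6))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        texts.append(
            make_two_slab_complex(
                n_rows=3, n_cols=12, covered_cols=covered,
                gap=4.0, seed=sub_seed, signal=signal,
            )
        )
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, text in enumerate(texts):
            (out / f"complex_{i:03d}.pdb").write_text(text)
    return texts
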