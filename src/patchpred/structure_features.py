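"""Structure-derived features: disulphides, hydrogen bonds, secondary
structure and patch planarity.

Disulphides are S-gamma pairs closer than 2.25 A (the mean bridge distance
plus a 10% tolerance for coordinate error).  Hydrogen bonds follow the
classical geometric rules: where the amide hydrogen can be rebuilt from the
backbone, H...acceptor <= 2.5 A with a 90-180 deg angle at the hydrogen;
otherwise donor...acceptor <= 3.35 A with a 90-180 deg angle at the donor
(antecedent-donor-acceptor).  Side-chain hydrogens are never built, so
side-chain donors always use the fallback rule.

Secondary structure is a Kabsch-Sander-style assignment: backbone H-bonds are
scored with the standard electrostatic energy and the -0.5 kcal/mol cutoff;
runs of i -> i+4 turns make helix (H), ladders of bridges make sheet (E), all
else is coil (C).  The patch-level class combines the member percentages:
helix-dominated (H), sheet-dominated (E), mixed (EH) or coil (C), with 20% as
the boundary on both axes.

Planarity is the RMS distance of the patch atoms from their best-fit plane
(the top-2 principal axes of the centred coordinates), i.e. the RMS residual
along the third principal axis.
"""

from __future__ import annotations

import warnings

import numpy as np

from .patches import Patch
from .structure import ChainStructure, ResidueId
from .tables import hbond_chemistry

SS_DISTANCE = 2.25       # A, S-gamma pair cutoff (strict <)
HA_DISTANCE = 2.50       # A, hydrogen...acceptor cutoff (<=)
DA_DISTANCE = 3.35       # A, donor...acceptor fallback cutoff (<=)
KS_ENERGY_CUTOFF = -0.5  # kcal/mol, Kabsch-Sander H-bond threshold


def detect_disulphides(chain: ChainStructure) -> dict[ResidueId, int]:
    """1 for cysteines whose S-gamma is < 2.25 A from another S-gamma."""
    out = {r.residue_id: 0 for r in chain.residues}
    sgs = [(r.residue_id, r.atom("SG").position)
           for r in chain.residues
           if r.residue_type == "CYS" and r.atom("SG") is not None]
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            if np.linalg.norm(sgs[i][1] - sgs[j][1]) < SS_DISTANCE:
                out[sgs[i][0]] = 1
                out[sgs[j][0]] = 1
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (deg) of the triangle a-b-c."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1, 1))))


def _amide_h(chain: ChainStructure, i: int) -> np.ndarray | None:
    """Rebuild the backbone amide hydrogen of residue i from N, CA, C(prev).

    H sits 1.0 A from N along the external bisector of the C(prev)-N and CA-N
    bonds.  Unavailable for the first residue, prolines, or missing atoms.
    """
    res = chain.residues[i]
    if res.residue_type == "PRO" or i == 0:
        return None
    n, ca = res.atom("N"), res.atom("CA")
    c_prev = chain.residues[i - 1].atom("C")
    if n is None or ca is None or c_prev is None:
        return None
    u = n.position - c_prev.position
    v = n.position - ca.position
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return None
    d = u / nu + v / nv
    nd = np.linalg.norm(d)
    if nd == 0:
        return None
    return n.position + d / nd


def detect_hydrogen_bonds(chain: ChainStructure) -> dict[ResidueId, int]:
    """1 for residues donating or accepting >=1 intra-chain hydrogen bond."""
    chem = hbond_chemistry()
    donors = []     # (res_index, donor_atom, antecedent_pos or None, h_computable)
    acceptors = []  # (res_index, acceptor_atom)
    for idx, res in enumerate(chain.residues):
        for entry in chem:
            if entry["residue"] not in ("*", res.residue_type):
                continue
            atom = res.atom(entry["atom"])
            if atom is None:
                continue
            if entry["residue"] == "*" and entry["atom"] == "N" and res.residue_type == "PRO":
                continue  # proline amide has no hydrogen
            ante = res.atom(entry["antecedent"])
            if entry["role"] in ("donor", "both"):
                donors.append((idx, atom, ante, entry["h_computable"]))
            if entry["role"] in ("acceptor", "both"):
                acceptors.append((idx, atom, ante))

    out = {r.residue_id: 0 for r in chain.residues}
    for d_idx, d_atom, d_ante, h_ok in donors:
        h_pos = _amide_h(chain, d_idx) if h_ok else None
        for a_idx, a_atom, _ in acceptors:
            if a_idx == d_idx:
                continue
            if a_atom is d_atom:
                continue
            bonded = False
            if h_pos is not None:
                ha = np.linalg.norm(h_pos - a_atom.position)
                if ha <= HA_DISTANCE and 90.0 <= _angle(
                    d_atom.position, h_pos, a_atom.position
                ) <= 180.0:
                    bonded = True
            else:
                da = np.linalg.norm(d_atom.position - a_atom.position)
                if da <= DA_DISTANCE and d_ante is not None and 90.0 <= _angle(
                    d_ante.position, d_atom.position, a_atom.position
                ) <= 180.0:
                    bonded = True
            if bonded:
                out[chain.residues[d_idx].residue_id] = 1
                out[chain.residues[a_idx].residue_id] = 1
    return out


# ---------------------------------------------------------------------------
# secondary structure (Kabsch-Sander style)
# ---------------------------------------------------------------------------

def _ks_hbonds(chain: ChainStructure) -> set[tuple[int, int]]:
    """Pairs (i, j): CO of residue i accepts the amide hydrogen of residue j.

    Energy = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN) kcal/mol with
    the amide H placed 1.0 A from N anti to the preceding carbonyl; bonds need
    E < -0.5 and sequence separation >= 2.
    """
    n_res = len(chain.residues)
    co = {}
    nh = {}
    for i, res in enumerate(chain.residues):
        c, o = res.atom("C"), res.atom("O")
        if c is not None and o is not None:
            co[i] = (c.position, o.position)
        n = res.atom("N")
        if n is None or res.residue_type == "PRO" or i == 0:
            continue
        c_prev, o_prev = chain.residues[i - 1].atom("C"), chain.residues[i - 1].atom("O")
        if c_prev is None or o_prev is None:
            continue
        d = c_prev.position - o_prev.position
        nd = np.linalg.norm(d)
        if nd == 0:
            continue
        nh[i] = (n.position, n.position + d / nd)

    bonds = set()
    q = 0.084 * 332.0
    for i, (c_pos, o_pos) in co.items():
        for j, (n_pos, h_pos) in nh.items():
            if abs(i - j) < 2:
                continue
            d_on = np.linalg.norm(o_pos - n_pos)
            d_ch = np.linalg.norm(c_pos - h_pos)
            d_oh = np.linalg.norm(o_pos - h_pos)
            d_cn = np.linalg.norm(c_pos - n_pos)
            if min(d_on, d_ch, d_oh, d_cn) < 0.5:
                continue  # clashing geometry, treat as no bond
            e = q * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
            if e < KS_ENERGY_CUTOFF:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(chain: ChainStructure) -> dict[ResidueId, str]:
    """Three-state assignment H / E / C per residue.

    4-turns (CO_i...HN_{i+4}) in consecutive pairs mark helix residues
    i+1..i+4; parallel/antiparallel bridge ladders (>= 2 consecutive bridge
    residues) mark sheet; everything else — including residues with missing
    backbone atoms and isolated single bridges — is coil.
    """
    n = len(chain.residues)
    bonds = _ks_hbonds(chain)
    hb = lambda i, j: (i, j) in bonds  # CO(i) <- NH(j)

    state = ["C"] * n
    # helices: two consecutive 4-turns
    turn4 = [hb(i, i + 4) for i in range(n)]
    for i in range(n - 5):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, i + 5):
                state[k] = "H"

    # bridges
    def par(i, j):
        return (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))

    def anti(i, j):
        return (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))

    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) >= 3 and (par(i, j) or anti(i, j)):
                bridge[i, j] = True
    in_bridge = bridge.any(axis=1)
    # ladders: runs of >=2 consecutive bridge residues
    for i in range(n):
        if not in_bridge[i]:
            continue
        neighbours = in_bridge[max(0, i - 1)] or (i + 1 < n and in_bridge[i + 1])
        if neighbours and state[i] != "H":
            state[i] = "E"
    return {r.residue_id: s for r, s in zip(chain.residues, state)}


def patch_ss_class(patch: Patch, assignment: dict[ResidueId, str]) -> str:
    """Patch class from member helix/sheet percentages, 20% boundaries.

    H: helix > 20% and sheet <= 20%; E: sheet > 20% and helix <= 20%;
    EH: both > 20%; C: both <= 20%.
    """
    members = patch.member_residue_ids
    states = [assignment[rid] for rid in members]
    alpha = 100.0 * states.count("H") / len(states)
    beta = 100.0 * states.count("E") / len(states)
    if alpha > 20.0 and beta <= 20.0:
        return "H"
    if alpha <= 20.0 and beta > 20.0:
        return "E"
    if alpha > 20.0 and beta > 20.0:
        return "EH"
    return "C"


SS_INDICATORS = ("helix", "sheet", "mix", "coil")
_SS_TO_INDICATOR = {"H": "helix", "E": "sheet", "EH": "mix", "C": "coil"}


def ss_class_indicators(ss_class: str) -> dict[str, int]:
    """Expand the nominal patch class into four binary indicator columns."""
    name = _SS_TO_INDICATOR[ss_class]
    return {ind: int(ind == name) for ind in SS_INDICATORS}


def patch_planarity(patch: Patch, chain: ChainStructure) -> float:
    """RMS distance (A) of all member-residue atoms from their best-fit plane.

    Equivalently the square root of the smallest eigenvalue of the coordinate
    covariance.  Degenerate patches (< 3 atoms or collinear) return 0.
    """
    coords = np.array([
        a.position
        for rid in patch.member_residue_ids
        for a in chain.residue_by_id(rid).atoms
    ])
    if len(coords) < 3:
        warnings.warn(f"patch at {patch.centre_residue_id}: <3 atoms, planarity 0")
        return 0.0
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    evals = np.linalg.eigvalsh(cov)
    if evals[1] <= 1e-12:  # collinear: no plane defined
        warnings.warn(f"patch at {patch.centre_residue_id}: collinear atoms, planarity 0")
        return 0.0
    return float(np.sqrt(max(evals[0], 0.0)))


def read_ss_override(path) -> dict[ResidueId, str]:
    """Optional per-residue override: TSV of chain, resnum, icode, state."""
    out = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chain\t"):
            continue
        c, num, icode, s = line.split("\t")
        if s not in ("H", "E", "C"):
            raise ValueError(f"bad secondary-structure state {s!r}")
        out[(c, int(num), icode)] = s
    return out
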