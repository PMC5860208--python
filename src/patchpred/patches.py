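"""Surface decomposition into overlapping patches.

A patch is grown around a highly exposed centre atom: residues with any atom
within the patch radius are candidates, and candidate atoms are pulled in,
sweep by sweep, when they touch an atom already in the patch *and* the two
residues' solvent vectors diverge by less than the angle threshold.  The angle
test keeps residues on opposite walls of a pocket out of the same patch, so a
patch is a contiguous cap of surface rather than everything inside a sphere.

The residue *geometry vector* runs from the C-alpha to the centroid of the
10 spatially closest C-alphas; the *solvent vector* is its negation and points
away from the body of the protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .structure import AtomRecord, ChainStructure, ResidueId, ResidueView


@dataclass
class GeometryVectors:
    residue_id: ResidueId
    geometry_vector: np.ndarray | None  # None when the residue has no C-alpha
    @property
    def solvent_vector(self) -> np.ndarray | None:
        return None if self.geometry_vector is None else -self.geometry_vector


@dataclass
class Patch:
    centre_residue_id: ResidueId
    centre_atom_name: str
    member_residue_ids: list[ResidueId]
    patch_radius: float
    class_label: str | None = None  # I | S | U
    f_asa: float | None = None
    features: dict = field(default_factory=dict)

    def __contains__(self, residue_id: ResidueId) -> bool:
        return residue_id in self.member_residue_ids


def residue_geometry_vector(
    residue: ResidueView, chain: ChainStructure, k: int = 10
) -> GeometryVectors:
    """Geometry vector of one residue: C-alpha -> centroid of k nearest C-alphas.

    Fewer than k neighbours uses all of them; ties at identical distance break
    toward the lower file index.  A residue without a C-alpha gets a ``None``
    vector and always fails downstream angle tests.
    """
    ca = residue.c_alpha
    if ca is None:
        return GeometryVectors(residue.residue_id, None)
    others = [
        (i, r.c_alpha)
        for i, r in enumerate(chain.residues)
        if r.residue_id != residue.residue_id and r.c_alpha is not None
    ]
    if not others:
        return GeometryVectors(residue.residue_id, np.zeros(3))
    d = np.array([np.linalg.norm(p - ca) for _, p in others])
    order = np.lexsort((np.array([i for i, _ in others]), d))
    chosen = order[: min(k, len(others))]
    centroid = np.mean([others[j][1] for j in chosen], axis=0)
    return GeometryVectors(residue.residue_id, centroid - ca)


def solvent_angle(a: GeometryVectors, b: GeometryVectors) -> float:
    """Angle (deg, in [0, 180]) between two residues' solvent vectors.

    A zero-length vector makes the angle undefined; by convention it is
    returned as 0 so that degenerate (perfectly symmetric) neighbourhoods do
    not fragment flat surfaces.
    """
    va, vb = a.solvent_vector, b.solvent_vector
    if va is None or vb is None:
        raise ValueError("solvent angle undefined for residues without C-alpha")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def in_contact(atom1: AtomRecord, atom2: AtomRecord, tolerance: float = 0.2) -> bool:
    """True iff centre distance < r1 + r2 + tolerance (strict)."""
    d = np.linalg.norm(atom1.position - atom2.position)
    return bool(d < atom1.vdw_radius + atom2.vdw_radius + tolerance)


def chain_geometry_vectors(
    chain: ChainStructure, k: int = 10
) -> dict[ResidueId, GeometryVectors]:
    return {
        r.residue_id: residue_geometry_vector(r, chain, k) for r in chain.residues
    }


def _angle_passes(
    gv: dict[ResidueId, GeometryVectors],
    rid_a: ResidueId,
    rid_b: ResidueId,
    threshold: float,
) -> bool:
    a, b = gv[rid_a], gv[rid_b]
    if a.geometry_vector is None or b.geometry_vector is None:
        return False  # no solvent vector: conservatively never pulled in
    return solvent_angle(a, b) < threshold


def contact_adjacency(
    atoms: list[AtomRecord], tolerance: float = 0.2
) -> list[set[int]]:
    """Per-atom sets of atom indices in vdW contact (distance < r1+r2+tol)."""
    import numpy as _np
    from scipy.spatial import cKDTree as _KD

    pos = _np.array([a.position for a in atoms])
    radii = _np.array([a.vdw_radius for a in atoms])
    adj: list[set[int]] = [set() for _ in atoms]
    if len(atoms) < 2:
        return adj
    tree = _KD(pos)
    for i, j in tree.query_pairs(2.0 * radii.max() + tolerance):
        if _np.linalg.norm(pos[i] - pos[j]) < radii[i] + radii[j] + tolerance:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def grow_patch(
    chain: ChainStructure,
    centre_atom: AtomRecord,
    patch_radius: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
    geometry: dict[ResidueId, GeometryVectors] | None = None,
    adjacency: list[set[int]] | None = None,
) -> Patch:
    """Grow one patch around a centre atom to its fixed point.

    1. the patch P starts as the centre atom;
    2. candidates C are all atoms of residues with >=1 atom centre within the
       patch radius of the centre atom;
    3. any candidate in contact with a patch atom whose residues pass the
       solvent-angle test moves to P;
    4. sweeps repeat until nothing moves;
    5. members are the residues contributing >=1 atom to P.

    The result is a fixed point, so the within-sweep visiting order cannot
    change the final membership.
    """
    radius = config.patch_radius if patch_radius is None else patch_radius
    atoms = chain.atoms
    try:
        centre_idx = next(i for i, a in enumerate(atoms) if a is centre_atom)
    except StopIteration:
        raise ValueError("centre atom does not belong to the chain")
    if geometry is None:
        geometry = chain_geometry_vectors(chain, config.neighbour_count)
    if adjacency is None:
        adjacency = contact_adjacency(atoms, config.contact_tolerance)

    centre_pos = centre_atom.position
    pos = np.array([a.position for a in atoms])
    dist_to_centre = np.linalg.norm(pos - centre_pos, axis=1)
    candidate_rids = {
        atoms[i].residue_id for i in np.nonzero(dist_to_centre <= radius)[0]
    }
    cand = [
        i for i, a in enumerate(atoms)
        if a.residue_id in candidate_rids and i != centre_idx
    ]

    in_patch = [centre_idx]
    patch_set = {centre_idx}
    angle_cache: dict[tuple[ResidueId, ResidueId], bool] = {}

    def pair_ok(rid_a, rid_b):
        key = (rid_a, rid_b)
        if key not in angle_cache:
            ok = _angle_passes(geometry, rid_a, rid_b, config.solvent_angle_threshold)
            angle_cache[key] = ok
            angle_cache[(rid_b, rid_a)] = ok
        return angle_cache[key]

    moved = True
    while moved:
        moved = False
        remaining = []
        for i in cand:
            rid_i = atoms[i].residue_id
            pulled = any(
                pair_ok(rid_i, atoms[j].residue_id)
                for j in adjacency[i] if j in patch_set
            )
            if pulled:
                in_patch.append(i)
                patch_set.add(i)
                moved = True
            else:
                remaining.append(i)
        cand = remaining

    member_rids: list[ResidueId] = []
    in_set = {atoms[i].residue_id for i in in_patch}
    for r in chain.residues:  # ordered by file position
        if r.residue_id in in_set:
            member_rids.append(r.residue_id)
    return Patch(
        centre_residue_id=centre_atom.residue_id,
        centre_atom_name=centre_atom.atom_name,
        member_residue_ids=member_rids,
        patch_radius=radius,
    )


def select_patch_centres(
    chain: ChainStructure, config: RunConfig = DEFAULT_CONFIG
) -> list[tuple[ResidueId, str]]:
    """One centre per residue with isolated-state RASA strictly above 25%.

    The centre atom is the residue's highest-ASA atom (isolated state); ties
    break to the first atom in file order.
    """
    centres = []
    for r in chain.residues:
        if r.rasa_isolated is None or r.rasa_isolated <= config.centre_rasa_threshold:
            continue
        best = max(r.atoms, key=lambda a: a.asa_isolated)  # max keeps first on ties
        centres.append((r.residue_id, best.atom_name))
    return centres


def make_patches(
    chain: ChainStructure,
    patch_radius: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[Patch]:
    """All surface patches of a chain, one per centre, in residue order."""
    geometry = chain_geometry_vectors(chain, config.neighbour_count)
    adjacency = contact_adjacency(chain.atoms, config.contact_tolerance)
    patches = []
    for rid, atom_name in select_patch_centres(chain, config):
        centre = chain.residue_by_id(rid).atom(atom_name)
        patches.append(
            grow_patch(chain, centre, patch_radius, config, geometry, adjacency)
        )
    return patches


def patches_to_tsv(patches: list[Patch]) -> str:
    """Serialise patches: chain, centre, radius, semicolon-joined member ids."""
    lines = ["chain\tcentre_resnum\tcentre_icode\tcentre_atom\tradius\tmembers"]
    for p in patches:
        members = ";".join(f"{c}/{n}/{i}" for c, n, i in p.member_residue_ids)
        c, n, i = p.centre_residue_id
        lines.append(f"{c}\t{n}\t{i}\t{p.centre_atom_name}\t{p.patch_radius:g}\t{members}")
    return "\n".join(lines) + "\n"
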