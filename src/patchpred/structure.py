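"""Atomic model: PDB reading and solvent accessibility in two states.

A protein chain is held as a list of residues, each a list of heavy atoms.
Solvent-accessible surface area (ASA) is computed twice for every chain of a
complex: once with all chains present (the *complexed* state) and once with the
chain extracted on its own (the *isolated* state).  The drop in relative
accessibility (RASA) between the two states is what defines interface residues
downstream.

ASA uses the Shrake-Rupley sphere-point method with a deterministic spiral
point lattice, so identical inputs give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, RunConfig
from .tables import THREE_TO_ONE, element_radius, max_asa, vdw_radii

ResidueId = tuple[str, int, str]  # (chain_id, residue_number, insertion code)


@dataclass
class AtomRecord:
    chain_id: str
    residue_number: int
    icode: str
    residue_type: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), A
    occupancy: float
    vdw_radius: float
    asa_isolated: float | None = None
    asa_complexed: float | None = None

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_number, self.icode)


@dataclass
class ResidueView:
    residue_id: ResidueId
    residue_type: str
    atoms: list[AtomRecord] = field(default_factory=list)
    asa_total_isolated: float | None = None
    asa_total_complexed: float | None = None
    rasa_isolated: float | None = None
    rasa_complexed: float | None = None

    @property
    def c_alpha(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.atom_name == "CA":
                return a.position
        return None

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class ChainStructure:
    chain_id: str
    residues: list[ResidueView] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.residue_type, "X") for r in self.residues)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def residue_by_id(self, residue_id: ResidueId) -> ResidueView:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        raise KeyError(residue_id)


class StructureParseError(ValueError):
    pass


def read_structure(path, config: RunConfig = DEFAULT_CONFIG) -> list[ChainStructure]:
    """Parse a PDB file into protein chains of heavy atoms.

    First MODEL only; waters and heteroatoms are dropped (selenomethionine is
    mapped to methionine); hydrogens are discarded; alternate locations resolve
    to the highest-occupancy conformer (ties to the first seen).  Residue
    numbering, insertion codes and file order are preserved.
    """
    radii = vdw_radii(config.radius_table_path)
    parser = PDBParser(QUIET=True)
    try:
        model = next(iter(parser.get_structure("s", str(path))))
    except StopIteration:
        raise StructureParseError(f"no MODEL found in {path}")
    except Exception as exc:  # Bio.PDB raises bare exceptions with line info
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    chains: list[ChainStructure] = []
    for bio_chain in model:
        chain = ChainStructure(chain_id=bio_chain.id)
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            resname = bio_res.get_resname().strip()
            if hetflag == "W":
                continue
            if hetflag.strip() and resname != "MSE":
                continue  # non-water heteroatom record
            if resname == "MSE":
                resname = "MET"
            if resname not in THREE_TO_ONE:
                continue
            res = ResidueView(
                residue_id=(bio_chain.id, int(resseq), icode.strip()),
                residue_type=resname,
            )
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    # keep the highest-occupancy altloc only
                    alts = bio_atom.disordered_get_list()
                    bio_atom = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
                element = (bio_atom.element or bio_atom.get_name()[0]).upper()
                if element == "H" or element == "D":
                    continue
                if resname == "MET" and bio_atom.get_name() == "SE":
                    atom_name = "SD"
                else:
                    atom_name = bio_atom.get_name()
                res.atoms.append(
                    AtomRecord(
                        chain_id=bio_chain.id,
                        residue_number=int(resseq),
                        icode=icode.strip(),
                        residue_type=resname,
                        atom_name=atom_name,
                        element=element,
                        position=np.asarray(bio_atom.get_coord(), dtype=float),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                        vdw_radius=element_radius(element, radii),
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if not chain.residues:
            warnings.warn(f"chain {bio_chain.id}: no standard residues, skipped")
            continue
        if config.filter_peptides and len(chain.residues) < config.min_chain_length:
            warnings.warn(
                f"chain {bio_chain.id}: {len(chain.residues)} residues "
                f"< {config.min_chain_length}, filtered as peptide"
            )
            continue
        chains.append(chain)
    return chains


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent accessibility
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic spiral lattice of n near-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_asa(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    point_density: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    A sphere of ``point_density`` lattice points is inflated to each atom's
    vdW radius + probe; the exposed fraction is the fraction of points outside
    every neighbouring atom's inflated sphere.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(positions)
    if n == 0:
        return np.zeros(0)
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    unit = _sphere_points(point_density)
    inflated = radii + probe_radius
    tree = cKDTree(positions)
    neighbours = tree.query_ball_point(positions, inflated + inflated.max())
    out = np.empty(n)
    for i in range(n):
        r_i = inflated[i]
        pts = positions[i] + r_i * unit
        neigh = [j for j in neighbours[i] if j != i]
        if not neigh:
            out[i] = 4.0 * np.pi * r_i ** 2
            continue
        diff = pts[:, None, :] - positions[neigh][None, :, :]
        d2 = np.einsum("pjk,pjk->pj", diff, diff)
        exposed = (d2 >= inflated[neigh] ** 2).all(axis=1)
        out[i] = exposed.sum() / point_density * 4.0 * np.pi * r_i ** 2
    return out


def compute_rasa(
    residue: ResidueView,
    state: str,
    reference: dict[str, float] | None = None,
) -> float | None:
    """Relative solvent accessibility (%) against the per-type maximum table.

    Values above 100% clamp to 100.  Unknown residue types give ``None`` (the
    residue is then ineligible as a patch centre).
    """
    reference = reference if reference is not None else max_asa()
    total = {"isolated": residue.asa_total_isolated,
             "complexed": residue.asa_total_complexed}[state]
    if total is None:
        raise ValueError(f"ASA for state {state!r} not computed")
    ref = reference.get(residue.residue_type)
    if ref is None or ref <= 0:
        warnings.warn(f"no RASA reference for {residue.residue_type}")
        return None
    return min(100.0, 100.0 * total / ref)


def _fill_state(chains: list[ChainStructure], state: str, config: RunConfig) -> None:
    atoms = [a for c in chains for a in c.atoms]
    vals = compute_asa(
        np.array([a.position for a in atoms]),
        np.array([a.vdw_radius for a in atoms]),
        config.probe_radius,
        config.point_density,
    )
    for a, v in zip(atoms, vals):
        setattr(a, f"asa_{state}", float(v))
    reference = max_asa(config.rasa_reference_path)
    for c in chains:
        for r in c.residues:
            total = float(sum(getattr(a, f"asa_{state}") for a in r.atoms))
            setattr(r, f"asa_total_{state}", total)
            setattr(r, f"rasa_{state}", compute_rasa(r, state, reference))


def annotate_accessibility(
    chains: list[ChainStructure], config: RunConfig = DEFAULT_CONFIG
) -> list[ChainStructure]:
    """Fill both accessibility states on every chain of a (possibly 1-chain) complex.

    Complexed: ASA with every chain present.  Isolated: each chain alone.
    For a monomer the two states coincide.
    """
    _fill_state(chains, "complexed", config)
    for chain in chains:
        _fill_state([chain], "isolated", config)
    return chains


def isolate_chain(
    chains: list[ChainStructure], chain_id: str, config: RunConfig = DEFAULT_CONFIG
) -> ChainStructure:
    """Return one chain carrying both complexed- and isolated-state ASA."""
    ids = [c.chain_id for c in chains]
    if chain_id not in ids:
        raise KeyError(f"chain {chain_id!r} not present; available: {ids}")
    chain = chains[ids.index(chain_id)]
    if chain.residues[0].asa_total_complexed is None:
        annotate_accessibility(chains, config)
    return chain
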