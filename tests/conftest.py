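"""Shared fixtures: in-memory chains and small synthetic corpora."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from patchpred.config import RunConfig
from patchpred.structure import AtomRecord, ChainStructure, ResidueView
from patchpred.tables import element_radius


def build_chain(residue_specs, chain_id="A", start=1) -> ChainStructure:
    """Construct a ChainStructure directly from (resname, [(atom, elem, xyz)])."""
    chain = ChainStructure(chain_id=chain_id)
    for k, (resname, atoms) in enumerate(residue_specs):
        res = ResidueView(
            residue_id=(chain_id, start + k, ""), residue_type=resname
        )
        for name, element, pos in atoms:
            res.atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=start + k,
                    icode="",
                    residue_type=resname,
                    atom_name=name,
                    element=element,
                    position=np.asarray(pos, dtype=float),
                    occupancy=1.0,
                    vdw_radius=element_radius(element),
                )
            )
        chain.residues.append(res)
    return chain


def random_micro_chain(rng: np.random.Generator, max_residues: int = 30) -> ChainStructure:
    """A compact random blob of residues for exhaustive patch oracles."""
    n = int(rng.integers(5, max_residues + 1))
    specs = []
    pos = np.zeros(3)
    names = ["ALA", "GLY", "SER", "LEU", "THR", "VAL"]
    for i in range(n):
        pos = pos + rng.normal(0, 1, 3) * 2.0
        atoms = [("CA", "C", pos.copy())]
        for j in range(int(rng.integers(0, 3))):
            atoms.append(
                (f"X{j}", rng.choice(["C", "N", "O"]), pos + rng.normal(0, 1, 3) * 1.4)
            )
        specs.append((names[int(rng.integers(len(names)))], atoms))
    return build_chain(specs)


@pytest.fixture(scope="session")
def small_strong_corpus(tmp_path_factory):
    """12 two-slab complexes with planted compositional signal, featurised."""
    from patchpred.pipeline import build_corpus_matrix
    from patchpred.synthetic import make_training_corpus

    d = tmp_path_factory.mktemp("corpus_strong")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        make_training_corpus(12, "strong", seed=7, out_dir=d)
        data = build_corpus_matrix(sorted(d.glob("*.pdb")), chain_ids=["A"])
    return d, data


@pytest.fixture(scope="session")
def two_slab_annotated(tmp_path_factory):
    """One gap-4 two-slab complex with both ASA states filled."""
    from patchpred.structure import annotate_accessibility, read_structure
    from patchpred.synthetic import make_two_slab_complex

    d = tmp_path_factory.mktemp("slab")
    path = d / "slab.pdb"
    path.write_text(make_two_slab_complex(seed=11))
    chains = read_structure(path)
    annotate_accessibility(chains)
    return path, chains


@pytest.fixture()
def default_config():
    return RunConfig()
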