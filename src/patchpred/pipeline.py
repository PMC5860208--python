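"""End-to-end orchestration: structure -> patches -> labels -> feature matrix.

The per-patch feature vector has eleven columns, in a fixed schema:

    prop      mean interface propensity of member residues
    hpho      mean Kyte-Doolittle hydropathy
    homology  mean homologue-alignment conservation (may be missing)
    FEP       mean functionally-equivalent-protein conservation (may be missing)
    SS        mean disulphide-bond indicator
    Hb        mean hydrogen-bond indicator
    helix/sheet/mix/coil   the four binary patch secondary-structure indicators
    pln       planarity (A)

plus, when ground truth is available, the binary ``intf`` label (I patches 1,
S patches 0, U patches carried with label NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .labeling import label_interface_residues, label_patches
from .patches import Patch, make_patches
from .sequence_features import (
    PropensityTable,
    TrainingResidue,
    build_propensity_table,
    collect_training_residues,
    patch_mean_feature,
    residue_hydrophobicity,
    residue_propensity,
)
from .structure import ChainStructure, annotate_accessibility, read_structure
from .structure_features import (
    assign_secondary_structure,
    detect_disulphides,
    detect_hydrogen_bonds,
    patch_planarity,
    patch_ss_class,
    ss_class_indicators,
)

FEATURE_COLUMNS = [
    "prop", "hpho", "homology", "FEP", "SS", "Hb",
    "helix", "sheet", "mix", "coil", "pln",
]


@dataclass
class CorpusData:
    """A featurised corpus: patch matrix, propensity table and provenance."""
    matrix: pd.DataFrame
    table: PropensityTable
    per_chain: dict
    residues_by_complex: dict[str, list]


def recompute_propensity_column(
    matrix: pd.DataFrame, table: PropensityTable
) -> pd.Series:
    """The ``prop`` column re-evaluated against a different propensity table."""
    out = []
    for comp in matrix["_member_comp"]:
        vals = [
            v for v in (residue_propensity(t, asa, table) for t, asa in comp)
            if not math.isnan(v)
        ]
        out.append(float(np.mean(vals)) if vals else float("nan"))
    return pd.Series(out, index=matrix.index)


def featurize_chain(
    chain: ChainStructure,
    patches: list[Patch],
    table: PropensityTable,
    conservation_homology: dict | None = None,
    conservation_fep: dict | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature matrix with one row per patch (index: patch position)."""
    prop = {
        r.residue_id: residue_propensity(r.residue_type, r.asa_total_isolated or 0.0, table)
        for r in chain.residues
    }
    hpho = {r.residue_id: residue_hydrophobicity(r.residue_type) for r in chain.residues}
    ss_bond = {k: float(v) for k, v in detect_disulphides(chain).items()}
    hbond = {k: float(v) for k, v in detect_hydrogen_bonds(chain).items()}
    ss_assign = assign_secondary_structure(chain)
    nan_map = {r.residue_id: float("nan") for r in chain.residues}
    homology = conservation_homology if conservation_homology is not None else nan_map
    fep = conservation_fep if conservation_fep is not None else nan_map

    comp = {
        r.residue_id: (r.residue_type, r.asa_total_isolated or 0.0)
        for r in chain.residues
    }
    rows = []
    members = []
    for p in patches:
        row = {
            "prop": patch_mean_feature(p, prop),
            "hpho": patch_mean_feature(p, hpho),
            "homology": patch_mean_feature(p, homology),
            "FEP": patch_mean_feature(p, fep),
            "SS": patch_mean_feature(p, ss_bond),
            "Hb": patch_mean_feature(p, hbond),
        }
        row.update(ss_class_indicators(patch_ss_class(p, ss_assign)))
        row["pln"] = patch_planarity(p, chain)
        if p.class_label is not None:
            row["intf"] = {"I": 1.0, "S": 0.0}.get(p.class_label, float("nan"))
        rows.append(row)
        members.append(tuple(comp[rid] for rid in p.member_residue_ids))
        p.features = row
    cols = FEATURE_COLUMNS + (["intf"] if rows and "intf" in rows[0] else [])
    df = pd.DataFrame(rows, columns=cols)
    # member composition (type, isolated ASA) kept alongside so the propensity
    # column can be recomputed against a different table (per-fold CV)
    df["_member_comp"] = members
    return df


def process_complex(
    pdb_path,
    config: RunConfig = DEFAULT_CONFIG,
    patch_radius: float | None = None,
):
    """Read a complex, compute both ASA states, build and label patches.

    Returns ``(chains, {chain_id: labelled patches})``; patch features are not
    yet attached (they need a propensity table).
    """
    chains = read_structure(pdb_path, config)
    annotate_accessibility(chains, config)
    patches = {}
    for chain in chains:
        ps = make_patches(chain, patch_radius, config)
        label_patches(ps, chain, config)
        patches[chain.chain_id] = ps
    return chains, patches


def corpus_training_residues(
    chains_per_complex: list[list[ChainStructure]],
    config: RunConfig = DEFAULT_CONFIG,
) -> list[TrainingResidue]:
    """Pool labelled residues from many complexes for the propensity table."""
    residues = []
    for chains in chains_per_complex:
        for chain in chains:
            ann = label_interface_residues(chain, config)
            residues.extend(
                collect_training_residues(chain, ann, config.surface_rasa_threshold)
            )
    return residues


def build_corpus_matrix(
    pdb_paths,
    config: RunConfig = DEFAULT_CONFIG,
    patch_radius: float | None = None,
    table: PropensityTable | None = None,
    chain_ids: list[str] | None = None,
):
    """Full featurisation of a corpus of complexes.

    When no propensity table is given, one is built from the corpus's own
    labelled residues (the training situation).  ``chain_ids`` restricts the
    patch rows (and propensity statistics) to the named chains of every
    complex — partner chains still occlude, they just contribute no rows.
    Returns ``(matrix, table, per_chain)`` where matrix stacks every chain's
    patch features (with ``intf`` labels and a ``complex``/``chain`` index)
    and per_chain maps (path, chain_id) to its (chain, patches) pair.
    """
    processed = []
    for path in pdb_paths:
        chains, patches = process_complex(path, config, patch_radius)
        if chain_ids is not None:
            chains = [c for c in chains if c.chain_id in chain_ids]
        processed.append((path, chains, patches))
    residues_by_complex = {
        str(path): corpus_training_residues([chains], config)
        for path, chains, _ in processed
    }
    if table is None:
        table = build_propensity_table(
            [r for rs in residues_by_complex.values() for r in rs],
            provenance="corpus",
        )
    frames = []
    per_chain = {}
    for path, chains, patches in processed:
        for chain in chains:
            df = featurize_chain(chain, patches[chain.chain_id], table, config=config)
            df.insert(0, "complex", str(path))
            df.insert(1, "chain", chain.chain_id)
            frames.append(df)
            per_chain[(str(path), chain.chain_id)] = (chain, patches[chain.chain_id])
    matrix = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return CorpusData(matrix, table, per_chain, residues_by_complex)
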