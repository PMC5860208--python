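"""Ground-truth interface labels for residues and patches.

A residue is *interface* when its relative accessibility drops by at least 10
percentage points between the isolated and complexed states.  A patch's
*interface fraction* is the share of its summed isolated-state RASA that is
contributed by interface members; the patch class is I (interface) at fraction
>= 0.5, S (surface) at exactly 0, and U (unlabelled rim) in between.  U
patches are kept here and filtered only by the training-set assembler and the
patch-level evaluator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .config import DEFAULT_CONFIG, RunConfig
from .patches import Patch
from .structure import ChainStructure, ResidueId


@dataclass
class InterfaceAnnotation:
    residue_id: ResidueId
    delta_rasa: float  # percentage points, isolated - complexed
    is_interface: bool


def label_interface_residues(
    chain: ChainStructure, config: RunConfig = DEFAULT_CONFIG
) -> list[InterfaceAnnotation]:
    """Per-residue interface labels from the two accessibility states."""
    out = []
    for r in chain.residues:
        if r.rasa_isolated is None or r.rasa_complexed is None:
            out.append(InterfaceAnnotation(r.residue_id, 0.0, False))
            continue
        delta = r.rasa_isolated - r.rasa_complexed
        out.append(
            InterfaceAnnotation(r.residue_id, delta, delta >= config.interface_delta_rasa)
        )
    return out


def interface_fraction(
    patch: Patch,
    annotations: dict[ResidueId, InterfaceAnnotation],
    rasa_isolated: dict[ResidueId, float | None],
) -> float:
    """Share of the patch's isolated-state RASA carried by interface residues."""
    denom = 0.0
    numer = 0.0
    for rid in patch.member_residue_ids:
        rasa = rasa_isolated.get(rid)
        if rasa is None:
            continue
        denom += rasa
        if annotations[rid].is_interface:
            numer += rasa
    if denom == 0.0:
        warnings.warn(f"patch at {patch.centre_residue_id}: zero total RASA")
        return 0.0
    return numer / denom


def assign_patch_class(f_asa: float) -> str:
    """I at fraction >= 0.5, S at exactly 0, U otherwise (rim patches)."""
    if not 0.0 <= f_asa <= 1.0:
        raise ValueError(f"interface fraction {f_asa} outside [0, 1]")
    if f_asa >= 0.5:
        return "I"
    if f_asa == 0.0:
        return "S"
    return "U"


def label_patches(
    patches: list[Patch],
    chain: ChainStructure,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[Patch]:
    """Attach f_asa and I/S/U class to every patch, in place."""
    ann = {a.residue_id: a for a in label_interface_residues(chain, config)}
    rasa = {r.residue_id: r.rasa_isolated for r in chain.residues}
    for p in patches:
        p.f_asa = interface_fraction(p, ann, rasa)
        p.class_label = assign_patch_class(p.f_asa)
    return patches


def labels_to_tsv(annotations: list[InterfaceAnnotation]) -> str:
    lines = ["chain\tresnum\ticode\tdelta_rasa\tresidue_label"]
    for a in annotations:
        c, n, i = a.residue_id
        lab = "interface" if a.is_interface else "non-interface"
        lines.append(f"{c}\t{n}\t{i}\t{a.delta_rasa:.4f}\t{lab}")
    return "\n".join(lines) + "\n"
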