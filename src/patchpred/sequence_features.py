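"""Sequence-derived residue features: hydrophobicity, interface propensity and
two alignment-based conservation scores.

The propensity of a residue of type X is

    ln(F_intf(X) / F_surf(X)) * ASA(i) / mean_surface_ASA(X)

where F_intf(X) / F_surf(X) are the fractions of the training set's interface /
surface accessible area contributed by type X.  Scaling by the residue's own
isolated-state ASA weights each residue by how exposed it actually is, and the
per-type mean surface ASA removes the bias toward bulky types.  Positive
values mean the type is over-represented at interfaces.

Conservation is scored per alignment column with the Valdar (2001) weighted
sum-of-pairs formulation; two alignments feed it: a family of functionally
equivalent proteins (FEP score) and a homologue set from a sequence search
(homology score).  Alignments are consumed as pre-built aligned FASTA files —
no network access — but the original admission filters are enforced on the
supplied metadata by the gatekeeper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patches import Patch
from .structure import ChainStructure, ResidueId
from .tables import kyte_doolittle


# ---------------------------------------------------------------------------
# interface propensity (training-set statistics)
# ---------------------------------------------------------------------------

@dataclass
class PropensityTable:
    f_intf: dict[str, float]
    f_surf: dict[str, float]
    mean_surface_asa: dict[str, float]
    provenance: str = ""

    def to_tsv(self) -> str:
        types = sorted(set(self.f_intf) | set(self.f_surf))
        lines = [f"# provenance: {self.provenance}",
                 "type\tf_intf\tf_surf\tmean_surface_asa"]
        for t in types:
            lines.append(
                f"{t}\t{self.f_intf.get(t, 0.0):.10g}\t{self.f_surf.get(t, 0.0):.10g}"
                f"\t{self.mean_surface_asa.get(t, float('nan')):.10g}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PropensityTable":
        f_intf, f_surf, mean_asa = {}, {}, {}
        provenance = ""
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("# provenance:"):
                provenance = line.split(":", 1)[1].strip()
                continue
            if not line or line.startswith("#") or line.startswith("type\t"):
                continue
            t, fi, fs, ma = line.split("\t")
            f_intf[t], f_surf[t], mean_asa[t] = float(fi), float(fs), float(ma)
        return cls(f_intf, f_surf, mean_asa, provenance)


@dataclass
class TrainingResidue:
    """One training-set residue: its type, isolated ASA and label category."""
    residue_type: str
    asa_isolated: float
    category: str  # interface | surface | buried


def collect_training_residues(
    chain: ChainStructure,
    annotations,
    surface_rasa_threshold: float = 10.0,
) -> list[TrainingResidue]:
    """Partition a labelled chain into interface / surface / buried residues.

    Surface means isolated-state RASA >= the threshold and not interface; the
    buried remainder contributes to neither propensity fraction.
    """
    ann = {a.residue_id: a for a in annotations}
    out = []
    for r in chain.residues:
        if r.asa_total_isolated is None:
            continue
        if ann[r.residue_id].is_interface:
            cat = "interface"
        elif r.rasa_isolated is not None and r.rasa_isolated >= surface_rasa_threshold:
            cat = "surface"
        else:
            cat = "buried"
        out.append(TrainingResidue(r.residue_type, r.asa_total_isolated, cat))
    return out


def build_propensity_table(
    residues: list[TrainingResidue], provenance: str = ""
) -> PropensityTable:
    """Interface/surface ASA fractions and per-type mean surface ASA."""
    intf_by_type: dict[str, float] = {}
    surf_by_type: dict[str, float] = {}
    surf_asa_lists: dict[str, list[float]] = {}
    for res in residues:
        if res.category == "interface":
            intf_by_type[res.residue_type] = (
                intf_by_type.get(res.residue_type, 0.0) + res.asa_isolated
            )
        elif res.category == "surface":
            surf_by_type[res.residue_type] = (
                surf_by_type.get(res.residue_type, 0.0) + res.asa_isolated
            )
            surf_asa_lists.setdefault(res.residue_type, []).append(res.asa_isolated)
    intf_total = sum(intf_by_type.values())
    surf_total = sum(surf_by_type.values())
    if intf_total == 0 or surf_total == 0:
        raise ValueError("training residues must include both interface and surface sets")
    f_intf = {t: v / intf_total for t, v in intf_by_type.items()}
    f_surf = {t: v / surf_total for t, v in surf_by_type.items()}
    mean_surface_asa = {t: float(np.mean(v)) for t, v in surf_asa_lists.items()}
    missing = set(f_intf) ^ set(f_surf)
    if missing:
        warnings.warn(f"types absent from one set, propensity undefined: {sorted(missing)}")
    return PropensityTable(f_intf, f_surf, mean_surface_asa, provenance)


def residue_propensity(
    residue_type: str, asa_isolated: float, table: PropensityTable
) -> float:
    """Log-ratio propensity scaled by the residue's own exposure; NaN if undefined."""
    fi = table.f_intf.get(residue_type)
    fs = table.f_surf.get(residue_type)
    mean = table.mean_surface_asa.get(residue_type)
    if not fi or not fs or not mean:
        return float("nan")
    return math.log(fi / fs) * asa_isolated / mean


def residue_hydrophobicity(residue_type: str) -> float:
    """Kyte-Doolittle hydropathy; NaN for non-standard types."""
    return kyte_doolittle().get(residue_type, float("nan"))


def patch_mean_feature(
    patch: Patch, values: dict[ResidueId, float]
) -> float:
    """Arithmetic mean of a residue feature over patch members, NaN-aware.

    Members with undefined (missing/NaN) values are left out of the mean; if
    no member has a value the patch feature is missing (NaN).
    """
    vals = [
        values[rid] for rid in patch.member_residue_ids
        if rid in values and values[rid] is not None and not math.isnan(values[rid])
    ]
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Valdar (2001) conservation
# ---------------------------------------------------------------------------

_GAPS = set("-.")


def _normalised_matrix(path: str | None = None) -> tuple[dict[tuple[str, str], float], str]:
    """Pairwise amino-acid similarity in [0, 1] with unit self-similarity.

    Default: the PET91-family JONES matrix shipped with Biopython, shifted to
    be non-negative and then diagonal-normalised (m(a,b)/sqrt(m(a,a)m(b,b)))
    so every identity scores exactly 1.  A custom TSV (header row+col of
    one-letter codes) may be supplied instead.
    """
    if path is not None:
        rows = [l.split("\t") for l in Path(path).read_text().splitlines()
                if l.strip() and not l.startswith("#")]
        alphabet = rows[0][1:]
        raw = {
            (r[0], a): float(v) for r in rows[1:] for a, v in zip(alphabet, r[1:])
        }
        alpha = "".join(alphabet)
    else:
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("JONES")
        alpha = str(m.alphabet)
        raw = {(a, b): float(m[a, b]) for a in alpha for b in alpha}
    lo = min(raw.values())
    hi = max(raw.values())
    shifted = {k: (v - lo) / (hi - lo) for k, v in raw.items()}
    out = {}
    for a in alpha:
        for b in alpha:
            denom = math.sqrt(shifted[(a, a)] * shifted[(b, b)])
            out[(a, b)] = min(1.0, shifted[(a, b)] / denom) if denom > 0 else 0.0
    return out, alpha


def _pair_sim(a: str, b: str, m: dict[tuple[str, str], float]) -> float:
    if a in _GAPS or b in _GAPS:
        return 0.0
    return m.get((a, b), 0.0)


def valdar01_scores(
    sequences: list[str],
    target_index: int = 0,
    matrix_path: str | None = None,
) -> list[float]:
    """Per-residue conservation of the target sequence, Valdar (2001) style.

    Column score = lambda * sum_{i<j} w_i w_j m(s_i, s_j), lambda normalising
    the pair weights to 1.  Sequence weights favour divergent sequences: w_i is
    the mean matrix distance (1 - mean pair similarity over shared non-gap
    columns) of sequence i to every other sequence.  When all weights vanish
    (identical sequences) uniform weights are used.  Gap pairs score 0;
    all-gap columns score 0.  Scores are reported per *target residue*,
    skipping columns where the target is gapped.

    Fewer than two sequences: every residue score is NaN (missing feature).
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        target = seqs[target_index] if seqs else ""
        return [float("nan")] * sum(1 for c in target if c not in _GAPS)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must share one length")
    m, _ = _normalised_matrix(matrix_path)
    n = len(seqs)

    # sequence weights from mean pairwise matrix distance
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cols = [
                m[(seqs[i][x], seqs[j][x])]
                for x in range(length)
                if seqs[i][x] not in _GAPS and seqs[j][x] not in _GAPS
                and (seqs[i][x], seqs[j][x]) in m
            ]
            s = float(np.mean(cols)) if cols else 0.0
            sim[i, j] = sim[j, i] = s
    w = np.array([np.mean([1.0 - sim[i, j] for j in range(n) if j != i]) for i in range(n)])
    pair_norm = sum(w[i] * w[j] for i in range(n) for j in range(i + 1, n))
    if pair_norm == 0.0:
        w = np.ones(n)
        pair_norm = n * (n - 1) / 2.0

    scores = []
    target = seqs[target_index]
    for x in range(length):
        if target[x] in _GAPS:
            continue
        if all(s[x] in _GAPS for s in seqs):
            scores.append(0.0)
            continue
        total = sum(
            w[i] * w[j] * _pair_sim(seqs[i][x], seqs[j][x], m)
            for i in range(n) for j in range(i + 1, n)
        )
        scores.append(total / pair_norm)
    return scores


# ---------------------------------------------------------------------------
# alignment provider + admission gatekeeper
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSet:
    """A pre-built aligned sequence set with optional search metadata."""
    sequences: list[str]
    ids: list[str]
    e_values: list[float | None] = field(default_factory=list)
    descriptions: list[str] = field(default_factory=list)
    target_index: int = 0


_FLAGGED_TERMS = ("putative", "predicted", "hypothetical")


def alignment_gatekeeper(
    aln: AlignmentSet,
    kind: str,
    min_members: int = 10,
    max_hits: int = 200,
    e_value_cutoff: float = 0.01,
) -> AlignmentSet | None:
    """Admission filters for the two conservation alignments.

    FEP families are accepted when they hold at least nine members besides the
    target (>=10 sequences in total).  Homologue sets first drop hits with
    E-value > 0.01 or descriptions containing putative/predicted/hypothetical,
    need a minimum of 10 surviving matches, and keep at most the 200 best by
    ascending E-value.  Rejection returns None:
    the corresponding conservation feature is missing for the whole chain.
    """
    if kind == "fep":
        return aln if len(aln.sequences) >= min_members else None
    if kind != "homologue":
        raise ValueError(f"unknown alignment kind {kind!r}")

    keep = []
    for i in range(len(aln.sequences)):
        if i == aln.target_index:
            continue
        e = aln.e_values[i] if i < len(aln.e_values) else None
        desc = (aln.descriptions[i] if i < len(aln.descriptions) else "").lower()
        if e is not None and e > e_value_cutoff:
            continue
        if any(t in desc for t in _FLAGGED_TERMS):
            continue
        keep.append(i)
    if len(keep) < min_members:
        return None
    keep.sort(key=lambda i: (aln.e_values[i] if i < len(aln.e_values)
                             and aln.e_values[i] is not None else math.inf))
    keep = keep[:max_hits]
    idx = [aln.target_index] + keep
    return AlignmentSet(
        sequences=[aln.sequences[i] for i in idx],
        ids=[aln.ids[i] for i in idx],
        e_values=[aln.e_values[i] if i < len(aln.e_values) else None for i in idx],
        descriptions=[aln.descriptions[i] if i < len(aln.descriptions) else "" for i in idx],
        target_index=0,
    )


def read_alignment_fasta(path, sidecar_tsv=None, target_id: str | None = None) -> AlignmentSet:
    """Load an aligned FASTA (+ optional TSV of id, E-value, description).

    The target defaults to the first record; pass ``target_id`` to select it.
    """
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    meta: dict[str, tuple[float | None, str]] = {}
    if sidecar_tsv is not None:
        for line in Path(sidecar_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            sid = parts[0]
            e = float(parts[1]) if len(parts) > 1 and parts[1] not in ("", "NA") else None
            desc = parts[2] if len(parts) > 2 else ""
            meta[sid] = (e, desc)
    target_index = ids.index(target_id) if target_id is not None else 0
    return AlignmentSet(
        sequences=seqs,
        ids=ids,
        e_values=[meta.get(i, (None, ""))[0] for i in ids],
        descriptions=[meta.get(i, (None, ""))[1] for i in ids],
        target_index=target_index,
    )


def conservation_for_chain(
    chain: ChainStructure,
    aln: AlignmentSet | None,
    kind: str,
    matrix_path: str | None = None,
) -> dict[ResidueId, float]:
    """Map admitted-alignment Valdar scores onto chain residues.

    The alignment's target sequence (gaps removed) must match the chain
    sequence.  A rejected or absent alignment yields NaN for every residue.
    """
    nan = {r.residue_id: float("nan") for r in chain.residues}
    if aln is None:
        return nan
    admitted = alignment_gatekeeper(aln, kind)
    if admitted is None:
        return nan
    scores = valdar01_scores(admitted.sequences, admitted.target_index, matrix_path)
    target = admitted.sequences[admitted.target_index]
    ungapped = [c for c in target if c not in _GAPS]
    if len(ungapped) != len(chain.residues):
        warnings.warn(
            f"alignment target length {len(ungapped)} != chain length "
            f"{len(chain.residues)}; conservation left missing"
        )
        return nan
    return {r.residue_id: s for r, s in zip(chain.residues, scores)}
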