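"""Sequence features: propensity arithmetic, hydropathy, conservation scoring."""

import math

import numpy as np
import pytest

from patchpred.patches import Patch
from patchpred.sequence_features import (
    AlignmentSet,
    PropensityTable,
    TrainingResidue,
    alignment_gatekeeper,
    build_propensity_table,
    patch_mean_feature,
    residue_hydrophobicity,
    residue_propensity,
    valdar01_scores,
)
from patchpred.tables import kyte_doolittle


class TestPropensityTable:
    def test_hand_counted_fractions(self):
        residues = [
            TrainingResidue("ALA", 60.0, "interface"),
            TrainingResidue("GLY", 40.0, "interface"),
            TrainingResidue("ALA", 30.0, "surface"),
            TrainingResidue("GLY", 70.0, "surface"),
        ]
        t = build_propensity_table(residues)
        assert t.f_intf["ALA"] == pytest.approx(0.6)
        assert t.f_intf["GLY"] == pytest.approx(0.4)
        assert t.f_surf["ALA"] == pytest.approx(0.3)
        assert t.mean_surface_asa["GLY"] == pytest.approx(70.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        types = ["ALA", "GLY", "SER", "LEU"]
        residues = [
            TrainingResidue(
                types[int(rng.integers(4))], float(rng.uniform(10, 100)),
                "interface" if rng.random() < 0.5 else "surface",
            )
            for _ in range(200)
        ]
        t = build_propensity_table(residues)
        assert sum(t.f_intf.values()) == pytest.approx(1.0)
        assert sum(t.f_surf.values()) == pytest.approx(1.0)

    def test_degenerate_set_rejected(self):
        with pytest.raises(ValueError):
            build_propensity_table([TrainingResidue("ALA", 10.0, "interface")])

    def test_tsv_round_trip(self):
        t = PropensityTable(
            {"ALA": 0.6, "GLY": 0.4}, {"ALA": 0.3, "GLY": 0.7},
            {"ALA": 55.0, "GLY": 40.0}, provenance="toy",
        )
        back = PropensityTable.from_tsv(t.to_tsv())
        assert back.f_intf == pytest.approx(t.f_intf)
        assert back.provenance == "toy"


class TestResiduePropensity:
    def test_direct_arithmetic(self):
        t = PropensityTable({"ALA": 0.6}, {"ALA": 0.3}, {"ALA": 50.0})
        # ln(0.6/0.3) * 50/50 = ln 2
        assert residue_propensity("ALA", 50.0, t) == pytest.approx(math.log(2.0))

    def test_equal_fractions_zero(self):
        t = PropensityTable({"ALA": 0.5}, {"ALA": 0.5}, {"ALA": 80.0})
        assert residue_propensity("ALA", 123.0, t) == 0.0

    def test_zero_asa_zero(self):
        t = PropensityTable({"ALA": 0.6}, {"ALA": 0.3}, {"ALA": 50.0})
        assert residue_propensity("ALA", 0.0, t) == 0.0

    def test_missing_surface_fraction(self):
        t = PropensityTable({"TRP": 0.6}, {}, {})
        assert math.isnan(residue_propensity("TRP", 50.0, t))

    def test_planted_type_sign(self):
        rng = np.random.default_rng(2)
        residues = []
        for _ in range(100):
            # TRP predominantly at the interface, LYS predominantly surface
            if rng.random() < 0.5:
                name = "TRP" if rng.random() < 0.9 else "LYS"
                cat = "interface"
            else:
                name = "LYS" if rng.random() < 0.9 else "TRP"
                cat = "surface"
            residues.append(TrainingResidue(name, float(rng.uniform(30, 120)), cat))
        t = build_propensity_table(residues)
        assert residue_propensity("TRP", 50.0, t) > 0
        assert residue_propensity("LYS", 50.0, t) < 0


class TestHydrophobicityAndMeans:
    def test_scale_values(self):
        assert residue_hydrophobicity("ILE") == 4.5
        assert residue_hydrophobicity("ARG") == -4.5
        assert len(kyte_doolittle()) == 20

    def test_patch_mean(self):
        patch = Patch(("A", 1, ""), "CA", [("A", 1, ""), ("A", 2, "")], 14.0)
        assert patch_mean_feature(patch, {("A", 1, ""): 1.0, ("A", 2, ""): 3.0}) == 2.0
        assert patch_mean_feature(patch, {("A", 1, ""): 5.0, ("A", 2, ""): float("nan")}) == 5.0
        assert math.isnan(patch_mean_feature(patch, {}))

    def test_patch_mean_within_bounds(self):
        rng = np.random.default_rng(3)
        ids = [("A", i, "") for i in range(8)]
        patch = Patch(("A", 0, ""), "CA", ids, 14.0)
        vals = {rid: float(v) for rid, v in zip(ids, rng.normal(0, 2, 8))}
        m = patch_mean_feature(patch, vals)
        assert min(vals.values()) <= m <= max(vals.values())


class TestValdar:
    def test_identical_sequences_score_one(self):
        scores = valdar01_scores(["ACDEF"] * 4)
        assert scores == pytest.approx([1.0] * 5)

    def test_fewer_than_two_sequences_missing(self):
        scores = valdar01_scores(["ACDEF"])
        assert len(scores) == 5 and all(math.isnan(s) for s in scores)

    def test_randomised_column_scores_lower(self):
        aligned = ["AAAAA", "AAAAA", "AAAAA", "AAAAA"]
        perturbed = ["AAAWA", "AAAKA", "AAADA", "AAAMA"]
        base = valdar01_scores(aligned)
        pert = valdar01_scores(perturbed)
        assert pert[3] < base[3]
        assert pert[0] == pytest.approx(1.0)

    def test_reordering_invariance(self):
        seqs = ["ACDEFG", "ACDKFG", "AWDEFG", "ACDEYG"]
        a = valdar01_scores(seqs, target_index=0)
        reordered = [seqs[0], seqs[3], seqs[1], seqs[2]]
        b = valdar01_scores(reordered, target_index=0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_target_gaps_skipped(self):
        scores = valdar01_scores(["AC-EF", "ACDEF", "ACDEF"], target_index=0)
        assert len(scores) == 4  # gap column dropped for the target

    def test_all_gap_column_scores_zero(self):
        scores = valdar01_scores(["A-C", "A-C", "AAC"], target_index=2)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] < 1.0  # two gap partners pull the column down


class TestGatekeeper:
    def _aln(self, n, evals=None, descs=None):
        return AlignmentSet(
            sequences=["ACDEF"] * n,
            ids=[f"s{i}" for i in range(n)],
            e_values=evals or [],
            descriptions=descs or [],
            target_index=0,
        )

    def test_fep_family_threshold(self):
        assert alignment_gatekeeper(self._aln(10), "fep") is not None
        assert alignment_gatekeeper(self._aln(9), "fep") is None

    def test_homologue_e_value_and_description_filters(self):
        n = 15
        evals = [None] + [0.001] * 10 + [0.5] * 4
        descs = [""] * 12 + ["putative protein", "", ""]
        out = alignment_gatekeeper(self._aln(n, evals, descs), "homologue")
        assert out is not None
        assert len(out.sequences) == 11  # target + 10 survivors

    def test_homologue_minimum_survivors(self):
        evals = [None] + [0.001] * 8 + [1.0] * 6
        out = alignment_gatekeeper(self._aln(15, evals), "homologue")
        assert out is None

    def test_homologue_top_200_cap(self):
        n = 251
        evals = [None] + [1e-6 * (i + 1) for i in range(n - 1)]
        out = alignment_gatekeeper(self._aln(n, evals), "homologue")
        assert len(out.sequences) == 201  # target + 200 best
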