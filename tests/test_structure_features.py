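"""Structural features: disulphides, H-bonds, secondary structure, planarity."""

import numpy as np
import pytest

from patchpred.patches import Patch
from patchpred.structure import read_structure
from patchpred.structure_features import (
    _amide_h,
    assign_secondary_structure,
    detect_disulphides,
    detect_hydrogen_bonds,
    patch_planarity,
    patch_ss_class,
    ss_class_indicators,
)
from patchpred.synthetic import make_helix, make_sheet, make_strand

from conftest import build_chain


def _cys_pair(distance):
    return build_chain([
        ("CYS", [("CA", "C", (0, 0, 0)), ("SG", "S", (0, 0, 1.8))]),
        ("CYS", [("CA", "C", (distance, 0, 0)), ("SG", "S", (distance, 0, 1.8 + 0))]),
    ])


class TestDisulphides:
    def test_threshold_strict(self):
        chain = _cys_pair(2.05)
        assert list(detect_disulphides(chain).values()) == [1, 1]
        chain = _cys_pair(2.25)
        assert list(detect_disulphides(chain).values()) == [0, 0]
        chain = _cys_pair(2.24)
        assert list(detect_disulphides(chain).values()) == [1, 1]

    def test_no_cysteine(self):
        chain = build_chain([("ALA", [("CA", "C", (0, 0, 0))])])
        assert list(detect_disulphides(chain).values()) == [0]


def _donor_chain_with_acceptor(ha_dist=None, angle_deg=150.0, da_dist=None,
                               ante_angle=120.0):
    """Two-residue chain: backbone N-H donor (res 2) and a carbonyl acceptor.

    When ``ha_dist`` is given the acceptor is placed at that distance from the
    rebuilt amide hydrogen, at ``angle_deg`` (D-H...A).  When ``da_dist`` is
    given a hydroxyl donor (no computable H) is used instead.
    """
    if da_dist is not None:
        # SER OG donor, fallback rule: angle at OG between CB and acceptor O
        theta = np.radians(ante_angle)
        acc = np.array([da_dist * np.cos(theta), da_dist * np.sin(theta), 0.0])
        return build_chain([
            ("SER", [("CA", "C", (0.5, -1.4, 0)), ("CB", "C", (1.45, 0, 0)),
                     ("OG", "O", (0, 0, 0))]),
            ("GLY", [("CA", "C", acc + np.array([2.0, 1.0, 0])),
                     ("C", "C", acc + np.array([1.3, 0, 0])),
                     ("O", "O", acc)]),
        ])
    chain = build_chain([
        ("GLY", [("CA", "C", (-2.0, 0.2, 0)),
                 ("C", "C", (-1.33, 0, 0)), ("O", "O", (-1.6, 1.2, 0))]),
        ("GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.0, 1.0, 0)),
                 ("C", "C", (2.4, 1.0, 0)), ("O", "O", (3.0, 2.0, 0))]),
    ])
    h = _amide_h(chain, 1)
    n = chain.residues[1].atom("N").position
    u = (h - n) / np.linalg.norm(h - n)  # N->H direction
    # acceptor in the xy-plane at the requested angle at H
    perp = np.cross(u, [0.0, 0.0, 1.0])
    theta = np.radians(180.0 - angle_deg)
    direction = np.cos(theta) * u + np.sin(theta) * perp
    acc = h + ha_dist * direction
    chain.residues.append(
        build_chain([
            ("GLY", [("CA", "C", acc + np.array([0, 0, 3.0])),
                     ("C", "C", acc + np.array([1.3, 0, 1.5])),
                     ("O", "O", acc)]),
        ], start=3).residues[0]
    )
    return chain


class TestHydrogenBonds:
    @pytest.mark.parametrize(
        "ha, angle, expected",
        [(2.4, 150.0, 1), (2.5, 90.0, 1), (2.51, 150.0, 0),
         (2.6, 150.0, 0), (2.4, 89.0, 0)],
    )
    def test_computable_hydrogen_rule(self, ha, angle, expected):
        chain = _donor_chain_with_acceptor(ha_dist=ha, angle_deg=angle)
        scores = detect_hydrogen_bonds(chain)
        assert scores[("A", 2, "")] == expected
        assert scores[("A", 3, "")] == expected

    @pytest.mark.parametrize(
        "da, ante, expected",
        [(3.3, 120.0, 1), (3.35, 120.0, 1), (3.36, 120.0, 0), (3.3, 89.0, 0)],
    )
    def test_fallback_rule_for_sidechain_donor(self, da, ante, expected):
        chain = _donor_chain_with_acceptor(da_dist=da, ante_angle=ante)
        scores = detect_hydrogen_bonds(chain)
        assert scores[("A", 1, "")] == expected


class TestSecondaryStructure:
    def test_ideal_helix_interior_H(self, tmp_path):
        p = tmp_path / "h.pdb"
        p.write_text(make_helix(15))
        (chain,) = read_structure(p)
        states = list(assign_secondary_structure(chain).values())
        assert states.count("H") >= 8
        assert all(s == "H" for s in states[3:-3])

    def test_antiparallel_sheet_interior_E(self, tmp_path):
        p = tmp_path / "s.pdb"
        p.write_text(make_sheet(8))
        (chain,) = read_structure(p)
        states = list(assign_secondary_structure(chain).values())
        assert states.count("E") >= 8

    def test_lone_extended_strand_is_coil(self, tmp_path):
        p = tmp_path / "e.pdb"
        p.write_text(make_strand(8))
        (chain,) = read_structure(p)
        assert set(assign_secondary_structure(chain).values()) == {"C"}


def _fake_patch_with_states(states):
    ids = [("A", i + 1, "") for i in range(len(states))]
    patch = Patch(ids[0], "CA", ids, 14.0)
    return patch, dict(zip(ids, states))


class TestPatchSsClass:
    @pytest.mark.parametrize(
        "states, expected",
        [
            (["H"] * 3 + ["C"] * 7, "H"),          # alpha 30, beta 0
            (["E"] * 3 + ["C"] * 7, "E"),          # alpha 0, beta 30
            (["H"] * 5 + ["E"] * 5 + ["C"] * 10, "EH"),  # both 25
            (["C"] * 10, "C"),
            (["H"] * 1 + ["E"] * 1 + ["C"] * 3, "C"),    # both exactly 20
            (["H"] * 2 + ["C"] * 8, "C"),          # alpha exactly 20
            (["E"] * 2 + ["C"] * 8, "C"),          # beta exactly 20
        ],
    )
    def test_boundaries(self, states, expected):
        patch, assignment = _fake_patch_with_states(states)
        assert patch_ss_class(patch, assignment) == expected

    def test_exhaustive_partition(self):
        # every composition maps to exactly one class, and the four indicator
        # columns are one-hot
        for n_h in range(0, 11):
            for n_e in range(0, 11 - n_h):
                states = ["H"] * n_h + ["E"] * n_e + ["C"] * (10 - n_h - n_e)
                patch, assignment = _fake_patch_with_states(states)
                cls = patch_ss_class(patch, assignment)
                assert cls in ("H", "E", "EH", "C")
                assert sum(ss_class_indicators(cls).values()) == 1


class TestPlanarity:
    def _patch_for(self, chain):
        ids = [r.residue_id for r in chain.residues]
        return Patch(ids[0], "CA", ids, 14.0)

    def test_coplanar_zero(self):
        chain = build_chain([
            ("GLY", [("CA", "C", (0, 0, 0)), ("X1", "C", (1, 0, 0))]),
            ("GLY", [("CA", "C", (0, 1, 0)), ("X1", "C", (2, 3, 0))]),
        ])
        assert patch_planarity(self._patch_for(chain), chain) == pytest.approx(0.0, abs=1e-9)

    def test_two_plane_fixture_rms_one(self):
        atoms1 = [("CA", "C", (x, y, 1.0)) for x in (0, 5) for y in (0, 5)]
        atoms2 = [("CA", "C", (x, y, -1.0)) for x in (0, 5) for y in (0, 5)]
        chain = build_chain([
            ("GLY", [(f"X{i}", "C", p) for i, (_, _, p) in enumerate(atoms1)]),
            ("GLY", [(f"X{i}", "C", p) for i, (_, _, p) in enumerate(atoms2)]),
        ])
        assert patch_planarity(self._patch_for(chain), chain) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 3, (12, 3))
        chain = build_chain([("GLY", [(f"X{i}", "C", p) for i, p in enumerate(pts)])])
        base = patch_planarity(self._patch_for(chain), chain)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        chain2 = build_chain([
            ("GLY", [(f"X{i}", "C", rot @ p + np.array([5, -3, 2])) for i, p in enumerate(pts)])
        ])
        assert patch_planarity(self._patch_for(chain2), chain2) == pytest.approx(base, abs=1e-9)

    def test_smallest_eigenvalue_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            pts = rng.normal(0, 2, (int(rng.integers(4, 30)), 3))
            chain = build_chain([("GLY", [(f"X{i}", "C", p) for i, p in enumerate(pts)])])
            got = patch_planarity(self._patch_for(chain), chain)
            centred = pts - pts.mean(axis=0)
            evals = np.linalg.eigvalsh(centred.T @ centred / len(pts))
            assert got == pytest.approx(np.sqrt(evals[0]), abs=1e-9)

    def test_collinear_degenerate(self):
        chain = build_chain([
            ("GLY", [("X0", "C", (0, 0, 0)), ("X1", "C", (1, 0, 0)),
                     ("X2", "C", (2, 0, 0))]),
        ])
        with pytest.warns(UserWarning):
            assert patch_planarity(self._patch_for(chain), chain) == 0.0
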