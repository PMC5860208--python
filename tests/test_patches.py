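"""Patch builder: geometry vectors, contact rule, growth to fixed point."""

import numpy as np
import pytest

from patchpred.config import RunConfig
from patchpred.patches import (
    GeometryVectors,
    chain_geometry_vectors,
    contact_adjacency,
    grow_patch,
    in_contact,
    make_patches,
    residue_geometry_vector,
    select_patch_centres,
    solvent_angle,
)
from patchpred.structure import annotate_accessibility

from conftest import build_chain, random_micro_chain


def naive_reference_patch(chain, centre_atom, radius, angle_thr=120.0, tol=0.2, k=10):
    """Unoptimised, loop-everything reimplementation of the growth procedure.

    Kept deliberately independent of the library internals: neighbour search,
    contacts and sweeps are all done by direct enumeration.
    """
    residues = chain.residues
    atoms = [a for r in residues for a in r.atoms]

    def geometry_vector(res):
        ca = res.c_alpha
        if ca is None:
            return None
        cands = []
        for idx, other in enumerate(residues):
            if other is res or other.c_alpha is None:
                continue
            cands.append((float(np.linalg.norm(other.c_alpha - ca)), idx))
        cands.sort()
        chosen = cands[:k]
        if not chosen:
            return np.zeros(3)
        centroid = np.zeros(3)
        for _, idx in chosen:
            centroid += residues[idx].c_alpha
        return centroid / len(chosen) - ca

    gv = {r.residue_id: geometry_vector(r) for r in residues}

    def angle_ok(r1, r2):
        v1, v2 = gv[r1], gv[r2]
        if v1 is None or v2 is None:
            return False
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            return True
        # solvent vectors are the negated geometry vectors; the angle between
        # them equals the angle between the geometry vectors
        cosang = float(np.dot(v1, v2) / (n1 * n2))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1))) < angle_thr

    cand_res = set()
    for r in residues:
        for a in r.atoms:
            if np.linalg.norm(a.position - centre_atom.position) <= radius:
                cand_res.add(r.residue_id)
                break
    C = [a for a in atoms if a.residue_id in cand_res and a is not centre_atom]
    P = [centre_atom]
    changed = True
    while changed:
        changed = False
        for a in list(C):
            hit = False
            for p in P:
                d = np.linalg.norm(a.position - p.position)
                if d < a.vdw_radius + p.vdw_radius + tol and angle_ok(
                    a.residue_id, p.residue_id
                ):
                    hit = True
                    break
            if hit:
                P.append(a)
                C.remove(a)
                changed = True
    return frozenset(a.residue_id for a in P)


class TestGeometryVectors:
    def test_single_neighbour_centroid(self):
        chain = build_chain([
            ("ALA", [("CA", "C", (0, 0, 0))]),
            ("ALA", [("CA", "C", (2, 0, 0))]),
        ])
        gv = residue_geometry_vector(chain.residues[0], chain)
        assert np.allclose(gv.geometry_vector, [2, 0, 0])
        assert np.allclose(gv.solvent_vector, [-2, 0, 0])

    def test_symmetric_neighbours_zero_vector(self):
        chain = build_chain([
            ("ALA", [("CA", "C", (0, 0, 0))]),
            ("ALA", [("CA", "C", (1, 0, 0))]),
            ("ALA", [("CA", "C", (-1, 0, 0))]),
            ("ALA", [("CA", "C", (0, 1, 0))]),
            ("ALA", [("CA", "C", (0, -1, 0))]),
        ])
        gv = residue_geometry_vector(chain.residues[0], chain)
        assert np.allclose(gv.geometry_vector, 0.0, atol=1e-12)

    def test_neighbour_set_matches_brute_force(self):
        rng = np.random.default_rng(42)
        chain = build_chain(
            [("ALA", [("CA", "C", rng.normal(0, 5, 3))]) for _ in range(12)]
        )
        for res in chain.residues:
            gv = residue_geometry_vector(res, chain, k=10)
            ca = res.c_alpha
            dists = sorted(
                (np.linalg.norm(r.c_alpha - ca), i)
                for i, r in enumerate(chain.residues)
                if r is not res
            )
            centroid = np.mean([chain.residues[i].c_alpha for _, i in dists[:10]], axis=0)
            assert np.allclose(gv.geometry_vector, centroid - ca)


class TestSolventAngle:
    @pytest.mark.parametrize(
        "v1, v2, expected",
        [((1, 0, 0), (1, 0, 0), 0.0), ((1, 0, 0), (-1, 0, 0), 180.0),
         ((1, 0, 0), (0, 1, 0), 90.0)],
    )
    def test_reference_angles(self, v1, v2, expected):
        a = GeometryVectors(("A", 1, ""), np.array(v1, dtype=float))
        b = GeometryVectors(("A", 2, ""), np.array(v2, dtype=float))
        assert solvent_angle(a, b) == pytest.approx(expected)
        assert solvent_angle(b, a) == pytest.approx(expected)

    def test_zero_vector_passes_as_zero(self):
        a = GeometryVectors(("A", 1, ""), np.zeros(3))
        b = GeometryVectors(("A", 2, ""), np.array([1.0, 0, 0]))
        assert solvent_angle(a, b) == 0.0


class TestContact:
    def test_contact_threshold_strict(self):
        mk = lambda x: build_chain([("ALA", [("CA", "C", (x, 0, 0))])]).atoms[0]
        a, b = mk(0.0), mk(3.5)
        a.vdw_radius = b.vdw_radius = 1.7
        assert in_contact(a, b)  # 3.5 < 3.6
        b.position = np.array([3.6, 0.0, 0.0])
        assert not in_contact(a, b)  # boundary is exclusive
        b.position = np.zeros(3)
        assert in_contact(a, b)


class TestGrowPatch:
    def test_single_residue_chain(self):
        chain = build_chain([("ALA", [("CA", "C", (0, 0, 0))])])
        p = grow_patch(chain, chain.atoms[0], 10.0)
        assert p.member_residue_ids == [("A", 1, "")]

    def test_fixed_point(self):
        rng = np.random.default_rng(3)
        chain = random_micro_chain(rng)
        p1 = grow_patch(chain, chain.atoms[0], 9.0)
        p2 = grow_patch(chain, chain.atoms[0], 9.0)
        assert p1.member_residue_ids == p2.member_residue_ids

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            chain = random_micro_chain(rng)
            centre = chain.atoms[int(rng.integers(len(chain.atoms)))]
            small = set(grow_patch(chain, centre, 9.0).member_residue_ids)
            large = set(grow_patch(chain, centre, 14.0).member_residue_ids)
            assert small <= large

    def test_connectivity_to_centre(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            chain = random_micro_chain(rng)
            centre = chain.atoms[int(rng.integers(len(chain.atoms)))]
            patch = grow_patch(chain, centre, 9.0)
            members = set(patch.member_residue_ids)
            adj = contact_adjacency(chain.atoms)
            atoms = chain.atoms
            # BFS over atom contacts restricted to member residues
            start = [i for i, a in enumerate(atoms) if a is centre]
            seen = set(start)
            stack = list(start)
            while stack:
                i = stack.pop()
                for j in adj[i]:
                    if j not in seen and atoms[j].residue_id in members:
                        seen.add(j)
                        stack.append(j)
            reachable = {atoms[i].residue_id for i in seen}
            assert members <= reachable

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(99)
        for _ in range(15):
            chain = random_micro_chain(rng)
            centre = chain.atoms[int(rng.integers(len(chain.atoms)))]
            got = frozenset(grow_patch(chain, centre, 8.0).member_residue_ids)
            want = naive_reference_patch(chain, centre, 8.0)
            assert got == want

    def test_centre_not_in_chain_rejected(self):
        chain = build_chain([("ALA", [("CA", "C", (0, 0, 0))])])
        other = build_chain([("ALA", [("CA", "C", (5, 0, 0))])])
        with pytest.raises(ValueError):
            grow_patch(chain, other.atoms[0], 10.0)


class TestCentresAndPatches:
    def test_centre_selection_rules(self, two_slab_annotated):
        _, chains = two_slab_annotated
        chain = chains[0]
        centres = select_patch_centres(chain)
        ids = {rid for rid, _ in centres}
        for r in chain.residues:
            if r.rasa_isolated is not None and r.rasa_isolated > 25.0:
                assert r.residue_id in ids
                # centre atom is the residue's max-ASA atom
                name = dict(centres)[r.residue_id]
                best = max(r.atoms, key=lambda a: a.asa_isolated)
                assert name == best.atom_name
            else:
                assert r.residue_id not in ids

    def test_boundary_rasa_not_centre(self):
        chain = build_chain([("ALA", [("CA", "C", (0, 0, 0))])])
        res = chain.residues[0]
        res.rasa_isolated = 25.0
        res.atoms[0].asa_isolated = 10.0
        assert select_patch_centres(chain) == []
        res.rasa_isolated = 25.0001
        assert select_patch_centres(chain) == [(("A", 1, ""), "CA")]

    def test_every_patch_contains_its_centre(self, two_slab_annotated):
        _, chains = two_slab_annotated
        patches = make_patches(chains[0])
        assert patches  # surface grid has centres
        for p in patches:
            assert p.centre_residue_id in p.member_residue_ids
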