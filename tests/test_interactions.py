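"""Hydrogen-bond geometry, PAE-gated contacts, catalog comparison."""

import numpy as np
import pytest

from conftest import make_frame
from orthostruct.io_formats import Atom, PaeMatrix, Residue, StructureModel
from orthostruct.interactions import (
    BASE_ANGLE, BASE_DISTANCE, compare_catalogs, detect_hbonds,
    donor_acceptor_table, interface_contacts,
)


def brute_force_hbonds(models, dist_tol, angle_tol, min_separation):
    """Independent O(N²) scan over every donor×acceptor combination."""
    found = set()
    max_d = BASE_DISTANCE + dist_tol
    min_a = BASE_ANGLE - angle_tol
    for ci, ma in enumerate(models):
        for ri, res in enumerate(ma.residues):
            donors, _ = donor_acceptor_table(res.name)
            for datom, dante in donors:
                d_at, a_at = res.atom(datom), res.atom(dante)
                if d_at is None or a_at is None:
                    continue
                for cj, mb in enumerate(models):
                    for rj, res2 in enumerate(mb.residues):
                        if ci == cj and ri == rj:
                            continue
                        if ci == cj and abs(res.number - res2.number) <= min_separation:
                            continue
                        _, accs = donor_acceptor_table(res2.name)
                        for aatom, _ in accs:
                            acc = res2.atom(aatom)
                            if acc is None:
                                continue
                            dxyz = np.array(d_at.xyz)
                            axyz = np.array(acc.xyz)
                            dist = np.linalg.norm(dxyz - axyz)
                            if dist > max_d or dist <= 0:
                                continue
                            v1 = np.array(a_at.xyz) - dxyz
                            v2 = axyz - dxyz
                            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                            if ang < min_a:
                                continue
                            found.add((ci, ri, datom, cj, rj, aatom))
    return found


def bond_keys(bonds, models):
    chain_idx = {m.chain_id: i for i, m in enumerate(models)}
    return {
        (chain_idx[b.donor_chain], b.donor_residue, b.donor_atom,
         chain_idx[b.acceptor_chain], b.acceptor_residue, b.acceptor_atom)
        for b in bonds
    }


def gly(number, n, ca, c, o):
    return Residue("GLY", number, (
        Atom("N", "N", tuple(n)), Atom("CA", "C", tuple(ca)),
        Atom("C", "C", tuple(c)), Atom("O", "O", tuple(o)),
    ), 90.0)


def far(offset):
    return np.array([offset, 50.0, 50.0])


class TestDetectHbonds:
    def test_ca_only_residues_give_nothing(self):
        res = [Residue("GLY", i + 1, (Atom("CA", "C", (i * 10.0, 0, 0)),), 90.0)
               for i in range(2)]
        assert detect_hbonds(StructureModel("A", tuple(res))) == []

    @pytest.mark.parametrize("extra,expect", [(0.3, 1), (0.5, 0)])
    def test_distance_criterion_boundary(self, extra, expect):
        # donor N of residue 10 aimed straight at acceptor O of residue 1
        d = BASE_DISTANCE + extra
        chain = StructureModel("A", (
            gly(1, far(0), far(1), np.array([d + 1.5, 0, 0]), np.array([d, 0, 0])),
            gly(10, np.array([0.0, 0, 0]), np.array([-1.5, 0, 0]),
                far(2), far(3)),
        ))
        bonds = [b for b in detect_hbonds(chain)
                 if b.donor_atom == "N" and b.acceptor_atom == "O"]
        assert len(bonds) == expect

    def test_angle_criterion(self):
        # acceptor placed at 60° off the donor-antecedent axis: below the
        # relaxed 70° minimum, no bond; at 90° the bond is called
        for ang, expect in ((60.0, 0), (90.0, 1)):
            rad = np.radians(ang)
            o_pos = 3.0 * np.array([np.cos(np.pi - rad), np.sin(np.pi - rad), 0])
            chain = StructureModel("A", (
                gly(1, far(0), far(1), o_pos + np.array([0, 1.5, 0]), o_pos),
                gly(10, np.array([0.0, 0, 0]), np.array([-1.5, 0, 0]),
                    far(2), far(3)),
            ))
            bonds = [b for b in detect_hbonds(chain)
                     if b.donor_atom == "N" and b.acceptor_atom == "O"]
            assert len(bonds) == expect, f"angle {ang}"

    @pytest.mark.parametrize("sep,expect", [(4, 0), (5, 0), (6, 1)])
    def test_sequence_separation_rule(self, sep, expect):
        chain = StructureModel("A", (
            gly(1, far(0), far(1), np.array([4.5, 0, 0]), np.array([3.0, 0, 0])),
            gly(1 + sep, np.array([0.0, 0, 0]), np.array([-1.5, 0, 0]),
                far(2), far(3)),
        ))
        bonds = [b for b in detect_hbonds(chain)
                 if b.donor_atom == "N" and b.acceptor_atom == "O"]
        assert len(bonds) == expect

    def test_inter_chain_bonds_keep_close_residues(self):
        a = StructureModel("A", (
            gly(1, far(0), far(1), np.array([4.5, 0, 0]), np.array([3.0, 0, 0])),
        ))
        b = StructureModel("B", (
            gly(1, np.array([0.0, 0, 0]), np.array([-1.5, 0, 0]), far(2), far(3)),
        ))
        bonds = detect_hbonds([a, b])
        assert any(x.scope == "inter" for x in bonds)

    def test_matches_brute_force_on_synthetic_complex(self, small_bundle):
        from orthostruct.io_formats import read_structure
        path, _, _ = small_bundle
        models = read_structure(path / "sp1_complex.pdb")
        bonds = detect_hbonds(models)
        assert bond_keys(bonds, models) == brute_force_hbonds(models, 0.4, 20.0, 5)
        assert len(bonds) > 0

    def test_tolerance_monotonicity_grid(self, small_bundle):
        from orthostruct.io_formats import read_structure
        path, _, _ = small_bundle
        models = read_structure(path / "sp1_complex.pdb")
        grid = [0.0, 0.2, 0.4, 0.6, 0.8]
        sets = {
            (dt, at): bond_keys(detect_hbonds(models, dt, at * 25, 5), models)
            for dt in grid for at in range(5)
        }
        for dt1, at1 in sets:
            for dt2, at2 in sets:
                if dt1 <= dt2 and at1 <= at2:
                    assert sets[(dt1, at1)] <= sets[(dt2, at2)]


def two_chains_apart(gap):
    a = StructureModel("A", (
        Residue("GLY", 1, (Atom("CA", "C", (0.0, 0, 0)),), 90.0),
    ))
    b = StructureModel("B", (
        Residue("GLY", 1, (Atom("CA", "C", (gap, 0, 0)),), 90.0),
    ))
    return a, b


class TestInterfaceContacts:
    def test_distant_chains_empty(self):
        a, b = two_chains_apart(100.0)
        assert interface_contacts(a, b, PaeMatrix(np.zeros((2, 2)))) == []

    @pytest.mark.parametrize("pae,expect", [(6.0, 0), (5.0, 0), (4.0, 1)])
    def test_pae_cutoff_strictly_below(self, pae, expect):
        a, b = two_chains_apart(3.0)
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = pae
        contacts = interface_contacts(a, b, PaeMatrix(m))
        assert len(contacts) == expect

    def test_dimension_mismatch(self):
        a, b = two_chains_apart(3.0)
        with pytest.raises(ValueError, match="PAE"):
            interface_contacts(a, b, PaeMatrix(np.zeros((5, 5))))

    def test_asymmetric_pae_uses_conservative_max(self):
        a, b = two_chains_apart(3.0)
        m = np.zeros((2, 2))
        m[0, 1], m[1, 0] = 2.0, 7.0
        assert interface_contacts(a, b, PaeMatrix(m)) == []

    def test_symmetric_under_chain_swap(self, small_bundle):
        from orthostruct.io_formats import read_pae, read_structure
        path, _, _ = small_bundle
        ma, mb = read_structure(path / "sp1_complex.pdb")
        pae = read_pae(path / "sp1_pae.json")
        na, nb = len(ma), len(mb)
        perm = np.concatenate([np.arange(na, na + nb), np.arange(na)])
        swapped = PaeMatrix(pae.values[np.ix_(perm, perm)])
        fwd = {(c.residue_a, c.residue_b) for c in
               interface_contacts(ma, mb, pae)}
        rev = {(c.residue_b, c.residue_a) for c in
               interface_contacts(mb, ma, swapped)}
        assert fwd == rev and fwd

    def test_matches_brute_force_distance_scan(self, small_bundle):
        from orthostruct.io_formats import read_pae, read_structure
        path, _, _ = small_bundle
        ma, mb = read_structure(path / "sp1_complex.pdb")
        pae = read_pae(path / "sp1_pae.json")
        na = len(ma)
        expect = set()
        for i, ra in enumerate(ma.residues):
            for j, rb in enumerate(mb.residues):
                dmin = min(
                    np.linalg.norm(np.array(x.xyz) - np.array(y.xyz))
                    for x in ra.atoms for y in rb.atoms
                )
                if dmin <= 4.0 and max(pae[i, na + j], pae[na + j, i]) < 5.0:
                    expect.add((i, j))
        got = {(c.residue_a, c.residue_b)
               for c in interface_contacts(ma, mb, pae)}
        assert got == expect


class TestCompareCatalogs:
    def test_identical_catalogs_p_one(self, small_bundle):
        from orthostruct.io_formats import read_structure
        path, _, _ = small_bundle
        models = read_structure(path / "sp1_complex.pdb")
        bonds = detect_hbonds(models)
        frame = make_frame(("sp1", "M" * len(models[0])),
                           ("sp2", "M" * len(models[0])))
        comps, counts = compare_catalogs({"sp1": bonds, "sp2": bonds}, frame)
        tested = [c for c in comps if c.p_raw == c.p_raw]
        assert tested and all(c.p_raw == pytest.approx(1.0) for c in tested)

    def test_empty_catalogs_skipped_with_reason(self):
        frame = make_frame(("sp1", "MKV"), ("sp2", "MKV"))
        comps, counts = compare_catalogs({"sp1": [], "sp2": []}, frame)
        assert counts["total"] == {"sp1": 0, "sp2": 0}
        in_category = [c for c in comps if c.category != "total"]
        assert all(c.p_raw != c.p_raw and "skipped" in c.note
                   for c in in_category)

    def test_regional_imbalance_significant_before_correction(self):
        """10 vs 0 bonds in one region at equal totals: the raw Fisher p
        (checked against exhaustive enumeration) is significant."""
        from math import comb

        from orthostruct.interactions import HBond
        from orthostruct.io_formats import RegionSet

        def bond(i, j):
            return HBond("A", i, "N", "A", j, "O", 3.0, 150.0, "intra")

        frame = make_frame(("sp1", "M" * 40), ("sp2", "M" * 40))
        regions = RegionSet("sp1", (("head", 1, 10),))
        in_region = [bond(i, i + 20) for i in range(10)]
        out_region = [bond(20 + i, 30 + i) for i in range(10)]
        comps, counts = compare_catalogs(
            {"sp1": in_region, "sp2": out_region}, frame, regions)
        assert counts["head"] == {"sp1": 10, "sp2": 0}
        (head,) = [c for c in comps if c.category == "head"]
        # enumeration oracle for [[10, 0], [0, 10]]
        denom = comb(20, 10)
        probs = [comb(10, x) * comb(10, 10 - x) / denom for x in range(11)]
        expect = sum(p for p in probs if p <= probs[10] * (1 + 1e-7))
        assert head.p_raw == pytest.approx(expect, rel=1e-7)
        assert head.p_raw < 0.05
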