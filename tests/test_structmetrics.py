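"""Superposition, RMSD normalization, SASA/volume, burial, contacts, SSE."""

import math

import numpy as np
import pytest

from foldflex import structmetrics as sm
from foldflex import synthdata as sd
from foldflex.structio import (
    AtomRecord,
    DomainDefinition,
    DomainInstance,
    HetGroup,
    ResidueRecord,
)

from conftest import make_chain_instance


def _rotmat(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    th = np.deg2rad(deg)
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * (kx @ kx)


def grid_search_rmsd(a, b, final_step=0.05):
    """Independent best-fit RMSD by coarse-to-fine Euler-angle grid search."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_for(angles):
        rx = _rotmat([1, 0, 0], angles[0])
        ry = _rotmat([0, 1, 0], angles[1])
        rz = _rotmat([0, 0, 1], angles[2])
        d = a @ (rz @ ry @ rx).T - b
        return math.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = (0.0, 0.0, 0.0)
    step = 30.0
    span = 180.0
    while step >= final_step:
        grids = [np.arange(c - span, c + span + step / 2, step) for c in best]
        vals = [
            (rmsd_for((x, y, z)), (x, y, z))
            for x in grids[0]
            for y in grids[1]
            for z in grids[2]
        ]
        _, best = min(vals)
        span = 2 * step
        step /= 4.0
    return rmsd_for(best)


class TestKabsch:
    def test_identical_sets_zero(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        assert sm.kabsch_superpose(a, a).rmsd < 1e-10

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        rot = _rotmat(rng.normal(size=3), 73.0)
        b = a @ rot.T + np.array([1.0, -2.0, 3.0])
        s = sm.kabsch_superpose(a, b)
        assert s.rmsd < 1e-8
        assert np.linalg.det(s.rotation) == pytest.approx(1.0)

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 3)) * 3
        b = a @ _rotmat([1, 2, 3], 40).T + rng.normal(scale=0.3, size=(6, 3))
        assert sm.kabsch_superpose(a, b).rmsd == pytest.approx(
            grid_search_rmsd(a, b), abs=1e-3
        )

    def test_symmetric_and_jointly_rigid_invariant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.5, size=(8, 3))
        r1 = sm.kabsch_superpose(a, b).rmsd
        r2 = sm.kabsch_superpose(b, a).rmsd
        rot = _rotmat([0, 1, 1], 25)
        r3 = sm.kabsch_superpose(a @ rot.T + 5, b @ rot.T + 5).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert r1 == pytest.approx(r3, abs=1e-9)

    def test_errors(self):
        a = np.zeros((2, 3))
        with pytest.raises(ValueError):
            sm.kabsch_superpose(a, a)
        with pytest.raises(ValueError):
            sm.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            sm.kabsch_superpose(line, line)


class TestRmsd100:
    def test_n_100_is_identity(self):
        for r in (0.0, 0.7, 2.0, 9.3):
            assert sm.rmsd100(r, 100) == pytest.approx(r)

    def test_n_400_hand_value(self):
        assert sm.rmsd100(2.0, 400) == pytest.approx(2.0 / (1 + math.log(2)), abs=1e-4)
        assert sm.rmsd100(2.0, 400) == pytest.approx(1.1813, abs=1e-3)

    def test_short_domain_flagged_absent(self):
        assert sm.rmsd100(1.0, 13) is None
        assert sm.rmsd100(1.0, 14) is not None


class TestRegionRmsd:
    def test_whole_region_equals_global(self):
        t = sd.build_template("mixed", 40, seed=0)
        conf = sd.rotate_segment(t, 21, 30, 25.0)
        sup, used = sm.superpose_instances(conf, t)
        r = sm.region_rmsd(sup, conf, t, used, (1, 40))
        assert r == pytest.approx(sup.rmsd, abs=1e-9)

    def test_identical_structures_zero(self):
        t = sd.build_template("mixed", 40, seed=0)
        sup, used = sm.superpose_instances(sd.clone_instance(t), t)
        assert sm.region_rmsd(sup, t, t, used, (5, 15)) == pytest.approx(0, abs=1e-9)

    def test_hinge_rotation_matches_analytic_displacement(self):
        # fix the superposition on the untouched core, rotate a region, and
        # compare with the closed-form rotated-point displacement
        t = sd.build_template("mixed", 40, seed=1)
        region = (26, 35)
        conf = sd.rotate_segment(t, region[0], region[1], 30.0)
        core = [(i, i) for i in range(20)]
        sup, _ = sm.superpose_instances(conf, t, core)
        got = sm.region_rmsd(sup, conf, t, [(i, i) for i in range(40)], region)
        axis = t.residues[25].ca.coords - t.residues[24].ca.coords
        rot = _rotmat(axis, 30.0)
        pivot = t.residues[25].ca.coords
        disp = [
            np.linalg.norm(rot @ (t.residues[i].ca.coords - pivot) + pivot
                           - t.residues[i].ca.coords) ** 2
            for i in range(region[0] - 1, region[1])
        ]
        assert got == pytest.approx(math.sqrt(np.mean(disp)), abs=1e-6)

    def test_partition_combines_to_global_quadratic_mean(self):
        t = sd.build_template("mixed", 30, seed=2)
        conf = sd.rotate_segment(t, 16, 24, 18.0)
        sup, used = sm.superpose_instances(conf, t)
        parts = [(1, 10), (11, 20), (21, 30)]
        total = 0.0
        for lo, hi in parts:
            r = sm.region_rmsd(sup, conf, t, used, (lo, hi))
            n = hi - lo + 1
            total += n * r * r
        assert math.sqrt(total / 30) == pytest.approx(sup.rmsd, abs=1e-9)

    def test_empty_region_absent(self):
        t = sd.build_template("mixed", 30, seed=2)
        sup, used = sm.superpose_instances(t, t)
        with pytest.warns(UserWarning):
            assert sm.region_rmsd(sup, t, t, used, (100, 120)) is None


def _lone_atom(element="SE"):
    d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "1")], "P1")
    return DomainInstance(
        d, "s", [ResidueRecord("A", "1", "A", [AtomRecord(element, element, [0, 0, 0])])]
    )


class TestSasa:
    def test_lone_atom_closed_form(self):
        _, _, total = sm.shrake_rupley_sasa(_lone_atom())
        assert total == pytest.approx(4 * math.pi * (1.9 + 1.4) ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "2")], "P1")
        inst = DomainInstance(d, "s", [
            ResidueRecord("A", "1", "A", [AtomRecord("SE", "SE", [0, 0, 0])]),
            ResidueRecord("A", "2", "A", [AtomRecord("SE", "SE", [100, 0, 0])]),
        ])
        _, _, total = sm.shrake_rupley_sasa(inst)
        assert total == pytest.approx(2 * 4 * math.pi * 3.3**2, rel=0.01)

    def test_coincident_atoms_equal_one(self):
        d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "2")], "P1")
        inst = DomainInstance(d, "s", [
            ResidueRecord("A", "1", "A", [AtomRecord("SE", "SE", [0, 0, 0])]),
            ResidueRecord("A", "2", "A", [AtomRecord("SE", "SE", [0, 0, 0])]),
        ])
        _, _, total = sm.shrake_rupley_sasa(inst)
        assert total == pytest.approx(4 * math.pi * 3.3**2, rel=0.01)

    def test_occlusion_monotone_on_approach(self):
        d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "2")], "P1")
        totals = []
        for dist in (8.0, 6.0, 4.0, 3.0, 2.0):
            inst = DomainInstance(d, "s", [
                ResidueRecord("A", "1", "A", [AtomRecord("C", "C", [0, 0, 0])]),
                ResidueRecord("A", "2", "A", [AtomRecord("C", "C", [dist, 0, 0])]),
            ])
            totals.append(sm.shrake_rupley_sasa(inst)[2])
        assert all(x >= y - 1e-9 for x, y in zip(totals, totals[1:]))

    def test_unknown_element_warns(self):
        inst = _lone_atom("XX")
        with pytest.warns(UserWarning):
            sm.shrake_rupley_sasa(inst)


class TestVolume:
    def test_lone_atom_closed_form(self):
        v = sm.estimate_volume(_lone_atom())
        assert v == pytest.approx(4 / 3 * math.pi * 1.9**3, rel=0.02)

    def test_disjoint_atoms_additive(self):
        d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "2")], "P1")
        inst = DomainInstance(d, "s", [
            ResidueRecord("A", "1", "A", [AtomRecord("SE", "SE", [0, 0, 0])]),
            ResidueRecord("A", "2", "A", [AtomRecord("SE", "SE", [20, 0, 0])]),
        ])
        assert sm.estimate_volume(inst) == pytest.approx(
            2 * 4 / 3 * math.pi * 1.9**3, rel=0.02
        )

    def test_grid_convergence(self):
        t = sd.build_template("helix-bundle", 30, seed=0)
        v1 = sm.estimate_volume(t, grid=0.5)
        v2 = sm.estimate_volume(t, grid=0.25)
        assert abs(v1 - v2) / v2 < 0.02


class TestBuriedExposed:
    def test_extended_peptide_nothing_buried(self):
        t = sd.build_template("extended", 25, seed=0)
        _, per_res, _ = sm.shrake_rupley_sasa(t)
        n_b, n_e, _ = sm.classify_buried_exposed(per_res, t.seq)
        assert n_b == 0 and n_e == 25

    def test_single_residue_exposed(self):
        t = sd.build_template("extended", 25, seed=0)
        _, per_res, _ = sm.shrake_rupley_sasa(t)
        n_b, n_e, be = sm.classify_buried_exposed(per_res[:1], t.seq[:1])
        assert (n_b, n_e) == (0, 1) and be == 0.0

    def test_globule_more_buried_than_extended(self):
        glob = sd.build_template("helix-bundle", 60, seed=4)
        ext = sd.build_template("extended", 60, seed=4)
        g = sm.geometry_metrics(glob)
        e = sm.geometry_metrics(ext)
        assert g.be_ratio > e.be_ratio
        assert e.av_ratio > g.av_ratio  # compactness trend

    def test_all_buried_absent_ratio(self):
        n_b, n_e, be = sm.classify_buried_exposed(np.zeros(3), "AAA")
        assert n_e == 0 and be is None


class TestContacts:
    def _het(self, name, element, pos):
        return HetGroup(name, "A", "101", [AtomRecord(element, element, pos)])

    def test_no_het_groups(self):
        inst = make_chain_instance(5)
        assert sm.contact_counts(inst, []) == (0, 0)

    def test_metal_contact(self):
        inst = make_chain_instance(5)
        mg = self._het("MG", "MG", inst.residues[2].ca.coords + [0, 2.1, 0])
        assert sm.contact_counts(inst, [mg]) == (1, 0)

    def test_distant_ligand_no_contact(self):
        inst = make_chain_instance(5)
        lig = self._het("LIG", "C", inst.residues[0].ca.coords + [0, 6.0, 0])
        assert sm.contact_counts(inst, [lig]) == (0, 0)

    def test_water_excluded(self):
        inst = make_chain_instance(5)
        w = self._het("HOH", "O", inst.residues[0].ca.coords + [0, 2.0, 0])
        assert sm.contact_counts(inst, [w]) == (0, 0)


def _dssp_energy(n_i, h_i, c_j, o_j):
    """Independent electrostatic hydrogen-bond energy (kcal/mol)."""
    f = 0.084 * 332
    return f * (
        1 / np.linalg.norm(o_j - n_i)
        + 1 / np.linalg.norm(c_j - h_i)
        - 1 / np.linalg.norm(o_j - h_i)
        - 1 / np.linalg.norm(c_j - n_i)
    )


class TestSse:
    def test_ideal_helix_mostly_h(self):
        res = sd.build_backbone([sd.HELIX_PHI_PSI] * 12, "A" * 12)
        d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "12")], "P1")
        inst = DomainInstance(d, "s", res)
        prof = sm.assign_sse(inst)
        assert prof.per_residue.count("H") >= 8
        # oracle: i -> i+4 hydrogen bonds on the generated coordinates
        for i in range(4, 10):
            prev_c = res[i - 1].atom("C").coords
            prev_o = res[i - 1].atom("O").coords
            co = (prev_c - prev_o) / np.linalg.norm(prev_c - prev_o)
            h = res[i].atom("N").coords + 1.01 * co
            e = _dssp_energy(res[i].atom("N").coords, h,
                             res[i - 4].atom("C").coords, res[i - 4].atom("O").coords)
            assert e < -0.5

    def test_antiparallel_sheet_central_e(self):
        sheet = sd.build_antiparallel_sheet(8)
        prof = sm.assign_sse(sheet)
        per = prof.per_residue
        assert set(per[2:6]) == {"E"} and set(per[10:14]) == {"E"}
        assert prof.frac_sheet > 0.5

    def test_extended_isolated_chain_all_coil(self):
        t = sd.build_template("extended", 20, seed=0)
        assert set(sm.assign_sse(t).per_residue) == {"C"}

    def test_missing_backbone_assigned_coil(self):
        res = sd.build_backbone([sd.HELIX_PHI_PSI] * 12, "A" * 12)
        res[5].atoms = [a for a in res[5].atoms if a.name != "O"]
        d = DomainDefinition("d1", "1.10.8.10", [("A", "1", "12")], "P1")
        with pytest.warns(UserWarning):
            prof = sm.assign_sse(DomainInstance(d, "s", res))
        assert prof.per_residue[5] == "C"

    @pytest.mark.parametrize(
        "pred, expt, expected",
        [
            ("HHHHCC", "HHHHCC", 0),
            ("HHHHHC", "CCCCCC", 5),
            ("CCCC", "EECC", -2),
        ],
    )
    def test_sse_count_difference(self, pred, expt, expected):
        mk = lambda s: sm.SSEProfile(s, s.count("H") / len(s), s.count("E") / len(s))
        assert sm.sse_count_difference(mk(pred), mk(expt)) == expected
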