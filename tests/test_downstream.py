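"""Two-region conformational clustering and annotation enrichment."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from foldflex import downstream as dn
from foldflex import synthdata as sd
from foldflex.census import GroupCensusRow


def _region_specs():
    return (dn.RegionSpec("r1", 26, 46), dn.RegionSpec("r2", 51, 78))


class TestTwoRegionRmsd:
    def test_reference_against_itself_zero(self):
        t = sd.build_template("mixed", 90, seed=0)
        ref = sd.clone_instance(t)
        ref.is_predicted = True
        tab = dn.two_region_rmsd([t], ref, _region_specs())
        assert tab.iloc[0]["rmsd_r1"] == pytest.approx(0.0, abs=1e-9)
        assert tab.iloc[0]["rmsd_r2"] == pytest.approx(0.0, abs=1e-9)

    def test_open_region_dominates_and_matches_rotation_oracle(self):
        t = sd.build_template("mixed", 90, seed=0)
        conf = sd.rotate_segment(t, 26, 46, 40.0)
        ref = sd.clone_instance(t)
        ref.is_predicted = True
        tab = dn.two_region_rmsd([conf], ref, _region_specs())
        r1, r2 = tab.iloc[0]["rmsd_r1"], tab.iloc[0]["rmsd_r2"]
        # the rotated region dominates; the untouched region picks up only
        # the compromise of the global superposition
        assert r1 > 2.5 * r2
        # closed-form check under a core-fixed superposition
        from foldflex.structmetrics import region_rmsd, superpose_instances

        core = [(i, i) for i in range(90) if not (25 <= i <= 45)]
        sup, _ = superpose_instances(conf, ref, core)
        axis = t.residues[25].ca.coords - t.residues[24].ca.coords
        axis /= np.linalg.norm(axis)
        th = np.deg2rad(40.0)
        kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                       [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * (kx @ kx)
        pivot = t.residues[25].ca.coords
        disp = [
            np.linalg.norm(rot @ (t.residues[i].ca.coords - pivot) + pivot
                           - t.residues[i].ca.coords) ** 2
            for i in range(25, 46)
        ]
        expected = math.sqrt(np.mean(disp))
        got = region_rmsd(sup, conf, ref, [(i, i) for i in range(90)], (26, 46))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_unresolved_region_excluded(self):
        t = sd.build_template("mixed", 90, seed=0)
        ref = sd.clone_instance(t)
        ref.is_predicted = True
        trunc = sd.clone_instance(t)
        trunc.residues = trunc.residues[50:]  # region 1 (26-46) missing
        pair_maps = {trunc.instance_id: [(i, i + 50) for i in range(40)]}
        with pytest.warns(UserWarning):
            tab = dn.two_region_rmsd([trunc], ref, _region_specs(), pair_maps)
        assert bool(tab.iloc[0]["excluded"]) is True


class TestClusterConformations:
    def _table(self, pts, ids=None):
        ids = ids or [f"i{k}" for k in range(len(pts))]
        return pd.DataFrame(
            {"instance_id": ids,
             "rmsd_r1": [p[0] for p in pts],
             "rmsd_r2": [p[1] for p in pts]}
        )

    def test_two_blobs_recovered_with_nearest_center_oracle(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal([1, 1], 0.05, size=(8, 2))
        blob2 = rng.normal([6, 5], 0.05, size=(8, 2))
        pts = np.vstack([blob1, blob2])
        cl = dn.cluster_conformations(self._table(pts))
        assert cl.k == 2
        labels = np.array([cl.labels[f"i{k}"] for k in range(16)])
        oracle = np.array([np.argmin([np.linalg.norm(p - c) for c in cl.centers])
                           for p in pts])
        assert np.array_equal(labels, oracle)

    def test_identical_points_single_cluster(self):
        cl = dn.cluster_conformations(self._table([(1.0, 2.0)] * 6))
        assert cl.k == 1

    def test_label_invariance_to_point_order(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal([1, 1], 0.1, (6, 2)),
                         rng.normal([5, 4], 0.1, (6, 2))])
        t1 = self._table(pts)
        t2 = t1.sample(frac=1, random_state=3)
        c1 = dn.cluster_conformations(t1)
        c2 = dn.cluster_conformations(t2)
        assert c1.labels == c2.labels

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            dn.cluster_conformations(self._table([(0, 0)]))

    def test_six_planted_archetypes_recovered(self):
        from conftest import hungarian_agreement

        t = sd.build_template("mixed", 90, seed=0, protein_acc="SWTEST")
        ens, truth = sd.generate_switch_ensemble(
            t, (26, 46), (51, 78), n_per_pattern=12, seed=0
        )
        ref = sd.clone_instance(t)
        ref.is_predicted = True
        tab = dn.two_region_rmsd(ens, ref, _region_specs())
        cl = dn.cluster_conformations(tab)
        assert cl.k == 6
        pred = [cl.labels[i] for i in tab["instance_id"]]
        assert hungarian_agreement(truth, pred) >= 0.95


class TestThresholdFractions:
    def test_all_zero(self):
        tab = pd.DataFrame({"instance_id": list("abc"),
                            "rmsd_r1": [0.0] * 3, "rmsd_r2": [0.0] * 3})
        assert set(dn.threshold_fractions(tab).values()) == {1.0}

    def test_direct_count(self):
        tab = pd.DataFrame({
            "instance_id": list("abcd"),
            "rmsd_r1": [0.5, 2.0, 3.0, 6.0],
            "rmsd_r2": [0.2, 1.0, 1.0, 1.0],
        })
        fr = dn.threshold_fractions(tab)
        assert fr[1.0] == 0.25 and fr[2.5] == 0.5 and fr[5.0] == 0.75

    def test_non_decreasing_property(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({
            "instance_id": [f"i{k}" for k in range(20)],
            "rmsd_r1": rng.exponential(2, 20),
            "rmsd_r2": rng.exponential(2, 20),
        })
        fr = list(dn.threshold_fractions(tab).values())
        assert fr == sorted(fr)


def _census_row(gid, median, accs):
    return GroupCensusRow(gid, "subcluster", 5, median, 0.1, 0.1,
                          median, median, 0, 0, protein_accs=tuple(accs))


class TestSelectProteinSets:
    def test_all_rigid_het_empty(self):
        rows = [_census_row(f"g{i}", 0.5, [f"P{i}"]) for i in range(10)]
        het, con = dn.select_protein_sets(rows)
        assert het == set()

    def test_lowest_decile_and_cutoff(self):
        rows = [_census_row(f"g{i}", float(i + 1), [f"P{i}"]) for i in range(10)]
        het, con = dn.select_protein_sets(rows)
        assert con == {"P0"}
        assert het == {f"P{i}" for i in range(2, 10)}  # medians 3..10 > 2.5

    def test_protein_with_rigid_and_flexible_domain_goes_het(self):
        rows = [
            _census_row("g0", 0.3, ["PX"]),
            _census_row("g1", 5.0, ["PX"]),
        ] + [_census_row(f"g{i+2}", 1.0, [f"P{i}"]) for i in range(4)]
        het, con = dn.select_protein_sets(rows)
        assert "PX" in het and "PX" not in con
        assert het.isdisjoint(con)


def _brute_force_tail(m, k_total, n_draw, k_obs):
    """P(X >= k_obs) by exact enumeration over all draws of size n_draw."""
    hits = total = 0
    for draw in combinations(range(m), n_draw):
        total += 1
        if sum(1 for x in draw if x < k_total) >= k_obs:
            hits += 1
    return hits / total


class TestHypergeomEnrich:
    def _ann(self, mapping):
        return pd.DataFrame(
            [{"protein_acc": p, "term": t} for p, ts in mapping.items() for t in ts]
        )

    def test_exact_small_case(self):
        het = {f"H{i}" for i in range(5)}
        con = {f"C{i}" for i in range(5)}
        ann = self._ann({p: ["t1"] for p in het})
        res = [r for r in dn.hypergeom_enrich(het, con, ann) if r.direction == "het"]
        assert res[0].p_value == pytest.approx(1 / 252)

    def test_term_annotating_everything_p_one(self):
        het, con = {"H1", "H2"}, {"C1", "C2"}
        ann = self._ann({p: ["t"] for p in het | con})
        for r in dn.hypergeom_enrich(het, con, ann):
            assert r.p_value == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            m = int(rng.integers(6, 13))
            n_het = int(rng.integers(2, m - 2))
            universe = [f"P{i}" for i in range(m)]
            het = set(universe[:n_het])
            con = set(universe[n_het:])
            k_total = int(rng.integers(1, m))
            ann = self._ann({p: ["t"] for p in universe[:k_total]})
            res = {r.direction: r for r in dn.hypergeom_enrich(het, con, ann)}
            k_obs = len(set(universe[:k_total]) & het)
            assert res["het"].p_value == pytest.approx(
                _brute_force_tail(m, k_total, n_het, k_obs)
            )

    def test_monotone_in_count_at_fixed_margins(self):
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 20, 8, 10)) for k in range(0, 9)]
        assert ps == sorted(ps, reverse=True)

    def test_bh_adjustment_present(self):
        het = {f"H{i}" for i in range(5)}
        con = {f"C{i}" for i in range(5)}
        ann = self._ann({p: ["t1", "t2"] for p in het})
        res = dn.hypergeom_enrich(het, con, ann)
        assert all(np.isfinite(r.adjusted_p) and r.adjusted_p >= r.p_value - 1e-12
                   for r in res)
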